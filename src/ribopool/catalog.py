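"""Ribotype catalog: diagnostic matrix, identity calling, abundance tables.

The catalog is a matrix of named ribotypes x diagnostic alignment columns
(character states in {A, C, G, T, D}; D marks a deleted column).  The
reference row (As1) is fully specified; other rows are dot-encoded against
it.  Unique sequences from a dereplicated pool are aligned to the reference
frame, projected onto the diagnostic columns, and called by exact state-map
identity — the operation behind statements like "the main ribotype of X is
identical to the main ribotype of Y".  Per-accession abundance tables carry
read counts, integer percentages (round-half-up), and the major/minor
classification (a major ribotype has more than ``major_threshold`` reads in
its pool).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .reference import (
    CoordinateError,
    ReferenceFrame,
    RibotypeDefinition,
    materialize_ribotype_sequence,
)

NOVEL = "novel"
UNASSIGNED = "unassigned"

#: Default major-ribotype threshold: strictly more than this many reads.
MAJOR_THRESHOLD = 1000

#: Beyond this column distance a novel variant's subgenome family is not
#: inferred from its nearest row (cross-family distances are ~40 columns,
#: sequencing noise 1-2, so 5 separates them cleanly).
NOVEL_FAMILY_CUTOFF = 5


class MatrixParseError(ValueError):
    pass


class ForeignSequenceError(ValueError):
    """Sequence does not align to the reference frame at usable identity."""


class EmptyPoolError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticMatrix:
    """Named ribotypes x diagnostic alignment columns."""

    positions: tuple[int, ...]
    reference_name: str
    rows: dict[str, RibotypeDefinition]   # fully expanded over all positions
    family: dict[str, str]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def states_of(self, name: str) -> dict[int, str]:
        return dict(self.rows[name].states)


def load_diagnostic_matrix(path: str | Path | None = None) -> DiagnosticMatrix:
    """Load a catalog TSV (header of 1-based positions; one dot-encoded row
    per ribotype; first data row is the fully specified reference).

    With no path, loads the packaged catalog transcription.
    """
    if path is None:
        path = resources.files("ribopool.data") / "ribotype_matrix.tsv"
    with open(str(path), newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["ribotype", "family"]:
            raise MatrixParseError("header must start with 'ribotype', 'family'")
        try:
            positions = tuple(int(p) for p in header[2:])
        except ValueError as exc:
            raise MatrixParseError(f"non-integer position in header: {exc}")
        rows: dict[str, RibotypeDefinition] = {}
        family: dict[str, str] = {}
        reference: dict[int, str] | None = None
        reference_name = ""
        for rec in reader:
            if not rec or not rec[0]:
                continue
            name, fam, cells = rec[0], rec[1], rec[2:]
            if name in rows:
                raise MatrixParseError(f"duplicate ribotype name {name!r}")
            if len(cells) != len(positions):
                raise MatrixParseError(
                    f"row {name!r} has {len(cells)} cells, expected {len(positions)}"
                )
            states: dict[int, str] = {}
            for pos, cell in zip(positions, cells):
                if cell == ".":
                    if reference is None:
                        raise MatrixParseError(
                            f"dot in reference row {name!r} at column {pos}"
                        )
                    states[pos] = reference[pos]
                elif cell in "ACGTD":
                    states[pos] = cell
                else:
                    raise MatrixParseError(
                        f"invalid cell {cell!r} in row {name!r} at column {pos}"
                    )
            if reference is None:
                reference = states
                reference_name = name
            rows[name] = RibotypeDefinition(name=name, states=states)
            family[name] = fam
    if reference is None:
        raise MatrixParseError("matrix has no rows")
    return DiagnosticMatrix(
        positions=positions,
        reference_name=reference_name,
        rows=rows,
        family=family,
    )


def column_distance(a: Mapping[int, str], b: Mapping[int, str]) -> int:
    """Count of diagnostic columns with differing states.

    Base vs base and base vs D each count 1; shared deletions (D vs D)
    count 0.  Symmetric, zero iff identical.
    """
    if set(a) != set(b):
        raise ValueError("state maps cover different position sets")
    return sum(1 for p in a if a[p] != b[p])


# ---------------------------------------------------------------------------
# Alignment projection
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end gaps free: the amplicon may start/stop inside the frame
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_to_reference(
    sequence: str,
    frame: ReferenceFrame,
    matrix: DiagnosticMatrix,
    min_identity: float = 0.8,
    max_length_deviation: float = 0.10,
) -> dict[int, str]:
    """Globally align a sequence to the reference frame (match +1, mismatch
    -1, gap -2, end gaps free) and read off the observed state — base or D —
    at every diagnostic column.
    """
    ref = frame.sequence
    if not ref:
        raise ValueError("empty reference frame")
    dev = abs(len(sequence) - len(ref)) / len(ref)
    if dev > max_length_deviation:
        raise ForeignSequenceError(
            f"length {len(sequence)} deviates {dev:.0%} from frame {len(ref)}"
        )
    alignment = _ALIGNER.align(ref, sequence)[0]
    ref_idx, query_idx = alignment.indices
    states: dict[int, str] = {}
    matches = 0
    aligned_cols = 0
    query_at: dict[int, str] = {}
    for ri, qi in zip(ref_idx, query_idx):
        if ri < 0:
            continue
        if qi < 0:
            query_at[int(ri)] = "D"
        else:
            ch = sequence[int(qi)]
            query_at[int(ri)] = ch
            aligned_cols += 1
            if ch == ref[int(ri)]:
                matches += 1
    if aligned_cols == 0 or matches / max(aligned_cols, 1) < min_identity:
        raise ForeignSequenceError(
            f"alignment identity {matches}/{aligned_cols} below {min_identity:.0%}"
        )
    for pos in matrix.positions:
        states[pos] = query_at.get(pos - 1, "D")
    return states


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RibotypeCall:
    called_name: str           # catalog name, or "novel"
    distance_to_call: int      # 0 for exact matches; else distance to nearest
    family: str                # subgenome family, or "unassigned"
    nearest: tuple[str, ...]   # nearest catalog rows (all tied candidates)


def call_ribotype(
    states: Mapping[int, str],
    matrix: DiagnosticMatrix,
    novel_family_cutoff: int = NOVEL_FAMILY_CUTOFF,
) -> RibotypeCall:
    """Call a state map against the catalog by exact identity, falling back
    to the nearest row(s) by column distance.  A tie between nearest rows is
    reported as-is (both candidates, no arbitrary pick); the family is copied
    from the nearest row(s) when they agree and the distance is within
    ``novel_family_cutoff``, otherwise "unassigned".
    """
    distances = {
        name: column_distance(states, row.states) for name, row in matrix.rows.items()
    }
    dmin = min(distances.values())
    nearest = tuple(sorted(n for n, d in distances.items() if d == dmin))
    if dmin == 0:
        name = nearest[0]
        return RibotypeCall(name, 0, matrix.family[name], nearest)
    families = {matrix.family[n] for n in nearest}
    if dmin <= novel_family_cutoff and len(families) == 1:
        fam = families.pop()
    else:
        fam = UNASSIGNED
    return RibotypeCall(NOVEL, dmin, fam, nearest)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def percent_of_pool(read_count: int, total_reads: int) -> int:
    """Integer percent with round-half-up, in exact integer arithmetic."""
    if total_reads <= 0:
        raise EmptyPoolError("total_reads must be positive")
    return (200 * read_count + total_reads) // (2 * total_reads)


@dataclass(frozen=True)
class TableEntry:
    name: str
    read_count: int
    percent: int
    is_major: bool


@dataclass(frozen=True)
class RibotypeTable:
    accession_id: str
    genome_label: str
    total_reads: int
    entries: tuple[TableEntry, ...]

    def percents(self, include_novel: bool = False) -> dict[str, int]:
        return {
            e.name: e.percent
            for e in self.entries
            if include_novel or not e.name.startswith(NOVEL)
        }

    def major_names(self) -> set[str]:
        return {e.name for e in self.entries if e.is_major}


@dataclass(frozen=True)
class CalledUnique:
    """A unique sequence with its projected states and catalog call."""

    sequence: str
    read_count: int
    states: Mapping[int, str]
    call: RibotypeCall


def call_pool(
    uniques: Sequence,
    frame: ReferenceFrame,
    matrix: DiagnosticMatrix,
    novel_family_cutoff: int = NOVEL_FAMILY_CUTOFF,
) -> tuple[list[CalledUnique], int]:
    """Align and call every unique sequence of a dereplicated pool.

    Returns the calls plus the number of reads excluded as foreign (failed
    the identity/length screens).
    """
    called: list[CalledUnique] = []
    n_foreign = 0
    for u in uniques:
        try:
            states = align_to_reference(u.sequence, frame, matrix)
        except ForeignSequenceError:
            n_foreign += u.read_count
            continue
        called.append(
            CalledUnique(
                sequence=u.sequence,
                read_count=u.read_count,
                states=states,
                call=call_ribotype(states, matrix, novel_family_cutoff),
            )
        )
    return called, n_foreign


def aggregate_pool(
    called: Sequence[CalledUnique],
    matrix: DiagnosticMatrix,
    derivative_mode: bool = False,
) -> tuple[dict[str, int], dict[str, dict[int, str]]]:
    """Sum read counts by called ribotype name, keeping one state map per
    aggregated name.

    Novel variants are kept apart under generated ``novel-<k>`` labels
    (numbered by descending count).  In derivative mode, a novel variant at
    column distance 1 from a single nearest catalog row is pooled into that
    row, reflecting that most low-frequency variants are sequencing/PCR
    derivatives of a major ribotype.
    """
    counts: dict[str, int] = {}
    states_by_name: dict[str, dict[int, str]] = {}
    novels: list[CalledUnique] = []
    for cu in called:
        call = cu.call
        if call.called_name != NOVEL:
            counts[call.called_name] = counts.get(call.called_name, 0) + cu.read_count
            states_by_name[call.called_name] = matrix.states_of(call.called_name)
        elif (
            derivative_mode
            and call.distance_to_call == 1
            and len(call.nearest) == 1
        ):
            host = call.nearest[0]
            counts[host] = counts.get(host, 0) + cu.read_count
            states_by_name[host] = matrix.states_of(host)
        else:
            novels.append(cu)
    novels.sort(
        key=lambda cu: (-cu.read_count, cu.call.nearest, tuple(sorted(cu.states.items())))
    )
    merged: dict[tuple, str] = {}  # identical state maps collapse to one node
    for cu in novels:
        key = tuple(sorted(cu.states.items()))
        name = merged.get(key)
        if name is None:
            name = f"{NOVEL}-{len(merged) + 1}"
            merged[key] = name
            states_by_name[name] = dict(cu.states)
        counts[name] = counts.get(name, 0) + cu.read_count
    return counts, states_by_name


def aggregate_calls(
    called: Iterable[tuple[RibotypeCall, int]],
    derivative_mode: bool = False,
) -> dict[str, int]:
    """Read-count aggregation by called name (counts only; see
    :func:`aggregate_pool` for the variant that retains state maps)."""
    counts: dict[str, int] = {}
    novels: list[tuple[int, RibotypeCall]] = []
    for call, n in called:
        if call.called_name != NOVEL:
            counts[call.called_name] = counts.get(call.called_name, 0) + n
        elif (
            derivative_mode
            and call.distance_to_call == 1
            and len(call.nearest) == 1
        ):
            novels_host = call.nearest[0]
            counts[novels_host] = counts.get(novels_host, 0) + n
        else:
            novels.append((n, call))
    novels.sort(key=lambda t: (-t[0], t[1].nearest))
    for k, (n, _call) in enumerate(novels, start=1):
        counts[f"{NOVEL}-{k}"] = counts.get(f"{NOVEL}-{k}", 0) + n
    return counts


def build_ribotype_table(
    counts: Mapping[str, int],
    accession_id: str,
    total_reads: int,
    genome_label: str = "",
    major_threshold: int = MAJOR_THRESHOLD,
) -> RibotypeTable:
    """Build a per-accession ribotype abundance table.

    ``counts`` maps called name -> read count (see :func:`aggregate_calls`);
    ``total_reads`` is the pool size (may exceed the sum of counts when reads
    were filtered upstream).  A ribotype is major iff its count is strictly
    greater than ``major_threshold``.
    """
    if total_reads <= 0:
        raise EmptyPoolError("empty pool: total_reads must be positive")
    if sum(counts.values()) > total_reads:
        raise ValueError("entry counts exceed total_reads")
    entries = tuple(
        TableEntry(
            name=name,
            read_count=c,
            percent=percent_of_pool(c, total_reads),
            is_major=c > major_threshold,
        )
        for name, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return RibotypeTable(accession_id, genome_label, total_reads, entries)


def table_from_pool(
    uniques: Sequence,
    frame: ReferenceFrame,
    matrix: DiagnosticMatrix,
    accession_id: str,
    total_reads: int,
    genome_label: str = "",
    major_threshold: int = MAJOR_THRESHOLD,
    derivative_mode: bool = False,
    novel_family_cutoff: int = NOVEL_FAMILY_CUTOFF,
) -> tuple[RibotypeTable, int]:
    """Align, call and tabulate a dereplicated pool.

    Returns the table plus the number of reads excluded as foreign (failed
    identity/length screens).
    """
    called, n_foreign = call_pool(uniques, frame, matrix, novel_family_cutoff)
    counts, _states = aggregate_pool(called, matrix, derivative_mode=derivative_mode)
    return (
        build_ribotype_table(
            counts, accession_id, total_reads, genome_label, major_threshold
        ),
        n_foreign,
    )


# ---------------------------------------------------------------------------
# Cross-accession comparison
# ---------------------------------------------------------------------------

def shared_ribotypes(
    a: RibotypeTable, b: RibotypeTable
) -> list[tuple[str, int, int, int, int]]:
    """Catalog ribotypes present in both tables, as
    (name, count_a, pct_a, count_b, pct_b), ordered by min(pct) descending.
    Novel entries are excluded — they are not comparable across pools.
    """
    ea = {e.name: e for e in a.entries if not e.name.startswith(NOVEL)}
    eb = {e.name: e for e in b.entries if not e.name.startswith(NOVEL)}
    shared = [
        (n, ea[n].read_count, ea[n].percent, eb[n].read_count, eb[n].percent)
        for n in ea.keys() & eb.keys()
    ]
    shared.sort(key=lambda t: (-min(t[2], t[4]), t[0]))
    return shared


def parent_overlap_score(cultivated: RibotypeTable, candidate: RibotypeTable) -> int:
    """Sum over shared ribotypes of min(percent) — how much of the two pools'
    composition overlaps.  Identical tables score the sum of their percents;
    disjoint tables score 0.  Candidate parents are ranked by this score.
    """
    return sum(min(pa, pb) for _, _, pa, _, pb in shared_ribotypes(cultivated, candidate))


# ---------------------------------------------------------------------------
# Table I/O and the packaged study tables
# ---------------------------------------------------------------------------

def write_table_tsv(table: RibotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tgenome\ttotal_reads\tribotype\treads\tpercent\tmajor\n")
        for e in table.entries:
            fh.write(
                f"{table.accession_id}\t{table.genome_label}\t{table.total_reads}\t"
                f"{e.name}\t{e.read_count}\t{e.percent}\t{int(e.is_major)}\n"
            )


def read_table_tsv(path: str | Path) -> RibotypeTable:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise ValueError(f"empty table file {path}")
    entries = tuple(
        TableEntry(r["ribotype"], int(r["reads"]), int(r["percent"]), bool(int(r["major"])))
        for r in rows
    )
    return RibotypeTable(
        accession_id=rows[0]["accession"],
        genome_label=rows[0]["genome"],
        total_reads=int(rows[0]["total_reads"]),
        entries=entries,
    )


def load_published_tables(path: str | Path | None = None) -> dict[str, RibotypeTable]:
    """Load the packaged transcription of the study's per-accession
    major-ribotype tables (printed counts and percents, kept verbatim —
    including the printed inconsistencies the lint flags)."""
    if path is None:
        path = resources.files("ribopool.data") / "major_ribotype_tables.tsv"
    by_acc: dict[str, list[dict[str, str]]] = {}
    with open(str(path), newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            by_acc.setdefault(rec["sample_id"], []).append(rec)
    tables = {}
    for acc, recs in by_acc.items():
        entries = tuple(
            TableEntry(
                name=r["ribotype"],
                read_count=int(r["reads"]),
                percent=int(r["percent"]),
                is_major=int(r["reads"]) > MAJOR_THRESHOLD,
            )
            for r in recs
        )
        tables[acc] = RibotypeTable(
            accession_id=acc,
            genome_label=recs[0]["genome"],
            total_reads=int(recs[0]["total_reads"]),
            entries=entries,
        )
    return tables
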