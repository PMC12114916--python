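"""Reference coordinate frame for ribotype alignment positions.

Ribotype definitions are given as character states over a fixed set of 1-based
alignment columns (the diagnostic-matrix coordinate system, columns 1..330).
Named ribotypes of the A-genome family share two deletion columns relative to
that frame; the C-genome-related ribotype instead realizes bases there and
deletes others.  The frame therefore carries a base at *every* alignment
column, plus the set of columns deleted in the reference ribotype (As1), so
that any ribotype — with or without the shared deletions — can be materialized
into an ungapped sequence and any observed sequence can be projected back onto
matrix coordinates.

The packaged frame sequence is SYNTHETIC: the study this mirrors does not
publish the full ITS1 amplicon, only the diagnostic columns.  The synthetic
330 bp sequence agrees with the reference ribotype (As1) at every diagnostic
column and is arbitrary (fixed once) elsewhere.  Everything downstream is a
function of the diagnostic columns only, so analyses of real data would swap
in the true reference without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STATES = frozenset("ACGTD")

# Synthetic ITS1-like frame realization (see module docstring).  Columns are
# 1-based; diagnostic columns match the As1 row of the packaged matrix, with
# the two As1-deleted columns (135, 307) holding the base the C-genome-related
# ribotype realizes there.
SYNTHETIC_FRAME_SEQ = (
    "GAGCAGACTTTCCGGGTCGCAGCAGTTCCAGATCTATTGATTCCCAGTTCTTGGTGCTGG"
    "AGTAACTCCATCTTGGTGCCGGTCACACAAGAACGATTACTCCGCCTGTCTAAGTGCTTA"
    "ATTGAGGGAAATAACGTCTCAGATTCAATCTTAAGTTGCCCTTTGTCGTATAGAGAGTCG"
    "CAGTTTGTTATACGTTCCTGTTGCCATGCCCAGGATTCGAGGCTCCGTCGGCAAAATCTG"
    "TACAAGATCCACACTGTTGGGGCTCATATAATGGTAACGTCCACTACCGTACCTTAGAGA"
    "GAACTTCTTATAGCTTTGCACGGGCACCGC"
)

# Alignment columns deleted in the reference ribotype (As1).
REFERENCE_DELETIONS = frozenset({135, 307})


class CoordinateError(ValueError):
    """A ribotype definition references a column outside the frame."""


@dataclass(frozen=True)
class RibotypeDefinition:
    """A named ribotype given by character states over alignment columns.

    ``states`` maps 1-based alignment column -> state in {A, C, G, T, D},
    where D marks a column deleted in this ribotype.  Columns not listed
    default to the reference (As1) state.
    """

    name: str
    states: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.states.values() if s not in VALID_STATES}
        if bad:
            raise ValueError(f"invalid states {sorted(bad)} in {self.name!r}")


@dataclass(frozen=True)
class ReferenceFrame:
    """The alignment coordinate system with a base at every column."""

    sequence: str = SYNTHETIC_FRAME_SEQ
    reference_deletions: frozenset[int] = REFERENCE_DELETIONS

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise CoordinateError(
                f"column {position} outside frame 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


def materialize_ribotype_sequence(
    frame: ReferenceFrame, definition: RibotypeDefinition
) -> str:
    """Realize a ribotype definition as an ungapped nucleotide sequence.

    Each listed non-deletion state replaces the frame base at its column;
    columns with state D are removed; unlisted columns keep the reference
    (As1) realization — i.e. the frame base, except at the reference-deleted
    columns, which are absent unless the definition explicitly realizes them.
    """
    out = []
    for pos in range(1, len(frame) + 1):
        state = definition.states.get(pos)
        if state is None:
            state = "D" if pos in frame.reference_deletions else frame.base_at(pos)
        if state == "D":
            continue
        out.append(state)
    for pos in definition.states:
        frame.base_at(pos)  # raises CoordinateError if out of range
    return "".join(out)
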