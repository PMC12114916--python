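"""Synthetic paired-end amplicon pool generator.

Emulates the statistical structure of a polyploid rDNA amplicon pool
sequenced as 2x300 paired-end reads: a mixture of a handful of true ribotype
sequences at fixed proportions (the multi-subgenome rDNA pool), a cloud of
low-frequency variants, and independent per-base substitution errors with a
declining 3' quality profile.  Everything is driven by one seeded generator
per pool, with a documented draw order, so output is byte-reproducible.

Draw order (one ``numpy`` Generator per pool):

1. one multinomial assignment of ribotypes to all read pairs (mixture keys
   in sorted name order);
2. per pair, in order: forward qualities, reverse qualities, forward error
   mask, forward substitution offsets, reverse error mask, reverse offsets.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .reference import ReferenceFrame, RibotypeDefinition, materialize_ribotype_sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Offsets i -> the i-th alternative base, per original base (error model).
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Pool specification is internally inconsistent."""


@dataclass(frozen=True)
class PoolSpec:
    """Recipe for one simulated per-accession amplicon pool.

    ``mixture`` maps ribotype name -> proportion of read pairs; proportions
    must sum to 1.  ``quality_mean``/``quality_decay`` parameterize the mean
    Phred score at the 5' end and its linear per-base decline toward the 3'
    end (Phred units per base).
    """

    accession_id: str
    mixture: Mapping[str, float]
    n_read_pairs: int
    per_base_error_rate: float = 0.003
    read_length: int = 300
    quality_mean: float = 36.0
    quality_decay: float = 0.03
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_read_pairs <= 0:
            raise ConfigurationError("n_read_pairs must be positive")
        if not 0.0 <= self.per_base_error_rate < 0.1:
            raise ConfigurationError("per_base_error_rate must be in [0, 0.1)")
        if any(p < 0 for p in self.mixture.values()):
            raise ConfigurationError("mixture proportions must be >= 0")
        total = sum(self.mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"mixture proportions sum to {total}, not 1")


@dataclass(frozen=True)
class SimulatedReadPair:
    id: str
    forward_seq: str
    reverse_seq: str
    forward_qual: tuple[int, ...]
    reverse_qual: tuple[int, ...]
    true_ribotype: str

    def __post_init__(self) -> None:
        assert len(self.forward_seq) == len(self.forward_qual)
        assert len(self.reverse_seq) == len(self.reverse_qual)


def _simulate_mate(
    template: str, rng: np.random.Generator, spec: PoolSpec
) -> tuple[str, tuple[int, ...]]:
    """Qualities then errors for one mate, per the documented draw order."""
    n = len(template)
    means = spec.quality_mean - spec.quality_decay * np.arange(n)
    quals = np.clip(
        np.rint(rng.normal(means, spec.quality_sd)), 2, 41
    ).astype(np.int64)
    seq = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    mask = rng.random(n) < spec.per_base_error_rate
    k = int(mask.sum())
    if k:
        # substitute to one of the three other bases, uniformly
        offsets = rng.integers(1, 4, size=k)
        idx = np.searchsorted(_BASES, seq[mask])
        seq[mask] = _BASES[(idx + offsets) % 4]
    return seq.tobytes().decode(), tuple(int(q) for q in quals)


def simulate_pool(
    spec: PoolSpec, ribotype_sequences: Mapping[str, str]
) -> Iterator[SimulatedReadPair]:
    """Generate exactly ``spec.n_read_pairs`` simulated read pairs.

    The forward mate is the 5' prefix of the amplicon, the reverse mate the
    reverse complement of its 3' suffix; mates overlap whenever the amplicon
    is shorter than twice the read length.
    """
    missing = sorted(set(spec.mixture) - set(ribotype_sequences))
    if missing:
        raise ConfigurationError(f"mixture references unknown ribotypes: {missing}")
    names = sorted(spec.mixture)
    for name in names:
        amplicon = ribotype_sequences[name]
        if len(amplicon) > 2 * spec.read_length - 20:
            raise ConfigurationError(
                f"amplicon {name!r} too long for overlapping 2x{spec.read_length} reads"
            )
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.mixture[n] for n in names], dtype=float)
    probs /= probs.sum()
    assignment = rng.choice(len(names), size=spec.n_read_pairs, p=probs)
    for i, a in enumerate(assignment):
        name = names[a]
        amplicon = ribotype_sequences[name]
        fwd_tpl = amplicon[: spec.read_length]
        rev_tpl = reverse_complement(amplicon[-spec.read_length:])
        fseq, fq = _simulate_mate(fwd_tpl, rng, spec)
        rseq, rq = _simulate_mate(rev_tpl, rng, spec)
        yield SimulatedReadPair(
            id=f"{spec.accession_id}:{i:06d}",
            forward_seq=fseq,
            reverse_seq=rseq,
            forward_qual=fq,
            reverse_qual=rq,
            true_ribotype=name,
        )


def _open_text(path: Path, mode: str = "wt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_pool(
    pairs: Iterable[SimulatedReadPair],
    out_dir: str | Path,
    accession_id: str,
    compress: bool = False,
) -> dict[str, Path]:
    """Write a pool as Phred+33 FASTQ mates plus a ground-truth sidecar TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if compress else ".fastq"
    r1 = out_dir / f"{accession_id}_R1{ext}"
    r2 = out_dir / f"{accession_id}_R2{ext}"
    truth = out_dir / f"{accession_id}_truth.tsv"
    with _open_text(r1) as f1, _open_text(r2) as f2, open(truth, "w", newline="") as ft:
        tw = csv.writer(ft, delimiter="\t", lineterminator="\n")
        tw.writerow(["read_id", "true_ribotype"])
        for pair in pairs:
            f1.write(
                f"@{pair.id}/1\n{pair.forward_seq}\n+\n"
                + "".join(chr(q + 33) for q in pair.forward_qual)
                + "\n"
            )
            f2.write(
                f"@{pair.id}/2\n{pair.reverse_seq}\n+\n"
                + "".join(chr(q + 33) for q in pair.reverse_qual)
                + "\n"
            )
            tw.writerow([pair.id, pair.true_ribotype])
    return {"r1": r1, "r2": r2, "truth": truth}


# ---------------------------------------------------------------------------
# Study-condition fixtures
# ---------------------------------------------------------------------------

#: Major-ribotype mixture of the K-4480-like pool: four named ribotypes at
#: their observed fractions, the remaining 30% spread over 20 minor variants.
K4480_MAJORS = {"Ad2/As3": 0.40, "Al/As2": 0.11, "As5": 0.11, "As6": 0.08}
K4480_N_READ_PAIRS = 21_927

#: Diagnostic columns untouched by every named A-family ribotype; minor
#: variants are placed here so they stay >= 2 columns from any catalog row.
_MINOR_VARIANT_COLUMNS = (29, 36, 43, 56, 62, 81, 94, 96, 102, 111,
                          118, 122, 126, 143, 161, 174, 184, 194, 198, 204)
_ALT = {"A": "G", "C": "A", "G": "T", "T": "C"}


def minor_variant_definitions(
    frame: ReferenceFrame, n: int = 20, prefix: str = "min"
) -> list[RibotypeDefinition]:
    """Low-frequency novel variants: two substitutions at quiet diagnostic
    columns, so each sits at column distance >= 2 from every catalog row."""
    cols = _MINOR_VARIANT_COLUMNS
    defs = []
    for i in range(n):
        a = cols[i % len(cols)]
        b = cols[(i + 1 + i // len(cols)) % len(cols)]
        if a == b:
            b = cols[(i + 2) % len(cols)]
        states = {a: _ALT[frame.base_at(a)], b: _ALT[frame.base_at(b)]}
        defs.append(RibotypeDefinition(name=f"{prefix}{i + 1:02d}", states=states))
    return defs


def k4480_pool(
    frame: ReferenceFrame,
    catalog_definitions: Mapping[str, RibotypeDefinition],
    seed: int = 0,
    n_read_pairs: int = K4480_N_READ_PAIRS,
    per_base_error_rate: float = 0.003,
) -> tuple[PoolSpec, dict[str, str]]:
    """Pool spec + sequences emulating the deepest A-strigosa accession:
    majors at 40/11/11/8 % and 30% spread over 20 minor novel variants."""
    minors = minor_variant_definitions(frame)
    mixture = dict(K4480_MAJORS)
    remainder = 1.0 - sum(mixture.values())
    for d in minors:
        mixture[d.name] = remainder / len(minors)
    sequences = {
        name: materialize_ribotype_sequence(frame, catalog_definitions[name])
        for name in K4480_MAJORS
    }
    for d in minors:
        sequences[d.name] = materialize_ribotype_sequence(frame, d)
    spec = PoolSpec(
        accession_id="K-4480-sim",
        mixture=mixture,
        n_read_pairs=n_read_pairs,
        per_base_error_rate=per_base_error_rate,
        seed=seed,
    )
    return spec, sequences
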