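"""Amplicon read processing: quality trimming, pair merging, dereplication.

The stage mirrors a conventional paired-end amplicon workflow for a short
(~330 bp) rDNA fragment sequenced as 2x300 reads: sliding-window quality
trimming of each mate, ungapped overlap merging with quality-weighted
consensus, and exact (100% identity) dereplication of the merged amplicons
into unique sequences with read counts.  Dereplication is deliberately exact:
ribotypes of interest differ by single substitutions, so any similarity
clustering would collapse them.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .synth import reverse_complement


@dataclass(frozen=True)
class TrimParams:
    """Sliding-window trimming parameters (window mean-quality rule)."""

    window_size: int = 4
    quality_threshold: float = 12.0
    min_length: int = 130

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.min_length < self.window_size:
            raise ValueError("min_length must be >= window_size")


@dataclass(frozen=True)
class Read:
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    read_count: int


def sliding_window_trim(read: Read, params: TrimParams) -> Read | None:
    """Trim a read at the first window whose mean quality drops below the
    threshold; within that window, individual bases still at or above the
    threshold are kept.  Returns ``None`` (discard) if the trimmed read is
    shorter than ``min_length``.
    """
    n = len(read.sequence)
    if n == 0:
        return None
    w = params.window_size
    cut = n
    if n >= w:
        q = np.asarray(read.qualities, dtype=float)
        window_means = np.convolve(q, np.ones(w) / w, mode="valid")
        failing = np.nonzero(window_means < params.quality_threshold)[0]
        if failing.size:
            cut = int(failing[0])
            # keep leading in-window bases that individually pass
            while cut < n and read.qualities[cut] >= params.quality_threshold:
                cut += 1
    if cut < params.min_length:
        return None
    if cut == n:
        return read
    return Read(read.sequence[:cut], read.qualities[:cut])


def merge_pair(
    forward: Read,
    reverse: Read,
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
) -> str | None:
    """Merge a trimmed mate pair into a consensus amplicon, or ``None``.

    The reverse mate is reverse-complemented and slid ungapped along the
    forward mate; the admissible offset (overlap >= ``min_overlap``, mismatch
    fraction <= ``max_mismatch_fraction``) with the highest score
    (matches - mismatches, ties to the longer overlap, then the smaller
    offset) defines the merge.  At overlap mismatches the base with the
    higher quality wins (ties to the forward base).
    """
    f = np.frombuffer(forward.sequence.encode(), dtype=np.uint8)
    r = np.frombuffer(
        reverse_complement(reverse.sequence).encode(), dtype=np.uint8
    )
    fq = np.asarray(forward.qualities, dtype=np.int64)
    rq = np.asarray(reverse.qualities[::-1], dtype=np.int64)
    nf, nr = len(f), len(r)
    if min(nf, nr) < min_overlap:
        return None

    def overlap_len(shift: int) -> int:
        return min(nf, shift + nr) - max(0, shift)

    shifts = sorted(
        range(-(nr - min_overlap), nf - min_overlap + 1),
        key=lambda s: (-overlap_len(s), abs(s), s),
    )
    best: tuple[int, int, int] | None = None  # (score, overlap, shift)
    for shift in shifts:
        ov = overlap_len(shift)
        if best is not None and best[0] >= ov:
            break  # no remaining shift can beat a found score
        lo_f, lo_r = max(0, shift), max(0, -shift)
        matches = int(np.count_nonzero(f[lo_f : lo_f + ov] == r[lo_r : lo_r + ov]))
        mism = ov - matches
        if mism > max_mismatch_fraction * ov:
            continue
        score = matches - mism
        if best is None or score > best[0]:
            best = (score, ov, shift)
    if best is None:
        return None
    _, ov, shift = best
    lo_f, lo_r = max(0, shift), max(0, -shift)
    fo, ro = f[lo_f : lo_f + ov], r[lo_r : lo_r + ov]
    take_r = rq[lo_r : lo_r + ov] > fq[lo_f : lo_f + ov]
    consensus = np.where(take_r, ro, fo)
    left = r[:lo_r] if shift < 0 else f[:lo_f]
    if shift + nr > nf:
        right = r[lo_r + ov :]
    else:
        right = f[lo_f + ov :]
    return np.concatenate([left, consensus, right]).tobytes().decode()


def dereplicate(sequences: Iterable[str]) -> tuple[list[UniqueSequence], int]:
    """Collapse exactly identical sequences into counted unique sequences.

    Sequences containing ambiguity characters (N) are excluded and counted
    separately, since a single N would fragment a true ribotype into spurious
    variants.  Output is ordered by read count descending, then sequence.
    """
    counts: Counter[str] = Counter()
    n_ambiguous = 0
    for seq in sequences:
        if "N" in seq:
            n_ambiguous += 1
            continue
        counts[seq] += 1
    uniques = [
        UniqueSequence(s, c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return uniques, n_ambiguous


# ---------------------------------------------------------------------------
# FASTQ I/O and the pooled stage
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Plain 4-line Phred+33 FASTQ reader (optionally gzipped)."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record in {path}")
            yield Read(seq, tuple(ord(c) - 33 for c in qual))


@dataclass(frozen=True)
class ProcessStats:
    n_pairs: int
    n_discarded: int  # pairs lost to trimming (either mate below min length)
    n_rejected: int   # pairs with no admissible overlap
    n_merged: int
    n_ambiguous: int  # merged sequences containing N

    def conserved(self) -> bool:
        return self.n_pairs == self.n_discarded + self.n_rejected + self.n_merged


def process_pairs(
    pairs: Iterable[tuple[Read, Read]],
    trim: TrimParams = TrimParams(),
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
) -> tuple[list[UniqueSequence], ProcessStats]:
    """Trim, merge and dereplicate a stream of mate pairs."""
    merged: list[str] = []
    n_pairs = n_discarded = n_rejected = 0
    for fwd, rev in pairs:
        n_pairs += 1
        tf = sliding_window_trim(fwd, trim)
        tr = sliding_window_trim(rev, trim)
        if tf is None or tr is None:
            n_discarded += 1
            continue
        amplicon = merge_pair(tf, tr, min_overlap, max_mismatch_fraction)
        if amplicon is None:
            n_rejected += 1
            continue
        merged.append(amplicon)
    uniques, n_ambiguous = dereplicate(merged)
    stats = ProcessStats(
        n_pairs=n_pairs,
        n_discarded=n_discarded,
        n_rejected=n_rejected,
        n_merged=len(merged),
        n_ambiguous=n_ambiguous,
    )
    return uniques, stats


def process_fastq(
    r1: str | Path,
    r2: str | Path,
    trim: TrimParams = TrimParams(),
    min_overlap: int = 20,
    max_mismatch_fraction: float = 0.1,
) -> tuple[list[UniqueSequence], ProcessStats]:
    return process_pairs(
        zip(read_fastq(r1), read_fastq(r2), strict=True),
        trim,
        min_overlap,
        max_mismatch_fraction,
    )


def write_uniques_fasta(uniques: Iterable[UniqueSequence], path: str | Path) -> None:
    """Unique sequences as FASTA with ``;size=<count>`` abundance headers."""
    with open(path, "w") as fh:
        for i, u in enumerate(uniques, start=1):
            fh.write(f">seq{i};size={u.read_count}\n{u.sequence}\n")


def write_uniques_tsv(uniques: Iterable[UniqueSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tread_count\n")
        for u in uniques:
            fh.write(f"{u.sequence}\t{u.read_count}\n")
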