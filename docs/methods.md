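# Methods

## The analysis in one paragraph

An accession's rDNA pool is summarized by the exact-sequence composition of
its ITS1 amplicons. Merged reads are dereplicated at 100% identity; each
unique sequence is aligned to a reference coordinate frame and read off at a
fixed set of diagnostic alignment columns; the resulting state map is called
against a catalog of named ribotypes by exact identity (nearest-row with
distance otherwise). Per-accession tables report read counts, integer
percents and the major/minor classification; cross-accession overlap of
called ribotypes quantifies shared parentage; and a statistical-parsimony
network connects ribotype state maps by single mutational steps up to a
confidence-bounded connection limit.

## The diagnostic matrix and reference frame

The catalog is a matrix of 14 named ribotypes × 50 diagnostic columns
(1-based alignment positions 29–316). The reference row (As1) is fully
specified; other rows are dot-encoded against it; `D` marks a deleted
column. Distances between ribotypes count differing columns: base↔base and
base↔D are 1 each, D↔D is 0. No indel weighting is applied — the matrix is
column-encoded and single columns are the unit of variation.

The packaged 330 bp reference frame sequence is **synthetic**: only the
diagnostic columns of the reference ribotype are fixed by the catalog, so
the frame carries those states, a base at every remaining column (arbitrary,
fixed once), and the set of columns deleted in As1 (135 and 307). Two
properties were imposed by construction: neighbours of every deletable
column differ from the deleted base, and the free column 136 differs from
the shared state of columns 135/138; both make the single-gap alignment of
every catalog ribotype uniquely optimal, so gap placement (and hence the
projected `D` state) is never ambiguous. Analyses of real data would swap in
the true reference sequence; everything downstream depends only on the
diagnostic columns.

Alignment to the frame is global pairwise (match +1, mismatch −1, gap −2,
end gaps free, via Biopython's `PairwiseAligner`); sequences whose length
deviates more than 10% from the frame or whose identity falls below 80% are
excluded as foreign.

## Read processing

- **Trimming** re-implements the conventional sliding-window rule: scan
  5′→3′ with window 4; at the first window whose *mean* Phred quality drops
  below 12, cut — keeping the leading bases of that window that individually
  still meet the threshold (this matches the behaviour of the widely used
  trimmer, and is what makes a Q30×150 + Q2×50 read trim to exactly 150 bp).
  Reads shorter than 130 bp after cutting are discarded. The rule is
  idempotent.
- **Merging** is ungapped: the reverse mate is reverse-complemented and slid
  along the forward mate; the admissible offset (overlap ≥ 20, mismatch
  fraction ≤ 0.1) with the highest matches-minus-mismatches score wins, ties
  going to the longer overlap then the smaller offset. At overlap
  mismatches the higher-quality base is taken (ties to the forward mate).
  Defaults (20, 0.1) are conventional for 2×300 amplicons of a ~330 bp
  fragment, where mates overlap by ~270 bp.
- **Dereplication** is exact string identity, ordered by count descending
  then sequence; no similarity clustering, because named ribotypes differ by
  as little as one substitution. Sequences containing `N` are excluded and
  counted separately rather than allowed to fragment true ribotypes.

## Tables, percents, majors

Integer percent = round-half-up(100·reads/total), computed in exact integer
arithmetic: `(200·c + t) // (2·t)`. A ribotype is **major** iff its count
strictly exceeds 1000 reads per pool; the network admission threshold is
≥ 10 reads (inclusive). Both are configuration values, not constants.

Novel variants (nonzero distance to every catalog row) are kept apart under
generated `novel-<k>` labels. In the optional **derivative mode** (off by
default), a novel variant at distance 1 from a single nearest catalog row is
pooled into that row. This reflects that in deep amplicon data most
low-frequency variants are sequencing/PCR derivatives of a major ribotype:
with a 0.3%/base error rate, roughly 8–10% of a ribotype's merged reads
carry an error at one of the 50 diagnostic columns and would otherwise leak
into singleton novels, biasing every major's percent a few points low. The
end-to-end recovery demonstration therefore runs with derivative mode on.

A table lint (`validate_table`) recomputes percents, checks that entry
counts do not exceed the pool total and that major flags match the
threshold. Applied to the packaged transcription of the published
per-accession tables it flags four blocks with internal arithmetic
inconsistencies; those printed rows are preserved verbatim and excluded from
exact-reproduction checks rather than corrected.

## Statistical-parsimony network

Connection limit: for two haplotypes differing at `j` of `m` sites, the
unknown true number of mutations `K ≥ j` is modelled by throwing `K`
mutations uniformly onto the `m` sites, each substituting to one of the
three alternative bases uniformly (Jukes–Cantor symmetry). A site hit `h`
times differs from its origin with probability `d_h = (3/4)(1 − (−1/3)^h)`;
collecting sites through the exponential generating function
`g(x,y) = Σ_h (y^h/h!)((1−d_h) + d_h x)` gives

    P(J = j | K = k) = (k!/m^k) · [y^k x^j] g(x,y)^m,

computed exactly by truncated polynomial exponentiation. With a flat prior
over `K`, the probability of parsimony is the posterior
`P_par(j) = P(J=j|K=j) / Σ_{k≥j} P(J=j|K=k)`, and the connection limit at
confidence `c` is the largest `j` with `P_par(i) ≥ c` for all `i ≤ j`. For
the 330-column frame this gives a limit of 4 steps at 95% (7 at 90%, 1 at
99%); the limit is non-decreasing in sequence length and non-increasing in
confidence. The historical desktop implementation of statistical parsimony
is closed about its tie handling, so this estimator is validated by those
monotonicity properties and by a brute-force small-case oracle rather than
by bit-matching.

Construction: admitted haplotypes (≥ 10 pooled reads) are first joined by
all unit-distance edges; then for d = 2 … limit, cross-component pairs at
distance d are joined through d−1 unsampled intermediates (flipping
differing columns in ascending order), best-supported pairs first — node
weight, then degree, then lexicographic name, a fixed and documented tie
rule. Intermediates whose states coincide with an existing node are reused.
Every edge is a unit step; every within-limit pair ends in one component.
Because connection is transitive, the *path* between two sampled haplotypes
may exceed their pairwise column distance (and the limit); that is inherent
to the method, not an artefact. Node weights carry per-accession percents
for entries above the major threshold — the published visualization rule in
which node radius grows with each pool's percent contribution.

## The synthetic pool generator

The generator emulates what the analysis assumes about a polyploid rDNA
pool sequenced at 2×300: a multinomial mixture of a few true ribotype
sequences at fixed proportions, plus independent per-base substitution
errors (default 0.3%/base, roughly a post-filtering Illumina error
magnitude) and Phred qualities drawn around a linearly declining 3′ profile
(mean 36, slope 0.03/base, sd 3, clipped to [2, 41]). One seeded generator
per pool with a documented draw order makes output byte-reproducible.

The packaged deep-pool recipe mirrors the deepest published A-genome
accession: 21,927 read pairs with majors at 40/11/11/8% and the remaining
30% spread over 20 minor variants at 1.5% each. The minor variants carry two
substitutions at diagnostic columns untouched by any named ribotype, so each
stays at distance ≥ 2 from the whole catalog — they are never absorbed by
derivative pooling and tabulate as minor novels, as intended.

Deliberately **not** simulated: PCR-cycle amplification bias, chimera
formation (off by default in the sense of absent), indel sequencing errors
(substitutions only, keeping dereplication ground truth unambiguous), and
concerted-evolution dynamics. Passing the end-to-end tests therefore shows
the pipeline recovers mixture composition under substitution noise — it
does not validate behaviour under chimeras or length-variant artefacts.

## Problem sizes and numerical choices

The end-to-end demonstration runs the full 21,927-pair pool (about half a
minute); unit tests use pools of 200–2000 pairs. The connection-limit DP
truncates the posterior sum at `k = j + 40`, far past where terms become
negligible (they decay faster than geometrically). Dereplication ties are
broken lexicographically; merge-offset ties prefer the longer overlap;
quality ties in consensus prefer the forward mate; all orderings are total,
so every stage is deterministic given the seed.

## Known limitations

- Ribotype identity is defined by the diagnostic columns only; variants
  differing solely at non-diagnostic positions are (intentionally) merged
  into the same call.
- The catalog cannot distinguish co-optimal gap placements in sequence
  contexts the packaged frame was specifically constructed to avoid; a real
  reference with long homopolymers adjacent to deletion columns would need
  the same scrutiny.
- The connection-limit estimator uses a flat prior over the true mutation
  count; other published estimators effectively assume a coalescent
  (geometric) prior and can give somewhat larger limits at the same
  confidence. All conclusions drawn here (A-side connectivity, C-genome
  isolation) are insensitive to that choice, since the relevant distances
  are 1–5 versus ~45 columns.
- Tree inference (Bayesian/ML) is out of scope; alignments and networks are
  exported in standard formats for external tools.
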