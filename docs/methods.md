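# Methods

## Model

The classifier treats each target as the set of canonical k-mers that
occur in it and nowhere else. Let S_t be target t's k-spectrum support
(canonical k-mers, k ≤ 32, 2-bit packed, canonical = min of forward and
reverse-complement code so that one lookup per window covers both
strands). The *discriminative* set is

    D_t = S_t \ ⋃_{u≠t} S_u

with one carve-out: for a declared chromosome-arm pair (L, S) with
centromere pseudo-target C, any k-mer whose owner set is exactly {L, S}
is moved to D_C instead of being dropped. Reassignment is decided before
the multi-target drop and the minimum-occurrence filter is applied after
discriminative filtering, so a rare arm-shared k-mer can still be removed
by the occurrence filter but never silently returned to an arm.

An object o with valid windows w_1 … w_n scores h_t = |{i : canon(w_i) ∈
D_t}| (repeated k-mers count once per window — the hit count is a window
count, not a set size). Assignment goes to argmax_t h_t; the confidence
score is h1/(h1+h2) over the two largest counts. Since the D_t are
pairwise disjoint, an object composed entirely of one target's sequence
can accumulate hits for that target only; this is what licenses the
express mode's first-hit rule.

## Parameters

- **k** (default 31, max 32): larger k raises precision and confidence
  at the cost of sensitivity to sequencing errors (one substitution
  invalidates up to k windows); smaller k raises sensitivity but admits
  chance matches. 19–22 favours sensitivity, ≥ 27 favours precision.
- **min_occurrence** (default 1): drop discriminative k-mers seen fewer
  times than this across all targets. Useful (≥ 2) when targets are raw
  reads, where singleton k-mers are mostly sequencing errors.
- **high-confidence threshold** (default 0.75, strict `>`): splits
  assignments into high/low confidence for reporting and post-filtering.
- **sampling**: `half` keeps the even ranks of each target's code-sorted
  discriminative list. Rank parity in a sorted order was chosen over
  "every other hash bucket" because it is deterministic, reproducible
  across machines, and balanced per target. `light_stride` (k = 27
  fixed) keeps k-mers whose start positions in the original target
  sequences are multiples of 135 — i.e. keep one 27-mer window, skip the
  next four non-overlapping ones, a 5× reduction. The stride is applied
  to positions, then the sample is intersected with the discriminative
  set, so a sampled k-mer that is common between targets stays excluded.
- **default-mode early stop**: querying stops once one target has
  collected ceil(n/2) hits where n counts *all* valid windows of the
  object, not only those queried so far; with the half index this bound
  is rarely reached by a wrong target first.

## Tie and degenerate-input rules

h1 = h2 > 0 from different targets: assign the smallest target id, flag
`tie`, confidence 0.5 (the score's lower bound — ties are assigned, not
dropped). h1 = 0 or an object shorter than k: `UNASSIGNED`, confidence
undefined. Express mode never measures h2, so it reports no confidence.
Windows containing any non-ACGT character are skipped whole (no IUPAC
expansion); lower case is accepted and U reads as T. Paired-end mates are
classified independently.

## Synthetic data

`make_community` draws i.i.d. uniform ACGT genomes and plants shared
blocks: block j of each recipient genome is placed uniformly inside bin
j (genome partitioned into one bin per block), which guarantees
non-overlap without rejection sampling. With `block_divergence` > 0 each
copy is independently substituted at that per-base rate, modelling
homologous-but-diverged sequence (paralogs, related species) rather than
verbatim duplication. `sample_reads` draws source genome and position
uniformly on the forward strand — canonical matching makes the classifier
strand-blind, which the suite verifies directly by reverse-complementing
reads — and applies independent per-base substitutions to a uniformly
chosen different base. No indels are simulated, so truth positions stay
exact; for an exact-k-mer classifier an indel behaves like a substitution
anyway (it invalidates the windows covering it).

What this emulates and what it does not: uniform random genomes have
essentially no repeat structure, so cross-target k-mer collisions are
rare at k ≥ 15 unless planted; real pangenomes share far more sequence.
Passing tests therefore demonstrate the correctness of the machinery
(counting, filtering, scoring, modes, formats) and the qualitative
behaviour of the confidence score, not field accuracy on real taxa. The
noisy-community experiment (7 × 30 kb genomes, five 2.5-kb blocks at 3%
divergence copied into three genomes each, one genome held out of the
index, 100-bp reads at 10% substitution error, k = 21) was designed to
reproduce the regime where confidence carries signal: reads from the
held-out "novel" genome can only hit its diverged relatives, producing
low-confidence and incorrect assignments, while unique-region reads from
indexed genomes score confidence 1.0. A back-of-envelope Poisson
calculation (≈ 0.53² × 0.47 of a novel-block read's 80 windows match one
relative's variant, × 0.9²¹ ≈ 0.11 chance of being error-free, ≈ 1.2
expected hits per relative) predicts a mix of near-ties and sparse wrong
hits for novel reads, hence mean confidence and high-confidence precision
above overall precision; these parameters were fixed from that
calculation.

## Numerical and format choices

K-mer extraction is a rolling 2-bit update (O(1) per window for both
strands) with the run-length reset on invalid characters. The index file
is a small custom binary layout (magic, version, k, sampling,
min-occurrence, a SHA-256 parameter digest, label/sequence/arm tables,
then code-sorted fixed-width records): round trips are bit-exact, loads
detect truncation by record count, and the digest lets `build` skip a
rebuild when an up-to-date index exists. Results CSVs print confidence
with four decimals and '.' decimal separator so outputs diff cleanly.
FASTA/FASTQ readers are streaming and line-tracked so malformed input is
reported with its line number; gzip is sniffed from magic bytes.
Problem sizes in the test suite and acceptance script (10 × 100 kb
genomes, 10⁴ reads; 50 random oracle instances; 4 × 10³ noisy reads) were
chosen so that every property is exercised at a scale where failure modes
(hash collisions aside — 4³¹ ≫ index size) would be visible while the
whole suite stays interactive.

## Limitations

Exact matching only: no spaced seeds, minimizers or mismatch tolerance,
so sensitivity decays geometrically with error rate at large k. Abundance
estimation, taxonomy-tree reconciliation and quality-aware scoring are
out of scope. The in-memory index is a Python dict of packed integers;
it is compact enough for desk-scale studies but not engineered for
multi-gigabase reference collections. Worker parallelism partitions
objects only; results are independent of worker count by construction.
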