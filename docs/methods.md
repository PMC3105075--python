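# Methods

This note documents the models and procedures implemented in `rumenmt`, the
defaults they ship with, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Conventions

All coordinates are 1-based inclusive (the BLAST convention); the overlap of
a hit spanning `a..b` is `b − a + 1`, and the test suite asserts this
identity. All randomness flows through numpy's PCG64 generator seeded with
explicit integers, so every output is reproducible byte-for-byte; tabular
outputs embed a short hash of the run configuration (excluding the output
path) in a header comment. Report rounding follows the field's reporting
style: gigabases and percents to one decimal, taxon-bin percents as whole
numbers at ≥ 10% and one decimal below, discovery rates as whole genes per
gigabase.

## ncRNA classification and depletion efficiency

A read is non-coding RNA iff (i) it has an alignment hit against the rRNA
database with E ≤ `max_evalue` (default 10⁻⁵) and query overlap ≥
`min_overlap` (default 50 bp), or (ii) it appears in the HMM/tRNA flag list;
the two routes combine by union. The parenthetical bit-score condition
(≥ 52) is treated as a fallback for hits lacking an E-value, not as a
conjunct — requiring both would silently tighten the rule.

Depletion efficiency assumes the original RNA pool was a fraction `c₀`
ncRNA (default 0.95) and that mRNA is fully retained. If a fraction `r` of
ncRNA is removed, the post-depletion ncRNA share is
`f = c₀(1−r) / (c₀(1−r) + (1−c₀))`; inverting,

```
r = 1 − [(1 − c₀)·f] / [c₀·(1 − f)],   clamped to [0, 1].
```

`r` is strictly decreasing in `f`, equals 1 at `f = 0` and 0 at `f = c₀`.
With `f = 0.184`, `c₀ = 0.95`: r ≈ 0.988, i.e. ~99% removal.

## Taxonomic binning

Queries take the taxon of their best significant hit, ordered by bit score
(descending) then E-value (ascending), at the generic significance rule
E ≤ 10⁻⁵. Exact ties go to the lowest common ancestor of the tied subject
taxa rather than to first-in-file order: file order is not reproducible, the
LCA is, and it matches how ambiguous top hits are conventionally resolved.
Aggregation lifts each assignment to its ancestor at the requested rank;
lineages with no node at that rank (including LCAs already coarser than it)
fall into an explicit `other/none` bucket, and hit-less queries into
`unassigned`, so universe percentages always total 100.

## CAZy annotation

The model→family association table distinguishes four provenance routes:

* **A** — families with directly published domain models: used as-is.
* **B** — candidate models screened against family membership. A model is
  accepted for a single family when every significant member hit comes from
  that family and ≥ 80% of the family's members conform to the model.
  When members of several families hit one model, a combined label (sorted,
  "/"-joined, e.g. "CE2/CE3") is accepted only if *every* implicated family
  passes the 80% bar — the conservative reading; mixed coverage is rejected
  as `impure`, uniformly insufficient coverage as `low_coverage`. The
  construction is order-independent by design.
* **C** — families without models: BLAST hits against representative
  sequences, labelled via an explicit representative→family mapping, at the
  same 52-bit cutoff.
* **D** — externally built profiles are consumed as pre-labelled model ids;
  profile training itself (multiple alignment, HMM estimation) is out of
  scope.

Module calling drops hits below 52 bits (boundary inclusive), merges
overlapping *same-label* calls into one span (union of coordinates, maximum
score) so that fragmented hits on a single domain cannot inflate family
counts, and keeps overlapping *distinct-label* calls so genuinely stacked
modules (catalytic + carbohydrate-binding) survive. Merging is idempotent.
A model with no route to a label produces a warning and an `unclassified`
call, counted separately and excluded from architecture analysis.

Architecture analysis restricts to contigs ≥ 500 bp (short contigs
overestimate gene counts); a contig is multi-domain iff it carries at least
two *distinct* labels. Identity bins for top database hits are [0, 50),
[50, 70] and (70, 100] — the published anchors fix only "less than 50" and
"more than 70", so the middle bin is closed on both sides to make the three
bins exhaustive; contigs without a hit are reported separately as `no_hit`.

## Expression and discovery rates

Fold coverage is `read_count × mean_read_len / contig_len` and is linear in
the read count. Total sequence yield uses `n_reads × mean read length` when
only summary inputs are available (the per-record sum is used when records
are in hand). Discovery rate is genes per gigabase, rounded to an integer;
rate ratios are reported to one decimal. Read mapping itself is not
implemented: read→contig origins are an input (the simulator's truth table,
or an external mapper's output), and normalization schemes (RPKM/TPM) are
deliberately absent.

## Comparative GH profiling

Per-sample glycoside-hydrolase family counts are row-normalized to percents
(so the comparison is scale-free), correlated with Pearson's r, and
transformed to the distance d = 1 − r ∈ [0, 2] — the minimal monotone
transform, which leaves the UPGMA topology identical to (1 − r)/2. The
family universe defaults to GH families only; it is a configuration
parameter. UPGMA repeatedly merges the pair of clusters at minimal distance,
with the merged cluster's distance to the rest the size-weighted arithmetic
mean and the merge height d/2 (so cophenetic distance = 2 × node height);
ties break on the lexicographically smallest pair of smallest member ids,
making the tree platform-independent. The implementation is checked against
a brute-force average-of-original-pairs oracle and against scipy's average
linkage on random matrices. The packaged reference profiles
(cellulolytic-like vs oligosaccharide-like) are synthetic stand-ins
constructed in code for demonstrations and planted-cluster tests; no real
genome annotations are shipped.

## Rarefaction

Collector's curves subsample `⌊f·N⌋` reads without replacement at each
effort fraction, replicated with independent seeded permutations. Each
replicate draws one permutation and counts categories by first-occurrence
position, which is equivalent to independent subsampling at every fraction
and makes each replicate's curve non-decreasing by construction; at `f = 1`
the richness equals the total category count with zero spread. The effort
needed for a target richness fraction is linearly interpolated between
evaluated points — no parametric extrapolation (Chao/ACE) is attempted.
The mean at small fractions matches the hypergeometric expectation
`K·(1 − C(N−N/K, n)/C(N, n))` for uniform categories.

## Synthetic data: what it emulates, and what it does not

The generator plants a fully known truth so that zero-noise runs must
reproduce it exactly (the test suite enforces this end to end). Defaults are
the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| read length | 108 nt | short-read mRNA-seq |
| contig length | log-normal, median 310 bp, σ = 0.6 | assembly of a deep run |
| contig GC | 0.379 ± 0.015 | AT-rich eukaryotic coding sequence |
| ncRNA GC | 0.51 | rRNA pool |
| ncRNA fraction | 0.184 | post-depletion share |
| expression weight | log-normal(μ = 3, σ = 1.5) | heavy tail: few contigs capture thousands of reads |
| architectures | ~9% of contigs carry a module; GH6/GH45/GH48 paired with CBM10 | anaerobic-fungal cellulase layout |
| taxa | fungal genera 55%, ciliates 27%, other eukaryotes 8%, bacteria 9%, archaea 1% | rumen-eukaryote-like community |

Reads sample contigs with probability ∝ expression weight × length; ncRNA
reads come from a dedicated rRNA reference pool, never from contigs, so the
ncRNA truth is unambiguous. Hit tables emit one domain hit per planted
module (score ≥ cutoff) with probability 1 − `fn_rate`, decoys at `fp_rate`
with scores/E-values failing the cutoffs in expectation, and rRNA/protein
alignment hits consistent with each read's origin; the rRNA-database subset
is distinguished by an `rrna_` subject-id prefix.

Two generator choices are deliberately tight. Sequences are built from an
exact base multiset matching the drawn GC (shuffled), not i.i.d. draws, and
the per-contig GC spread is a small sd = 0.015: under heavy-tailed
expression weighting the effective number of contigs behind a category mean
is roughly `n·e^{−σ²}` (≈ 30 at n = 300), so a realistic several-point GC
spread would leave read-weighted category means unidentifiable at the 0.5 pp
level the recovery tests require. Consequently passing GC-recovery tests
show the *accounting* is correct, not that category means are separable in
real data, where within-category GC varies far more.

Other real-data features the simulator does not model: sequencing error and
quality scores, paired-end structure, chimeric assembly, strain-level
variation in hit identity, database incompleteness (every coding read finds
a protein hit at zero noise), and correlated search-tool failure modes
(false negatives are independent Bernoulli events). Zero-noise truth
recovery therefore validates the pipeline's logic, not its robustness to
real search output.

## Problem sizes

The default pipeline run uses 2,000 contigs and 100,000 reads; the test
suite's shared community uses 300 contigs and 100,000 reads, with smaller
populations for determinism and error-path checks; the brute-force UPGMA
oracle runs on 100 random matrices of up to 8 leaves. These sizes were
chosen so every statistical check (binomial recovery of the ncRNA fraction,
±0.5 pp GC recovery, Spearman ρ > 0.95 between counts and planted weights)
has comfortable resolving power while the whole suite stays fast.

## Known limitations

* The HMM route of ncRNA identification is consumed as a flag list; no
  covariance/HMM model is implemented.
* Whether a read with a significant E-value but short overlap should count
  when also HMM-flagged is ambiguous in the emulated design; union
  semantics were adopted.
* Step B's acceptance criteria as conventionally stated conflict with the
  existence of combined classes; the all-families-pass-coverage
  reconciliation used here is an interpretation.
* Read-level and contig-level family counts are reported separately and
  never summed, since deduplication across the two is underdetermined.
* The "average sequence coverage" of highly expressed gene sets depends on
  which gene set and which mean is intended; the formula is exposed and no
  particular headline value is asserted.
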