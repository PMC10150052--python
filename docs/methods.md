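# Methods

## The inference problem

A B-cell clone is the set of cells descended from one V(D)J
rearrangement.  Sequencing gives reads that have diverged from their
founder by somatic hypermutation (SHM) anywhere along the sequence, so
clone membership must be inferred from sequence similarity and germline
gene annotations.  Every diversity index downstream — and any biological
claim built on it — inherits the errors of this step.  The package
therefore treats the clone definition as an explicit, swappable modeling
choice and provides the machinery to measure how much results depend on
it.

## Preprocessing

Input is an annotated AIRR Rearrangement TSV (the package does not run
germline alignment; it consumes tables already annotated by an upstream
tool).  The pipeline: keep productive rearrangements; resolve tied
top gene candidates to the alphabetically first (remaining candidates
kept as ranked alternatives); group records with identical junction
strings and keep one representative chosen uniformly at random, carrying
the summed copy number.  Identical junctions are assumed clonally
related — two independent rearrangements essentially never produce the
same junction string — which shrinks the clustering problem and fixes
the junction-only method's partition.  Productive filtering is applied
before collapsing; on productive-only records the two orders commute
(tested).  Records with empty junctions are excluded with a logged
count.  Gene calls are compared at gene level by default (allele
suffixes `*xx` stripped), switchable.

Accuracy against ground truth is always evaluated at the read level:
partitions computed on collapsed representatives are first expanded back
through the collapse map, so that a method is credited (or penalized)
for every read it implicitly assigns.

## Distances

* Normalized Levenshtein, `2·Lev/(|s₁|+|s₂|+Lev)`, on junctions.  The
  unit-cost edit distance comes from edlib; the normalization maps into
  [0, 1] and compensates junction-length differences (two empty strings
  are at distance 0 by continuity).
* tf-idf *k*-mer cosine distance on full sequences truncated to their
  3'-anchored window of *L* nucleotides — anchoring at the 3' end keeps
  the junction region regardless of 5' read loss.  tf is the raw k-mer
  count in the sequence; idf = ln(|S|/df) with df the number of corpus
  sequences containing the k-mer (document frequency; a total-occurrence
  denominator is available as `idf_mode="occurrence"` for sensitivity
  checks).  No smoothing terms: a k-mer present in every sequence
  carries weight exactly 0.  k-mers containing N are skipped.  Zero
  vectors are at cosine distance 1 from nonzero vectors and 0 from each
  other, keeping NaNs out of the linkage.  Defaults k = 7, L = 130.

## Clonal identification

All clustering uses complete-linkage hierarchical agglomerative
clustering (HAC) cut at a distance threshold, so every pair inside a
clone is within the cut height (bounded clone diameter).  scipy's
linkage implementation is used; its tie handling is deterministic, which
is what matters for reproducibility.  The three methods:

1. **junction-only** — equivalence classes of identical junctions; no
   threshold.
2. **vj_junction** — records grouped by (V, J) call; HAC on normalized
   Levenshtein junction distances inside each group.  Clones never span
   gene groups, which is exactly why wrong V calls fragment clones.
3. **alignment_free** — HAC on tf-idf cosine distances over the whole
   repertoire, no gene grouping.  The idf corpus is the repertoire being
   clustered, so the partition of two fixed sequences legitimately
   depends on the rest of the repertoire; negation sequences are
   projected onto this fixed vocabulary without altering it.

**Threshold calibration.**  Default: negation-based.  For each negation
sequence take the distance to its nearest repertoire neighbor (for
vj_junction restricted to same-V/J records, distance 1 if none exist —
mirroring the clustering's group constraint); the threshold is the lower
δ-quantile (order statistic at index ⌈δN⌉, δ = 0.01), so at most ≈ δ of
unrelated sequences fall below it and specificity is ≈ 1 − δ.  The
alternative bimodality-based calibration fits a Gaussian KDE (Silverman
bandwidth) to the within-repertoire nearest-neighbor distances and puts
the threshold at the density minimum between the two highest modes; it
needs at least 50 distances and fails loudly on unimodal densities.
Thresholds are distances throughout; the common "90% CDR3 similarity"
convention corresponds to a distance threshold of 0.1 (the CLI accepts
`--threshold-as-similarity`).

## Diversity

Hill numbers `αD = (Σ pᵢ^α)^{1/(1−α)}` with closed-form limits at
α ∈ {0, 1, ∞} and log-sum-exp evaluation elsewhere for numerical
stability at large α (the α → 1 limit is accurate to ~10⁻⁶ relative
error at |α−1| = 10⁻⁶, tested).  Entropies are in nats.  Clone
abundances default to copy-number weighting (collapsed duplicates count
their multiplicity); representative weighting is available because the
right choice depends on whether duplicate reads are biological or
technical.

Diversity profiles evaluate αD on α = exp(tan(Aπ/2)) for N evenly
spaced A ∈ [−1, 1]; the endpoints map to the exact α → 0 and α → ∞
limits (richness, 1/dominance) rather than evaluating tan(±π/2).

Chao1 uses the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)), defined
even when no doubletons exist.  The coverage-adjusted Shannon estimator
uses C = 1 − f₁/n and p̃ᵢ = C·pᵢ, the standard Chao–Shen construction;
an alternative reading that divides by the coverage (p̃ᵢ = pᵢ/C) is
available as `adjust="inverse"` for sensitivity analysis.  The estimator
is undefined when every clone is a singleton (C = 0) and raises with
guidance rather than returning a number.

Clone-composition summaries split reads among the dominant clone,
expanded clones (abundance ≥ 1%, excluding the dominant) and
non-expanded clones; a clone at exactly 1% counts as expanded (a tie
rule is required at the boundary).

## Partition and ranking agreement

MI between partitions is computed from the contingency table of shared
records; AMI subtracts the exact hypergeometric expectation E{MI} under
random labelings with fixed cluster sizes and normalizes by
max(H(A), H(B)) − E{MI} (scikit-learn's implementation, cross-checked in
the tests against a factorial-enumeration oracle at n = 6 and against
hand-built contingency tables).  Two trivial partitions are identical
and score 1 by convention.

Spearman ρ (average ranks for ties) compares per-sample diversity
values across methods; constant columns are reported as missing with a
warning rather than as a number.  The optimal-α scan evaluates the full
Hill curve per sample on a vectorized grid (default [0, 100] in steps
of 0.01), averages ρ over method pairs, and returns the first argmax —
deterministic on flat curves.

## Robustness experiments

**Subsampling.**  Reads (representatives expanded by copy count) are
drawn without replacement at each ratio; the pipeline is re-run per draw
with the threshold fixed at its full-depth calibration (the draws are
shallower looks at the same sample, not new samples; recalibration is
possible via config).  Reported as fold change against full depth.  The
expected pattern — and what the tests assert — is that α < 1 orders
(richness hardest) collapse at low depth while α > 1 orders and
dominance are nearly unbiased; Chao1's fold change can exceed plain
richness's because it is driven by the unstable singleton count (a
recorded diagnostic, not an invariant).

**V-gene annotation artifacts.**  Removing the first 70 nt of each read
emulates primer designs that lose the 5' V region; since the package
does not re-run germline alignment, the downstream effect is emulated by
injecting V-call corruption: with a configurable rate the primary call
is replaced by a different gene from the pool (truth demoted into the
alternatives), and tied alternative candidates can be added at an
independent rate.  A singleton of the gene-restricted method is a
*potential false negative* when some combination of its top-6 V and J
candidates places its junction within the clustering threshold of an
existing clone with that gene pair; the fraction such singletons that a
second (alignment-free) partition already marks non-singleton is the
rescue fraction.

## The simulator

`simulate_repertoire` draws, per clone, a founder of layout
[V stub | junction | J stub] — one fixed random stub per germline gene
and simulation (shared with the negation set, as germline genes are
individual-independent), a fresh junction of 30–60 nt unique across
founders — and grows a lineage as a uniform random recursive tree (or a
star), applying independent per-site substitutions at `shm_rate` on
every edge, in junction and framework alike.  Unrelated singleton
founders are added to a target fraction; negation sequences are founders
from an independent stream whose junctions are rejection-sampled against
the repertoire.  Defaults: 200 clones, power-law sizes (zipf exponent 2,
minimum 2, cap 100), singleton fraction 0.3, shm_rate 0.01, V stub
210 nt / J stub 40 nt (so L = 130 retains the junction), 200 negation
sequences.  The clone-size exponent is a free choice; it produces the
heavy-tailed size spectrum typical of repertoires without reproducing
any particular dataset.

What the simulator does *not* emulate: SHM hotspot motifs and
transition bias, indels (off by default; Levenshtein normalization
anticipates them when enabled), selection, class switching, sequencing
error, primer bias, and real germline allele diversity.  Passing tests
therefore demonstrate correctness of the algorithms and the direction
and rough magnitude of method effects under idealized clonal structure —
not performance figures transferable to experimental data.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations of roughly 10²–10³
reads, 10-seed replications for ordering claims, 30 subsampling
repetitions, and held-out negation sets of 200 — sizes chosen so the
statistical claims are stable under the fixed seeds while the whole
analysis remains a desk-scale computation.  Other numerical choices:
distances clipped to [0, 1] after floating-point cosine; KDE grid of 512
points; quantile rule is the lower order statistic (never interpolated),
so calibrated thresholds are always observed distances.

## Known limitations

* Clone definitions are heavy-chain only; paired-chain and isotype
  information are out of scope.
* No probabilistic lineage-based clone inference; the three methods are
  deliberately the simple, widely used ones being evaluated.
* The alignment-free method's corpus dependence means partitions are not
  stable under repertoire composition changes — a property of the
  method, surfaced rather than hidden.
* Chao estimators are reported without confidence intervals.
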