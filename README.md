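# clonediv

Clonal identification and diversity analysis of B-cell receptor (BCR)
repertoires.

B cells descended from a common ancestor — a *clone* — share a V(D)J
rearrangement but diverge through somatic hypermutation, so grouping
sequenced receptors into clones is an inference problem, and every
downstream diversity statement depends on how it is solved.  `clonediv`
implements three widely used clone definitions side by side, quantifies
clonal diversity in Hill's unified framework, and provides the agreement
and robustness analyses needed to judge how much a biological conclusion
depends on the choice of method.

## What it computes

**Clonal identification** (all three consume an annotated AIRR
Rearrangement TSV and emit a sequence→clone partition):

* **Junction-only** — same clone ⟺ identical CDR3 junction string.
* **VJ & junction** — same V and J gene call, then complete-linkage
  hierarchical clustering of junctions under the normalized Levenshtein
  distance `2·Lev(s₁,s₂)/(|s₁|+|s₂|+Lev(s₁,s₂))`, cut at a calibrated
  threshold.
* **Alignment-free** — sequences truncated to their last *L* = 130 nt,
  embedded as tf-idf weighted *k*-mer vectors (*k* = 7,
  idf = ln(|S|/df)), clustered by cosine distance with the same
  complete-linkage rule — no germline gene assignment needed.

Distance thresholds are calibrated from *negation sequences* (reads from
unrelated individuals, which cannot be clonally related): the threshold
is the lower δ-quantile (δ = 1% by default) of their nearest-neighbor
distances to the repertoire, giving specificity ≈ 1 − δ.  A
bimodality-based alternative locates the valley of the within-repertoire
nearest-neighbor distance density.

**Diversity** of the resulting clone abundances p₁…p_S:

* Hill numbers `αD = (Σ pᵢ^α)^{1/(1−α)}`, covering richness (⁰D),
  Shannon (¹D = e^H), Simpson (λ = 1/²D) and dominance (p_max = 1/∞D);
  evenness E(a,b) = aD/bD; diversity profiles on the
  α = exp(tan(Aπ/2)) grid, A ∈ [−1, 1].
* Bias-corrected estimators for incomplete sampling: Chao1 richness
  `S_obs + f₁(f₁−1)/(2(f₂+1))` and the Chao–Shen coverage-adjusted
  Shannon entropy.

**Comparison & robustness**: adjusted mutual information between
partitions (exact hypergeometric chance correction), Spearman rank
agreement of diversity across methods with a scan for the optimal Hill
order α, read-depth subsampling fold-change analysis, and a
false-negative analysis of singletons under ambiguous or wrong V-gene
calls.  A ground-truth simulator (clonal lineage trees with tunable
hypermutation, singletons, negation sequences, annotation corruption)
makes every analysis testable without external data.

## Worked example

```python
from clonediv import (SimulationConfig, simulate_repertoire, simulate_negation_set,
                      collapse_identical_junctions, identify_clones,
                      adjusted_mutual_information, truth_partition,
                      abundance_from_partition, diversity_table)

cfg = SimulationConfig(n_clones=100, shm_rate=0.01, seed=42)
repertoire, truth = simulate_repertoire(cfg)
negation = simulate_negation_set(cfg, repertoire)
collapsed = collapse_identical_junctions(repertoire, seed=42)
print(f"{len(repertoire)} reads, {len(collapsed)} unique junctions")

clones = identify_clones(collapsed, "vj_junction", negation=negation)
print(f"threshold = {clones.threshold:.3f}, {clones.n_clones} clones")

ami = adjusted_mutual_information(clones.expand(collapsed.collapse_map),
                                  truth_partition(truth))
print(f"AMI vs ground truth = {ami:.3f}")

ab = abundance_from_partition(clones, collapsed)
for name, value in diversity_table(ab).items():
    print(f"{name:>12}: {value:.3f}")
```

prints

```
426 reads, 292 unique junctions
threshold = 0.395, 226 clones
AMI vs ground truth = 0.990
    richness: 226.000
     shannon: 5.102
     simpson: 0.011
   dominance: 0.059
    evenness: 0.728
      hill_0: 226.000
      hill_1: 164.425
      hill_2: 94.224
       chao1: 336.915
chao_shannon: 5.640
```

426 simulated reads collapse to 292 distinct junctions.  The negation
set calibrates a junction-distance threshold of 0.395; complete-linkage
clustering inside V/J groups yields 226 clones whose read-level
partition agrees with the simulated ground truth at AMI 0.990.  The
clone abundances give an effective Shannon diversity of e^5.10 ≈ 164
equally-common clones, a dominant clone holding 5.9% of reads, and a
Chao1 estimate that ~111 clones were missed at this depth.

The same three workflows are available from a shell via the `clonediv`
command (`simulate`, `cluster`, `diversity`, `compare`, `subsample`,
`truncate`, `alpha-scan`, `report`); every subcommand reads and writes
plain TSV/JSON.

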