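"""Clonal diversity under Hill's unified framework.

The Hill number of order α of an abundance vector p is

    αD = (Σᵢ pᵢ^α)^{1/(1−α)},          1 ≤ αD ≤ S,

an "effective number of clones": α < 1 favors rare clones, α > 1 common
ones.  Classical indices are special cases — richness ⁰D = S, Shannon
¹D = exp(H), Simpson λ = 1/²D, dominance p_max = 1/∞D — and the evenness
E(a,b) = aD/bD measures abundance homogeneity.  A diversity *profile*
evaluates αD on a grid α = exp(tan(A·π/2)) for A ∈ [−1, 1], compressing
the whole α ∈ [0, ∞] axis (richness through dominance) into a finite
vector.

For incomplete samples, the bias-corrected Chao1 estimator extrapolates
richness from singleton/doubleton counts (f₁, f₂), and the Chao–Shen
coverage-adjusted estimator corrects the plug-in Shannon entropy.
Entropies are in nats throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "AbundanceVector",
    "abundance_from_partition",
    "hill_diversity",
    "shannon_entropy",
    "simpson_index",
    "dominance",
    "richness",
    "evenness",
    "DiversityProfile",
    "diversity_profile",
    "chao1_richness",
    "chao_shannon",
    "clonal_composition_summary",
    "diversity_table",
]


@dataclass
class AbundanceVector:
    """Clone abundances: integer counts and the relative abundances they induce."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size == 0:
            raise ValueError("abundance vector must have at least one clone")
        if (self.counts < 1).any():
            raise ValueError("all clone counts must be >= 1")

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        """Relative abundances, summing to 1."""
        return self.counts / self.counts.sum()

    @property
    def S_obs(self) -> int:
        """Observed number of clones."""
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        """Number of singleton clones (count exactly 1)."""
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        """Number of doubleton clones (count exactly 2)."""
        return int((self.counts == 2).sum())


def abundance_from_partition(partition, rep, weight: str = "copy_counts") -> AbundanceVector:
    """Clone abundance vector induced by a partition of a repertoire.

    ``weight="representatives"`` counts one unit per record;
    ``weight="copy_counts"`` (default) weights records by their copy
    number, so collapsed duplicate reads contribute their multiplicity.
    """
    if len(partition) == 0:
        raise ValueError("empty partition")
    count_of = {r.id: (r.count if weight == "copy_counts" else 1) for r in rep.records}
    if weight not in ("copy_counts", "representatives"):
        raise ValueError(f"unknown weighting {weight!r}")
    totals: dict[str, int] = {}
    for rid, label in partition.assignment.items():
        if rid not in count_of:
            raise ValueError(f"partition id {rid!r} not present in repertoire")
        totals[label] = totals.get(label, 0) + count_of[rid]
    return AbundanceVector(counts=np.array(list(totals.values())))


def hill_diversity(ab: AbundanceVector, alpha: float) -> float:
    """Hill number αD = (Σ pᵢ^α)^{1/(1−α)} with its closed-form limits.

    α = 0 → richness S; α = 1 → exp(H); α = ∞ → 1/p_max.  Evaluated in
    log space (log-sum-exp) for numerical stability at large α.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = ab.p
    if alpha == 0:
        return float(ab.S_obs)
    if math.isinf(alpha):
        return float(1.0 / p.max())
    if alpha == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    logp = np.log(p)
    return float(np.exp(logsumexp(alpha * logp) / (1.0 - alpha)))


def shannon_entropy(ab: AbundanceVector) -> float:
    """Plug-in Shannon entropy H = −Σ pᵢ ln pᵢ (nats)."""
    p = ab.p
    return float(-(p * np.log(p)).sum())


def simpson_index(ab: AbundanceVector) -> float:
    """Simpson index λ = Σ pᵢ² = 1/²D: probability two random picks share a clone."""
    p = ab.p
    return float((p * p).sum())


def dominance(ab: AbundanceVector) -> float:
    """Relative abundance of the most abundant clone, p_max = 1/∞D."""
    return float(ab.p.max())


def richness(ab: AbundanceVector) -> int:
    """Observed clone count, ⁰D."""
    return ab.S_obs


def evenness(ab: AbundanceVector, a: float = 1.0, b: float = 0.0) -> float:
    """Evenness E(a,b) = aD / bD with a > b ≥ 0; bounded by 1/S ≤ E ≤ 1.

    The default E(1,0) = exp(H)/S is the common choice; E(2,1) is
    preferred for small samples.
    """
    if not a > b:
        raise ValueError("evenness requires a > b")
    if b < 0:
        raise ValueError("evenness requires b >= 0")
    return hill_diversity(ab, a) / hill_diversity(ab, b)


@dataclass
class DiversityProfile:
    """Hill diversity profile on the exp-tan transformed grid."""

    A_grid: np.ndarray          # N points in [-1, 1]
    alpha_grid: np.ndarray      # alpha = exp(tan(A*pi/2)); endpoints are 0 and inf
    values: np.ndarray          # corresponding Hill numbers


def diversity_profile(ab: AbundanceVector, N: int = 101) -> DiversityProfile:
    """Evaluate αD on α = exp(tan(A·π/2)) for N evenly spaced A in [−1, 1].

    The endpoints A = ∓1 map to the exact α → 0 and α → ∞ limits (richness
    and 1/dominance) rather than evaluating tan(±π/2).
    """
    if N < 3:
        raise ValueError("profile needs at least 3 grid points")
    A = np.linspace(-1.0, 1.0, N)
    alpha = np.empty(N)
    alpha[0], alpha[-1] = 0.0, np.inf
    alpha[1:-1] = np.exp(np.tan(A[1:-1] * np.pi / 2.0))
    values = np.array([hill_diversity(ab, a) for a in alpha])
    return DiversityProfile(A_grid=A, alpha_grid=alpha, values=values)


def chao1_richness(ab: AbundanceVector) -> float:
    """Bias-corrected Chao1 richness: S_obs + f₁(f₁−1) / (2(f₂+1)) ≥ S_obs."""
    return ab.S_obs + ab.f1 * (ab.f1 - 1) / (2.0 * (ab.f2 + 1))


def chao_shannon(ab: AbundanceVector, adjust: str = "standard") -> float:
    """Chao–Shen coverage-adjusted Shannon entropy (nats).

    The sample coverage C = 1 − f₁/n discounts abundances for unseen
    clones (p̃ᵢ = C·pᵢ) and each term is inflated by the probability that
    clone i appears in a sample of size n:

        H_Chao = Σᵢ −p̃ᵢ ln p̃ᵢ / (1 − (1 − p̃ᵢ)ⁿ).

    ``adjust="inverse"`` applies p̃ᵢ = pᵢ/C instead (an alternative
    reading of the coverage adjustment, for sensitivity checks).
    Undefined when every clone is a singleton (C = 0).
    """
    n = ab.n
    C = 1.0 - ab.f1 / n
    if C <= 0.0:
        raise ValueError(
            "Chao–Shen entropy undefined: all clones are singletons (coverage 0); "
            "collect deeper sequencing or use the plug-in entropy"
        )
    if adjust == "standard":
        pt = C * ab.p
    elif adjust == "inverse":
        pt = np.minimum(ab.p / C, 1.0)
    else:
        raise ValueError(f"unknown adjust {adjust!r}")
    terms = -pt * np.log(pt)
    denom = 1.0 - (1.0 - pt) ** n
    # p̃ = 1 (single clone): the term is 0 and the denominator 1 - 0^n = 1
    with np.errstate(invalid="ignore"):
        vals = np.where(denom > 0, terms / np.where(denom > 0, denom, 1.0), 0.0)
    return float(vals.sum())


def clonal_composition_summary(ab: AbundanceVector) -> dict[str, float]:
    """Fractions of sequences in the dominant clone, expanded clones
    (abundance ≥ 1%, excluding the dominant one) and non-expanded clones.

    The 1% boundary is inclusive on the expanded side.  Fractions sum to 1.
    """
    p = ab.p
    imax = int(np.argmax(p))
    dom = float(p[imax])
    mask = np.ones(p.size, dtype=bool)
    mask[imax] = False
    expanded = float(p[mask][p[mask] >= 0.01].sum())
    return {
        "dominant": dom,
        "expanded": expanded,
        "non_expanded": float(1.0 - dom - expanded),
    }


def diversity_table(ab: AbundanceVector, alphas=(0.0, 1.0, 2.0),
                    chao: bool = True) -> dict[str, float]:
    """All standard indices of one abundance vector as a flat mapping."""
    out: dict[str, float] = {
        "richness": float(richness(ab)),
        "shannon": shannon_entropy(ab),
        "simpson": simpson_index(ab),
        "dominance": dominance(ab),
        "evenness": evenness(ab),
    }
    for a in alphas:
        out[f"hill_{a:g}"] = hill_diversity(ab, a)
    if chao:
        out["chao1"] = chao1_richness(ab)
        try:
            out["chao_shannon"] = chao_shannon(ab)
        except ValueError:
            out["chao_shannon"] = float("nan")
    return out
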