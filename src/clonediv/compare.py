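"""Agreement between clonal partitions and between diversity rankings.

Partitions are compared by mutual information computed from the
contingency table of shared records, and by its chance-corrected form

    AMI(A,B) = (MI − E{MI}) / (max(H(A), H(B)) − E{MI}),

where E{MI} is the exact expectation of MI under the permutation
(hypergeometric) model with fixed cluster sizes: AMI is 1 for identical
partitions (up to relabeling) and ≈ 0 for independent ones.  Diversity
rankings across samples are compared with Spearman's ρ, including a scan
over the Hill order α for the value that maximizes cross-method rank
agreement.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.metrics import adjusted_mutual_info_score, mutual_info_score

from .clustering import ClonalPartition
from .diversity import AbundanceVector

__all__ = [
    "aligned_labels",
    "contingency_table",
    "mutual_information",
    "adjusted_mutual_information",
    "expected_mutual_information",
    "singleton_labels",
    "singleton_agreement",
    "spearman_rank_agreement",
    "optimal_alpha_scan",
]


def aligned_labels(A: ClonalPartition, B: ClonalPartition) -> tuple[list, list]:
    """Label vectors of two partitions aligned on their common record universe."""
    if set(A.assignment) != set(B.assignment):
        raise ValueError("partitions cover different record universes")
    ids = sorted(A.assignment)
    return [A.assignment[i] for i in ids], [B.assignment[i] for i in ids]


def contingency_table(A: ClonalPartition, B: ClonalPartition) -> np.ndarray:
    """Counts of records shared by each pair of clones (rows: A, cols: B)."""
    la, lb = aligned_labels(A, B)
    return pd.crosstab(pd.Series(la), pd.Series(lb)).to_numpy()


def mutual_information(A: ClonalPartition, B: ClonalPartition) -> float:
    """MI between two partitions from their contingency table (nats)."""
    la, lb = aligned_labels(A, B)
    return float(mutual_info_score(la, lb))


def expected_mutual_information(A: ClonalPartition, B: ClonalPartition) -> float:
    """Exact E{MI} under random labelings with the two partitions' fixed
    cluster sizes (hypergeometric model)."""
    from sklearn.metrics.cluster import expected_mutual_information as _emi

    c = contingency_table(A, B)
    return float(_emi(c.astype(np.int64), int(c.sum())))


def adjusted_mutual_information(A: ClonalPartition, B: ClonalPartition) -> float:
    """Chance-corrected MI, normalized by max(H(A), H(B)) − E{MI}.

    Two trivial partitions (both single-cluster, or both all-singletons)
    are identical and score 1 by convention.
    """
    la, lb = aligned_labels(A, B)
    return float(adjusted_mutual_info_score(la, lb, average_method="max"))


def singleton_labels(partition: ClonalPartition) -> dict[str, str]:
    """Classify each record as ``singleton`` (clone of size 1) or ``non_singleton``."""
    sizes = partition.sizes()
    return {
        rid: ("singleton" if sizes[label] == 1 else "non_singleton")
        for rid, label in partition.assignment.items()
    }


def singleton_agreement(A: ClonalPartition, B: ClonalPartition) -> float:
    """Fraction of records on which two partitions agree about singleton status."""
    la = singleton_labels(A)
    lb = singleton_labels(B)
    if set(la) != set(lb):
        raise ValueError("partitions cover different record universes")
    return float(np.mean([la[i] == lb[i] for i in la]))


def spearman_rank_agreement(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman ρ between methods' per-sample diversity values.

    ``values`` is a samples × methods table.  Ties receive average ranks.
    A method with constant values across samples has no defined ranking:
    its correlations are reported as NaN with a warning.
    """
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples to rank")
    methods = list(values.columns)
    const = [m for m in methods if np.ptp(values[m].to_numpy()) == 0]
    if const:
        warnings.warn(f"constant diversity values for method(s) {const}; "
                      "Spearman undefined there", stacklevel=2)
    ranks = values.rank(axis=0, method="average")
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            if a in const or b in const:
                rho = np.nan
            else:
                ra, rb = ranks[a].to_numpy(), ranks[b].to_numpy()
                with np.errstate(invalid="ignore"):
                    rho = float(np.corrcoef(ra, rb)[0, 1])
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def _hill_curve(ab: AbundanceVector, alphas: np.ndarray) -> np.ndarray:
    """Vectorized Hill numbers over a grid of α values (α=1 via its limit)."""
    logp = np.log(ab.p)
    out = np.empty(len(alphas))
    near_one = np.isclose(alphas, 1.0)
    a = alphas[~near_one]
    if a.size:
        lse = logsumexp(np.outer(a, logp), axis=1)
        out[~near_one] = np.exp(lse / (1.0 - a))
    if near_one.any():
        out[near_one] = np.exp(-(np.exp(logp) * logp).sum())
    return out


def optimal_alpha_scan(
    samples: Mapping[str, Sequence[AbundanceVector]],
    alpha_min: float = 0.0,
    alpha_max: float = 100.0,
    step: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Scan the Hill order α for maximal cross-method rank agreement.

    ``samples`` maps each clonal-identification method to its per-sample
    abundance vectors (same sample order everywhere).  For every α on the
    grid the per-sample Hill numbers are computed for each method, the
    Spearman ρ is taken for every method pair and averaged.  Returns the
    first-argmax α and the full (α, mean ρ) curve.
    """
    methods = list(samples)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    n_samples = len(samples[methods[0]])
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if any(len(samples[m]) != n_samples for m in methods):
        raise ValueError("methods must cover the same samples")
    alphas = np.arange(alpha_min, alpha_max + step / 2.0, step)
    # per method: matrix (n_samples, n_alphas) of Hill values -> ranks
    rank_mats = {}
    for m in methods:
        vals = np.vstack([_hill_curve(ab, alphas) for ab in samples[m]])
        rank_mats[m] = rankdata(vals, axis=0)
    mean_rho = np.zeros(len(alphas))
    n_pairs = 0
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            ra, rb = rank_mats[a], rank_mats[b]
            ra_c = ra - ra.mean(axis=0)
            rb_c = rb - rb.mean(axis=0)
            denom = np.sqrt((ra_c ** 2).sum(axis=0) * (rb_c ** 2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.where(denom > 0, (ra_c * rb_c).sum(axis=0) / denom, np.nan)
            mean_rho += np.nan_to_num(rho, nan=0.0)
            n_pairs += 1
    mean_rho /= n_pairs
    curve = pd.DataFrame({"alpha": alphas, "mean_spearman": mean_rho})
    alpha_opt = float(alphas[int(np.argmax(mean_rho))])
    return alpha_opt, curve
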