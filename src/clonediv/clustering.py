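"""Clonal identification: three clustering methods plus threshold calibration.

Clonally related B cells descend from one founder and diverge by somatic
hypermutation, so their receptors are similar but rarely identical.  Three
operational clone definitions are implemented, each as a scikit-learn
style estimator over a :class:`~clonediv.records.Repertoire`:

* :class:`JunctionOnlyClonotyper` — same clone iff identical CDR3 junction.
* :class:`VJJunctionClonotyper` — same V and J gene, then complete-linkage
  hierarchical agglomerative clustering (HAC) of the normalized
  Levenshtein distances between junctions, cut at a distance threshold.
* :class:`AlignmentFreeClonotyper` — tf-idf k-mer vectors of the
  3'-truncated full sequences, cosine distances, complete-linkage HAC over
  the whole repertoire (no gene grouping, hence robust to bad V calls).

The distance threshold is calibrated either from *negation sequences*
(reads from unrelated individuals, assumed clonally unrelated: the
threshold is the lower δ-quantile of their nearest-neighbor distances to
the repertoire, giving specificity ≈ 1−δ) or from the valley between the
two modes of the within-repertoire nearest-neighbor distance distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .metrics import cosine_distance_matrix, normalized_levenshtein, tfidf_matrix
from .records import NegationSet, Repertoire

__all__ = [
    "ClonalPartition",
    "ThresholdCalibration",
    "CalibrationError",
    "calibrate_threshold_negation",
    "calibrate_threshold_bimodal",
    "JunctionOnlyClonotyper",
    "VJJunctionClonotyper",
    "AlignmentFreeClonotyper",
    "cluster_junction_only",
    "cluster_vj_junction",
    "cluster_alignment_free",
    "identify_clones",
]


class CalibrationError(RuntimeError):
    """Threshold calibration could not be performed."""


@dataclass
class ClonalPartition:
    """Assignment of every repertoire record to a clone label.

    Labels are opaque; only the induced set partition is meaningful.
    """

    assignment: dict[str, str]
    method: str
    threshold: Optional[float]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.assignment)

    def labels_for(self, ids) -> list[str]:
        return [self.assignment[i] for i in ids]

    @property
    def clones(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, label in self.assignment.items():
            out.setdefault(label, []).append(rid)
        return out

    @property
    def n_clones(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> dict[str, int]:
        return {label: len(members) for label, members in self.clones.items()}

    def expand(self, collapse_map: dict[str, list[str]]) -> "ClonalPartition":
        """Propagate each representative's clone label to its collapsed members.

        Identical-junction members are clonally related by assumption, so a
        partition computed on collapsed representatives induces one on the
        original reads.  Comparisons against ground truth are made at the
        read level through this expansion.
        """
        assignment: dict[str, str] = {}
        for rid, label in self.assignment.items():
            for member in collapse_map.get(rid, [rid]):
                assignment[member] = label
        return ClonalPartition(assignment=assignment, method=self.method,
                               threshold=self.threshold, params=dict(self.params))

    def restrict(self, ids) -> "ClonalPartition":
        """Partition restricted to a subset of record ids (e.g. after collapsing)."""
        missing = [i for i in ids if i not in self.assignment]
        if missing:
            raise KeyError(f"ids not in partition: {missing[:5]}")
        return ClonalPartition(
            assignment={i: self.assignment[i] for i in ids},
            method=self.method,
            threshold=self.threshold,
            params=dict(self.params),
        )


@dataclass
class ThresholdCalibration:
    """Calibrated clustering threshold plus the distance distributions behind it."""

    threshold: float
    method: str  # "negation" or "bimodal"
    delta: Optional[float] = None
    negation_nn_distances: np.ndarray = field(default_factory=lambda: np.array([]))
    within_nn_distances: np.ndarray = field(default_factory=lambda: np.array([]))


def _vj_groups(rep: Repertoire) -> dict[tuple[str, str], list[int]]:
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(rep.records):
        groups.setdefault((r.v_call, r.j_call), []).append(i)
    return groups


def _quantile_threshold(nn: np.ndarray, delta: float) -> float:
    """Lower empirical quantile: order statistic at 1-based index ceil(δ·N)."""
    order = np.sort(nn)
    idx = max(math.ceil(delta * len(order)), 1) - 1
    return float(order[idx])


def calibrate_threshold_negation(
    rep: Repertoire,
    neg: NegationSet,
    metric: str = "normalized_levenshtein",
    delta: float = 0.01,
    k: int = 7,
    L: int = 130,
) -> ThresholdCalibration:
    """Negation-based threshold: lower δ-quantile of negation nearest-neighbor distances.

    For each negation sequence the distance to its nearest neighbor in the
    repertoire is computed — for the gene-restricted metric only among
    records with the same V and J call (no counterpart → distance 1); for
    the cosine metric over the whole repertoire, with negation sequences
    projected onto the repertoire's tf-idf vocabulary so that the corpus
    statistics are not perturbed.  At the returned threshold, at most a
    fraction ≈ δ of clonally unrelated sequences would be merged.
    """
    if len(neg) == 0:
        raise CalibrationError("negation set is empty")
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    if metric == "normalized_levenshtein":
        groups = _vj_groups(rep)
        junctions = rep.junctions
        nn = np.ones(len(neg))
        any_counterpart = False
        for a, nrec in enumerate(neg):
            idxs = groups.get((nrec.v_call, nrec.j_call))
            if not idxs:
                continue
            any_counterpart = True
            nn[a] = min(normalized_levenshtein(nrec.junction, junctions[i]) for i in idxs)
        if not any_counterpart:
            raise CalibrationError(
                "no negation sequence has a same-V/J counterpart in the repertoire; "
                "consider the alignment-free (cosine) metric"
            )
    elif metric == "cosine":
        X, vocab, idf = tfidf_matrix([r.sequence for r in rep.records], k=k, L=L)
        Y, _, _ = tfidf_matrix([r.sequence for r in neg], k=k, L=L,
                               vocabulary=vocab, idf=idf)
        nn = cosine_distance_matrix(Y, X).min(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return ThresholdCalibration(
        threshold=_quantile_threshold(nn, delta),
        method="negation",
        delta=delta,
        negation_nn_distances=nn,
    )


def _within_nn_distances(rep: Repertoire, metric: str, k: int, L: int) -> np.ndarray:
    if metric == "normalized_levenshtein":
        groups = _vj_groups(rep)
        junctions = rep.junctions
        out = []
        for idxs in groups.values():
            if len(idxs) < 2:
                continue
            for i in idxs:
                out.append(min(normalized_levenshtein(junctions[i], junctions[j])
                               for j in idxs if j != i))
        return np.asarray(out)
    if metric == "cosine":
        X, _, _ = tfidf_matrix([r.sequence for r in rep.records], k=k, L=L)
        D = cosine_distance_matrix(X)
        np.fill_diagonal(D, np.inf)
        return D.min(axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def calibrate_threshold_bimodal(
    rep: Repertoire,
    metric: str = "normalized_levenshtein",
    k: int = 7,
    L: int = 130,
    grid_size: int = 512,
) -> ThresholdCalibration:
    """Bimodality-based threshold: valley of the within-repertoire
    nearest-neighbor distance density.

    The nearest-neighbor distance distribution of a repertoire mixes a
    low-distance mode (clonal relatives) and a high-distance mode
    (unrelated sequences / singletons).  A Gaussian kernel density
    (Silverman bandwidth) is fit and the threshold is placed at the density
    minimum between the two highest modes.  Fails on unimodal densities.
    """
    from scipy.stats import gaussian_kde

    nn = _within_nn_distances(rep, metric, k, L)
    if len(nn) < 50:
        raise CalibrationError(
            f"need >= 50 within-repertoire nearest-neighbor distances, got {len(nn)}"
        )
    if np.ptp(nn) == 0:
        raise CalibrationError("nearest-neighbor distances are constant (single mode); "
                               "use the negation method")
    kde = gaussian_kde(nn, bw_method="silverman")
    xs = np.linspace(nn.min(), nn.max(), grid_size)
    dens = kde(xs)
    interior = np.arange(1, grid_size - 1)
    maxima = interior[(dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    # include boundary modes
    if dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [grid_size - 1]])
    if len(maxima) < 2:
        raise CalibrationError("density is unimodal; use the negation method")
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    lo, hi = sorted(int(i) for i in top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return ThresholdCalibration(
        threshold=float(xs[valley]),
        method="bimodal",
        within_nn_distances=nn,
    )


def _complete_linkage_labels(D: np.ndarray, threshold: float) -> np.ndarray:
    """Cut a complete-linkage dendrogram so merges happen at height <= threshold."""
    n = D.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(squareform(D, checks=False), method="complete")
    return fcluster(Z, t=threshold, criterion="distance")


class BaseClonotyper(BaseEstimator):
    """Base class for clonal identification estimators.

    Subclasses implement ``_cluster`` and expose after :meth:`fit`:

    ``labels_`` — clone label per record, aligned with the repertoire order;
    ``partition_`` — the full :class:`ClonalPartition`;
    ``threshold_`` — the distance cut used (``None`` for junction-only);
    ``calibration_`` — the :class:`ThresholdCalibration` if one was run.
    """

    method_name = "base"

    def fit(self, repertoire: Repertoire, negation: Optional[NegationSet] = None):
        if len(repertoire) == 0:
            raise ValueError("cannot cluster an empty repertoire")
        self.calibration_ = None
        labels = self._cluster(repertoire, negation)
        self.labels_ = np.asarray(labels, dtype=object)
        self.partition_ = ClonalPartition(
            assignment=dict(zip(repertoire.ids, self.labels_)),
            method=self.method_name,
            threshold=getattr(self, "threshold_", None),
            params=self.get_params(),
        )
        return self

    def fit_predict(self, repertoire: Repertoire, negation: Optional[NegationSet] = None):
        return self.fit(repertoire, negation).labels_

    def _cluster(self, repertoire, negation):  # pragma: no cover - abstract
        raise NotImplementedError


class JunctionOnlyClonotyper(BaseClonotyper):
    """Clones are equivalence classes of identical junction strings.

    Simple and threshold-free, but splits lineages whose junctions carry
    somatic hypermutations, inflating diversity.
    """

    method_name = "junction_only"

    def _cluster(self, repertoire, negation):
        del negation
        self.threshold_ = None
        label_of: dict[str, str] = {}
        labels = []
        for r in repertoire.records:
            if r.junction not in label_of:
                label_of[r.junction] = f"jo{len(label_of)}"
            labels.append(label_of[r.junction])
        return labels


class VJJunctionClonotyper(BaseClonotyper):
    """Same V and J gene, junction distance below a threshold (complete linkage).

    Records are grouped by their (V, J) gene assignment; inside each group
    a complete-linkage HAC of pairwise normalized Levenshtein junction
    distances is cut at ``threshold``, so every pair inside a clone is
    within the cut height.  Clones never span gene groups.

    ``threshold=None`` triggers calibration at fit time: negation-based
    (requires a negation set; tolerance ``delta``) or bimodality-based.
    """

    method_name = "vj_junction"

    def __init__(self, threshold: Optional[float] = None, delta: float = 0.01,
                 calibration: str = "negation"):
        self.threshold = threshold
        self.delta = delta
        self.calibration = calibration

    def _resolve_threshold(self, repertoire, negation, metric, **kw):
        if self.threshold is not None:
            if not (0.0 <= self.threshold <= 1.0):
                raise ValueError("threshold must lie in [0, 1]")
            return float(self.threshold)
        if self.calibration == "negation":
            if negation is None:
                raise CalibrationError("negation calibration requires a negation set")
            cal = calibrate_threshold_negation(repertoire, negation, metric=metric,
                                               delta=self.delta, **kw)
        elif self.calibration == "bimodal":
            cal = calibrate_threshold_bimodal(repertoire, metric=metric, **kw)
        else:
            raise ValueError(f"unknown calibration {self.calibration!r}")
        self.calibration_ = cal
        return cal.threshold

    def _cluster(self, repertoire, negation):
        self.threshold_ = self._resolve_threshold(repertoire, negation,
                                                  metric="normalized_levenshtein")
        junctions = repertoire.junctions
        labels = [""] * len(repertoire)
        for (v, j), idxs in _vj_groups(repertoire).items():
            m = len(idxs)
            D = np.zeros((m, m))
            for a in range(m):
                for b in range(a + 1, m):
                    D[a, b] = D[b, a] = normalized_levenshtein(
                        junctions[idxs[a]], junctions[idxs[b]])
            flat = _complete_linkage_labels(D, self.threshold_)
            for pos, c in zip(idxs, flat):
                labels[pos] = f"{v}|{j}|{c}"
        return labels


class AlignmentFreeClonotyper(BaseClonotyper):
    """Gene-assignment-free clustering of tf-idf k-mer cosine distances.

    Full sequences are 3'-truncated to ``L`` nucleotides, embedded as
    tf-idf weighted k-mer vectors (corpus = the repertoire being
    clustered), and complete-linkage HAC over the cosine distance matrix
    is cut at ``threshold`` — over the whole repertoire, with no V/J
    pre-grouping.  Because idf weights are corpus-dependent, the partition
    of two given sequences can change when the rest of the repertoire
    changes.
    """

    method_name = "alignment_free"

    def __init__(self, threshold: Optional[float] = None, k: int = 7, L: int = 130,
                 delta: float = 0.01, calibration: str = "negation",
                 idf_mode: str = "document"):
        self.threshold = threshold
        self.k = k
        self.L = L
        self.delta = delta
        self.calibration = calibration
        self.idf_mode = idf_mode

    def _cluster(self, repertoire, negation):
        if self.threshold is not None:
            if not (0.0 <= self.threshold <= 1.0):
                raise ValueError("threshold must lie in [0, 1]")
            self.threshold_ = float(self.threshold)
        elif self.calibration == "negation":
            if negation is None:
                raise CalibrationError("negation calibration requires a negation set")
            cal = calibrate_threshold_negation(repertoire, negation, metric="cosine",
                                               delta=self.delta, k=self.k, L=self.L)
            self.calibration_ = cal
            self.threshold_ = cal.threshold
        elif self.calibration == "bimodal":
            cal = calibrate_threshold_bimodal(repertoire, metric="cosine",
                                              k=self.k, L=self.L)
            self.calibration_ = cal
            self.threshold_ = cal.threshold
        else:
            raise ValueError(f"unknown calibration {self.calibration!r}")
        X, _, _ = tfidf_matrix([r.sequence for r in repertoire.records],
                               k=self.k, L=self.L, idf_mode=self.idf_mode)
        D = cosine_distance_matrix(X)
        flat = _complete_linkage_labels(D, self.threshold_)
        return [f"af{c}" for c in flat]


def cluster_junction_only(rep: Repertoire) -> ClonalPartition:
    return JunctionOnlyClonotyper().fit(rep).partition_


def cluster_vj_junction(rep: Repertoire, threshold: float) -> ClonalPartition:
    return VJJunctionClonotyper(threshold=threshold).fit(rep).partition_


def cluster_alignment_free(rep: Repertoire, threshold: float,
                           k: int = 7, L: int = 130) -> ClonalPartition:
    return AlignmentFreeClonotyper(threshold=threshold, k=k, L=L).fit(rep).partition_


_METHODS = {
    "junction_only": JunctionOnlyClonotyper,
    "vj_junction": VJJunctionClonotyper,
    "alignment_free": AlignmentFreeClonotyper,
}


def identify_clones(rep: Repertoire, method: str,
                    negation: Optional[NegationSet] = None, **config) -> ClonalPartition:
    """Dispatch wrapper: build the estimator for ``method``, fit, return the partition."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    est = _METHODS[method](**config)
    return est.fit(rep, negation=negation).partition_
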