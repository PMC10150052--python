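"""Pairwise sequence distances.

Two metrics drive clonal identification:

* **Normalized Levenshtein distance** between junctions,
  ``2·Lev(s1,s2) / (|s1| + |s2| + Lev(s1,s2))``, which maps the unit-cost
  edit distance into ``[0, 1]`` while compensating for length differences.
* **Cosine distance between tf-idf weighted k-mer vectors** of the (3'
  anchored, length-``L`` truncated) full sequences — the alignment-free
  route that needs no germline gene assignment.

The idf weight of a k-mer is ``ln(|S| / df)`` with ``df`` the number of
corpus sequences containing the k-mer (natural log, no smoothing), so a
k-mer present in every sequence carries weight exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from scipy import sparse

__all__ = [
    "normalized_levenshtein",
    "levenshtein",
    "truncate_3prime",
    "tfidf_matrix",
    "tfidf_vectorize",
    "KmerVector",
    "DistanceMatrix",
    "cosine_distance",
    "cosine_distance_matrix",
    "pairwise_distances",
]


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    return edlib.align(s1, s2, task="distance")["editDistance"]


def normalized_levenshtein(s1: str, s2: str) -> float:
    """Length-normalized edit distance in ``[0, 1]``; 0 iff the strings are equal."""
    lev = levenshtein(s1, s2)
    denom = len(s1) + len(s2) + lev
    if denom == 0:  # both empty
        return 0.0
    return 2.0 * lev / denom


def truncate_3prime(seq: str, L: int) -> str:
    """Keep the last ``L`` nucleotides (3'-anchored window); shorter sequences whole.

    Anchoring at the 3' end retains the junction region, which sits toward
    the 3' end of a V(D)J read.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return seq[-L:] if len(seq) > L else seq


@dataclass
class KmerVector:
    """tf-idf weighted k-mer vector of one sequence over a shared corpus vocabulary."""

    kmer_index: dict[str, int]
    weights: sparse.csr_matrix  # shape (1, vocabulary size)
    k: int
    L: int

    def toarray(self) -> np.ndarray:
        return np.asarray(self.weights.todense()).ravel()


def _kmers(seq: str, k: int) -> list[str]:
    # k-mers containing N are skipped: ambiguous bases carry no identity
    return [seq[i:i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i:i + k]]


def tfidf_matrix(
    sequences: Sequence[str],
    k: int = 7,
    L: int = 130,
    idf_mode: str = "document",
    vocabulary: Optional[dict[str, int]] = None,
    idf: Optional[np.ndarray] = None,
):
    """tf-idf k-mer matrix of a corpus of nucleotide sequences.

    Each sequence is reduced to its 3'-anchored window of length ``L`` and
    decomposed into overlapping k-mers.  ``tf`` is the raw count in the
    sequence; ``idf = ln(|S| / df)`` with ``df`` the number of sequences
    containing the k-mer (``idf_mode="document"``) or the total occurrence
    count across the corpus (``idf_mode="occurrence"``).

    When ``vocabulary`` and ``idf`` are given, the corpus statistics are
    taken as fixed and only term frequencies are computed (used to project
    negation sequences onto a repertoire's vocabulary without altering it).

    Returns ``(X, vocabulary, idf)`` with ``X`` a CSR matrix of shape
    ``(n_sequences, vocabulary size)``.
    """
    if not sequences:
        raise ValueError("empty corpus")
    if k < 1:
        raise ValueError("k must be >= 1")
    if L < k:
        raise ValueError("L must be >= k")
    truncated = [truncate_3prime(s.upper(), L) for s in sequences]
    fit_vocab = vocabulary is None
    if fit_vocab:
        vocabulary = {}
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    df_counts: dict[int, int] = {}
    occ_counts: dict[int, int] = {}
    for seq in truncated:
        row: dict[int, int] = {}
        for kmer in _kmers(seq, k):
            if fit_vocab:
                idx = vocabulary.setdefault(kmer, len(vocabulary))
            else:
                idx = vocabulary.get(kmer)
                if idx is None:
                    continue
            row[idx] = row.get(idx, 0) + 1
        for idx, tf in row.items():
            indices.append(idx)
            data.append(tf)
            df_counts[idx] = df_counts.get(idx, 0) + 1
            occ_counts[idx] = occ_counts.get(idx, 0) + tf
        indptr.append(len(indices))
    if fit_vocab and not vocabulary:
        raise ValueError(f"empty vocabulary: no sequence contains a {k}-mer")
    n_features = len(vocabulary)
    X = sparse.csr_matrix(
        (np.asarray(data, dtype=float), np.asarray(indices), np.asarray(indptr)),
        shape=(len(truncated), n_features),
    )
    if idf is None:
        n_docs = len(truncated)
        counts = df_counts if idf_mode == "document" else occ_counts
        idf = np.zeros(n_features)
        for idx, c in counts.items():
            idf[idx] = np.log(n_docs / c)
    X = X.multiply(idf).tocsr()
    return X, vocabulary, idf


def tfidf_vectorize(sequences: Sequence[str], k: int = 7, L: int = 130,
                    idf_mode: str = "document") -> list[KmerVector]:
    """Vectorize a corpus; returns one :class:`KmerVector` per sequence."""
    X, vocab, _ = tfidf_matrix(sequences, k=k, L=L, idf_mode=idf_mode)
    return [KmerVector(kmer_index=vocab, weights=X.getrow(i), k=k, L=L)
            for i in range(X.shape[0])]


def cosine_distance(a, b) -> float:
    """Cosine distance ``1 − a·b / (‖a‖‖b‖)`` with a zero-vector convention.

    A zero vector is at distance 1 from any nonzero vector and at distance
    0 from another zero vector (keeps NaNs out of clustering).
    """
    va = a.toarray() if isinstance(a, KmerVector) else np.asarray(a, dtype=float).ravel()
    vb = b.toarray() if isinstance(b, KmerVector) else np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 and nb == 0.0:
        return 0.0
    if na == 0.0 or nb == 0.0:
        return 1.0
    d = 1.0 - float(np.dot(va, vb)) / (na * nb)
    return float(min(max(d, 0.0), 1.0))


def cosine_distance_matrix(X, Y=None) -> np.ndarray:
    """Dense cosine-distance matrix between sparse row matrices, applying
    the same zero-vector convention as :func:`cosine_distance`."""
    from sklearn.metrics.pairwise import cosine_distances

    symmetric = Y is None
    if symmetric:
        Y = X
    D = cosine_distances(X, Y)
    zx = np.asarray(X.multiply(X).sum(axis=1)).ravel() == 0
    zy = np.asarray(Y.multiply(Y).sum(axis=1)).ravel() == 0
    if zx.any() or zy.any():
        D[zx, :] = 1.0
        D[:, zy] = 1.0
        D[np.ix_(zx, zy)] = 0.0
    np.clip(D, 0.0, 1.0, out=D)
    if symmetric:
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    return D


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over repertoire records."""

    ids: list[str]
    values: np.ndarray
    metric: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_distances(rep, metric: str = "normalized_levenshtein",
                       k: int = 7, L: int = 130) -> DistanceMatrix:
    """Full pairwise distance matrix over a repertoire.

    ``normalized_levenshtein`` compares junctions; ``cosine`` compares
    tf-idf k-mer vectors of the 3'-truncated full sequences (the corpus is
    the repertoire itself).
    """
    ids = rep.ids
    n = len(ids)
    if metric == "normalized_levenshtein":
        junctions = rep.junctions
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = normalized_levenshtein(junctions[i], junctions[j])
    elif metric == "cosine":
        X, _, _ = tfidf_matrix([r.sequence for r in rep.records], k=k, L=L)
        D = cosine_distance_matrix(X)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=ids, values=D, metric=metric)
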