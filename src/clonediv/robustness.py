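"""Sensitivity experiments: sequencing depth and V-gene annotation quality.

Two questions are addressed.  First, how do diversity estimates react to
reduced sequencing depth?  Reads are subsampled without replacement at a
range of ratios, the full pipeline (clustering, abundances, indices) is
re-run per draw, and the fold change against the full-depth value is
recorded — rare-clone-sensitive orders (α < 1) degrade, common-clone
orders (α > 1) barely move.  Second, how does losing the 5' end of the V
region (and the wrong or ambiguous V-gene calls it causes) corrupt
gene-restricted clonal identification?  Singletons whose alternative V/J
annotations would place them inside an existing clone are flagged as
*potential false negatives*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClonalPartition, identify_clones
from .diversity import (AbundanceVector, abundance_from_partition, chao1_richness,
                        chao_shannon, hill_diversity)
from .records import NegationSet, Repertoire, record_with
from .metrics import normalized_levenshtein

__all__ = [
    "SubsamplingResult",
    "subsample_records",
    "subsample_analysis",
    "truncate_v_region",
    "ambiguous_call_rate",
    "FalseNegativeReport",
    "false_negative_singletons",
    "mismatch_rate_vs_reference",
]

logger = logging.getLogger(__name__)


@dataclass
class SubsamplingResult:
    """Per-ratio index values and fold changes against full depth."""

    ratios: list[float]
    repetitions: int
    full_depth: dict[str, float]
    values: pd.DataFrame        # columns: ratio, repetition, index, value
    fold_changes: pd.DataFrame  # columns: ratio, index, mean, std

    def fold_change(self, ratio: float, index: str) -> tuple[float, float]:
        row = self.fold_changes[
            (self.fold_changes["ratio"] == ratio) & (self.fold_changes["index"] == index)
        ]
        if row.empty:
            raise KeyError(f"no fold change recorded for ratio={ratio}, index={index}")
        return float(row["mean"].iloc[0]), float(row["std"].iloc[0])


def subsample_records(rep: Repertoire, ratio: float, rng: np.random.Generator) -> Repertoire:
    """Draw a fraction of reads without replacement.

    Representatives are expanded into their copy counts (reads), a
    hypergeometric draw keeps ``round(ratio * total reads)`` of them, and
    the surviving representatives are rebuilt with their new counts —
    emulating a shallower sequencing run of the same sample.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must lie in (0, 1]")
    if ratio == 1.0:
        return rep
    counts = np.array([r.count for r in rep.records])
    total = counts.sum()
    m = int(round(ratio * total))
    if m < 2:
        raise ValueError(f"ratio {ratio} keeps fewer than 2 reads")
    owner = np.repeat(np.arange(len(counts)), counts)
    kept = rng.choice(owner, size=m, replace=False)
    new_counts = np.bincount(kept, minlength=len(counts))
    records = [record_with(r, count=int(c))
               for r, c in zip(rep.records, new_counts) if c > 0]
    return rep.with_records(records)


def _index_values(ab: AbundanceVector, alphas: Sequence[float],
                  indices: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for a in alphas:
        out[f"hill_{a:g}"] = hill_diversity(ab, a)
    if "chao1" in indices:
        out["chao1"] = chao1_richness(ab)
    if "chao_shannon" in indices:
        try:
            out["chao_shannon"] = chao_shannon(ab)
        except ValueError:
            out["chao_shannon"] = np.nan
    if "dominance" in indices:
        out["dominance"] = 1.0 / hill_diversity(ab, np.inf)
    return out


def subsample_analysis(
    rep: Repertoire,
    method: str = "junction_only",
    ratios: Sequence[float] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
    reps: int = 30,
    seed: int = 0,
    alphas: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
    indices: Sequence[str] = ("chao1", "chao_shannon", "dominance"),
    negation: Optional[NegationSet] = None,
    weight: str = "copy_counts",
    **method_config,
) -> SubsamplingResult:
    """Re-run the full pipeline on shallower draws and report fold changes.

    The clustering threshold is calibrated once at full depth (when the
    method needs one) and reused for every draw, since all draws come from
    the same sample.  Ratios that keep fewer than 2 reads are skipped with
    a warning.  Fold change = index(subsample) / index(full depth).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    full_partition = identify_clones(rep, method, negation=negation, **method_config)
    if full_partition.threshold is not None:
        method_config = {**method_config, "threshold": full_partition.threshold}
    full_ab = abundance_from_partition(full_partition, rep, weight=weight)
    full_vals = _index_values(full_ab, alphas, indices)

    rows = []
    for ratio in ratios:
        for rep_i in range(reps if ratio < 1.0 else 1):
            try:
                sub = subsample_records(rep, ratio, rng)
            except ValueError as exc:
                logger.warning("skipping ratio %s: %s", ratio, exc)
                break
            part = identify_clones(sub, method, negation=negation, **method_config)
            ab = abundance_from_partition(part, sub, weight=weight)
            for name, val in _index_values(ab, alphas, indices).items():
                rows.append({"ratio": ratio, "repetition": rep_i, "index": name,
                             "value": val})
    values = pd.DataFrame(rows)
    fold_rows = []
    for (ratio, name), grp in values.groupby(["ratio", "index"]):
        ref = full_vals[name]
        fc = grp["value"].to_numpy() / ref if ref and np.isfinite(ref) else np.full(len(grp), np.nan)
        fold_rows.append({"ratio": ratio, "index": name,
                          "mean": float(np.nanmean(fc)), "std": float(np.nanstd(fc, ddof=1)) if len(fc) > 1 else 0.0})
    return SubsamplingResult(
        ratios=list(ratios), repetitions=reps, full_depth=full_vals,
        values=values, fold_changes=pd.DataFrame(fold_rows),
    )


def truncate_v_region(rep: Repertoire, n_nt: int = 70) -> Repertoire:
    """Remove the first ``n_nt`` nucleotides (5' end) of every sequence.

    Junctions are untouched.  Records whose whole sequence is consumed are
    dropped with a warning.
    """
    if n_nt < 0:
        raise ValueError("n_nt must be >= 0")
    if n_nt == 0:
        return rep
    kept, dropped = [], 0
    for r in rep.records:
        trimmed = r.sequence[n_nt:]
        if not trimmed:
            dropped += 1
            continue
        kept.append(record_with(r, sequence=trimmed))
    if dropped:
        logger.warning("dropped %d records shorter than %d nt", dropped, n_nt)
    return rep.with_records(kept)


def ambiguous_call_rate(rep: Repertoire) -> tuple[float, float]:
    """Fractions of records with tied top V (resp. J) gene candidates."""
    n = len(rep)
    if n == 0:
        return 0.0, 0.0
    v = sum(1 for r in rep.records if len(r.v_candidates) >= 2) / n
    j = sum(1 for r in rep.records if len(r.j_candidates) >= 2) / n
    return float(v), float(j)


@dataclass
class FalseNegativeReport:
    """Singletons that an alternative V/J annotation would place in an existing clone."""

    n_singletons: int
    n_potential_false_negative: int
    rate: float
    rescue_by_other_method: float = float("nan")
    flagged_ids: list[str] = field(default_factory=list)


def false_negative_singletons(
    partition: ClonalPartition,
    rep: Repertoire,
    threshold: float,
    top_n: int = 6,
    other: Optional[ClonalPartition] = None,
) -> FalseNegativeReport:
    """Probe singletons of a gene-restricted partition for annotation-driven misses.

    For every singleton, each combination of its ``top_n`` ranked V and J
    candidates (beyond the assigned pair) is tried: if under some
    alternative (V, J) the singleton's junction lies within ``threshold``
    (normalized Levenshtein) of a member of an existing clone carrying
    that gene pair, the singleton is a *potential false negative* — its
    isolation may be an artifact of a wrong gene call.  When a second
    partition ``other`` (e.g. alignment-free) is given, the fraction of
    flagged singletons it already classifies as non-singletons is reported
    as the rescue fraction.
    """
    from .compare import singleton_labels

    sizes = partition.sizes()
    by_id = {r.id: r for r in rep.records}
    # clone members per (v, j): junction plus clone label
    members: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for rid, label in partition.assignment.items():
        r = by_id[rid]
        members.setdefault((r.v_call, r.j_call), []).append((r.junction, label))

    singles = [rid for rid, label in partition.assignment.items() if sizes[label] == 1]
    if singles and not any(by_id[rid].v_alternatives or by_id[rid].j_alternatives
                           for rid in singles):
        logger.warning("no alternative annotations available; "
                       "false-negative rate undefined")
        return FalseNegativeReport(n_singletons=len(singles),
                                   n_potential_false_negative=0, rate=float("nan"))

    flagged = []
    for rid in singles:
        r = by_id[rid]
        own_label = partition.assignment[rid]
        v_cands = r.v_candidates[:top_n]
        j_cands = r.j_candidates[:top_n]
        hit = False
        for v, j in product(v_cands, j_cands):
            if (v, j) == (r.v_call, r.j_call):
                continue
            for junction, label in members.get((v, j), ()):
                if label == own_label or sizes[label] < 1:
                    continue
                if normalized_levenshtein(r.junction, junction) <= threshold:
                    hit = True
                    break
            if hit:
                break
        if hit:
            flagged.append(rid)

    rate = len(flagged) / len(singles) if singles else 0.0
    rescue = float("nan")
    if other is not None and flagged:
        other_singletons = singleton_labels(other)
        rescue = float(np.mean([other_singletons[rid] == "non_singleton"
                                for rid in flagged]))
    return FalseNegativeReport(
        n_singletons=len(singles),
        n_potential_false_negative=len(flagged),
        rate=float(rate),
        rescue_by_other_method=rescue,
        flagged_ids=flagged,
    )


def mismatch_rate_vs_reference(annotated: Repertoire, reference: Repertoire) -> float:
    """Fraction of records whose V call differs between two annotation passes."""
    ref = {r.id: r.v_call for r in reference.records}
    if set(r.id for r in annotated.records) != set(ref):
        raise ValueError("the two repertoires cover different record ids")
    n = len(annotated)
    return float(sum(1 for r in annotated.records if r.v_call != ref[r.id]) / n)
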