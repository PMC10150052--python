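"""Ground-truth repertoire simulator.

Generates B-cell repertoires with known clonal structure: each clone
descends from a founder receptor (a fixed per-gene V stub, a random
junction, a fixed J stub), diversified along a lineage tree by somatic
hypermutation (independent per-site substitutions on every tree edge,
hitting junction and non-junction positions alike).  Unrelated singleton
founders are mixed in at a configurable fraction, and *negation
sequences* — founder-style receptors guaranteed clonally unrelated to the
repertoire — are drawn from an independent random stream to emulate reads
from other individuals.  Annotation artifacts of 5'-truncated reads
(tied V-gene candidates, outright wrong V calls) can be injected on top.

The simulator aims at statistical structure — variable junction lengths,
heavy-tailed clone sizes, tunable mutation load — not at reproducing any
particular germline database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .records import NegationSet, Repertoire, SequenceRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_repertoire",
    "simulate_negation_set",
    "inject_annotation_ambiguity",
    "truth_partition",
]

_BASES = np.array(list("ACGT"))


def _default_v_pool() -> tuple[str, ...]:
    return tuple(f"IGHV{f}-{n}" for f in range(1, 7) for n in (2, 11, 23, 34, 69))


def _default_j_pool() -> tuple[str, ...]:
    return tuple(f"IGHJ{n}" for n in range(1, 7))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated repertoire.

    Defaults: 200 clones with power-law sizes (exponent 2, minimum 2,
    capped at 100 members), 30% of records unrelated singletons, per-site
    per-edge hypermutation rate 0.01, junctions of 30-60 nt inside a
    ~300 nt read (V stub 210 nt, J stub 40 nt — so a 130 nt 3'-anchored
    window always retains the junction), and 200 negation sequences.
    """

    n_clones: int = 200
    clone_size_distribution: tuple = ("powerlaw", 2.0)
    clone_sizes: Optional[tuple[int, ...]] = None  # explicit override
    max_clone_size: int = 100
    singleton_fraction: float = 0.3
    shm_rate: float = 0.01
    tree_shape: str = "random"  # "random" recursive tree or "star"
    junction_length_range: tuple[int, int] = (30, 60)
    v_gene_pool: tuple[str, ...] = field(default_factory=_default_v_pool)
    j_gene_pool: tuple[str, ...] = field(default_factory=_default_j_pool)
    v_stub_len: int = 210
    j_stub_len: int = 40
    n_negation: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.singleton_fraction < 1.0):
            raise ValueError("singleton_fraction must lie in [0, 1)")
        if not (0.0 <= self.shm_rate <= 1.0):
            raise ValueError("shm_rate must lie in [0, 1]")
        if not self.v_gene_pool or not self.j_gene_pool:
            raise ValueError("gene pools must be non-empty")
        lo, hi = self.junction_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid junction_length_range")


@dataclass
class GroundTruth:
    """True clone labels and the lineage trees that generated them."""

    assignment: dict[str, str]
    trees: dict[str, list[int]]  # clone label -> parent index per member (-1 = founder)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _gene_stubs(config: SimulationConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Fixed germline stub sequence per gene.

    Drawn from a stream keyed only by the simulation seed, so the
    repertoire and its negation set (reads from "other individuals")
    share the same germline genes, as real donors do.
    """
    rng = np.random.default_rng([config.seed, 1861])
    v = {g: _random_seq(rng, config.v_stub_len) for g in sorted(config.v_gene_pool)}
    j = {g: _random_seq(rng, config.j_stub_len) for g in sorted(config.j_gene_pool)}
    return v, j


def _draw_clone_sizes(rng: np.random.Generator, cfg: SimulationConfig) -> list[int]:
    if cfg.clone_sizes is not None:
        return list(cfg.clone_sizes)
    kind, param = cfg.clone_size_distribution[0], cfg.clone_size_distribution[1]
    sizes = []
    for _ in range(cfg.n_clones):
        if kind == "powerlaw":
            # zipf with minimum clone size 2, capped
            m = 1 + int(rng.zipf(param))
            sizes.append(min(m, cfg.max_clone_size))
        elif kind == "geometric":
            sizes.append(min(1 + int(rng.geometric(param)), cfg.max_clone_size))
        elif kind == "fixed":
            sizes.append(int(param))
        else:
            raise ValueError(f"unknown clone size distribution {kind!r}")
    return sizes


def _fresh_junction(rng, cfg, used: set[str]) -> str:
    lo, hi = cfg.junction_length_range
    for _ in range(1000):
        j = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if j not in used:
            used.add(j)
            return j
    raise RuntimeError("could not draw a fresh junction (range too narrow?)")


def simulate_repertoire(config: SimulationConfig) -> tuple[Repertoire, GroundTruth]:
    """Simulate one repertoire with ground-truth clone labels.

    Clone members are the nodes of a lineage tree grown from the founder
    (uniform random attachment, or a star when ``tree_shape="star"``);
    each edge applies independent per-site substitutions at ``shm_rate``
    to the member's V stub, junction and J stub alike.  Records carry the
    true V/J calls and a ``truth_clone`` label.  Founder junctions are
    rejection-sampled to be unique across clones and singletons, so truth
    labels never collide by chance.
    """
    rng = np.random.default_rng(config.seed)
    v_stubs, j_stubs = _gene_stubs(config)
    sizes = _draw_clone_sizes(rng, config)
    used_junctions: set[str] = set()
    records: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    trees: dict[str, list[int]] = {}

    def make_founder():
        v = config.v_gene_pool[int(rng.integers(len(config.v_gene_pool)))]
        j = config.j_gene_pool[int(rng.integers(len(config.j_gene_pool)))]
        junction = _fresh_junction(rng, config, used_junctions)
        return v, j, (v_stubs[v], junction, j_stubs[j])

    for c, size in enumerate(sizes):
        label = f"clone{c}"
        v, j, founder = make_founder()
        nodes = [founder]
        parents = [-1]
        for i in range(1, size):
            parent = 0 if config.tree_shape == "star" else int(rng.integers(i))
            pv, pj, pjj = nodes[parent]
            nodes.append((
                _mutate(rng, pv, config.shm_rate),
                _mutate(rng, pj, config.shm_rate),
                _mutate(rng, pjj, config.shm_rate),
            ))
            parents.append(parent)
        trees[label] = parents
        for i, (vp, jn, jp) in enumerate(nodes):
            rid = f"{label}_seq{i}"
            records.append(SequenceRecord(
                id=rid, sequence=vp + jn + jp, v_call=v, j_call=j,
                junction=jn, productive=True, truth_clone=label,
            ))
            assignment[rid] = label

    n_clonal = len(records)
    sf = config.singleton_fraction
    n_singletons = int(round(sf / (1.0 - sf) * n_clonal)) if sf > 0 else 0
    for s in range(n_singletons):
        label = f"singleton{s}"
        v, j, (vp, jn, jp) = make_founder()
        rid = f"{label}_seq0"
        records.append(SequenceRecord(
            id=rid, sequence=vp + jn + jp, v_call=v, j_call=j,
            junction=jn, productive=True, truth_clone=label,
        ))
        assignment[rid] = label
        trees[label] = [-1]

    return Repertoire(records=records), GroundTruth(assignment=assignment, trees=trees)


def simulate_negation_set(config: SimulationConfig,
                          repertoire: Optional[Repertoire] = None,
                          stream: int = 0) -> NegationSet:
    """Draw founder-style sequences from an independent random stream.

    Junctions are rejection-sampled against the repertoire's junctions (if
    given), so negation sequences are never string-identical to — and by
    construction clonally unrelated to — the repertoire.  ``stream``
    selects among independent draws (e.g. one set to calibrate a
    threshold, a held-out set to measure its specificity); all streams
    share the simulation's germline stubs.
    """
    rng = np.random.default_rng([config.seed, 7919, stream])
    if config.n_negation == 0:
        return NegationSet(records=[])
    v_stubs, j_stubs = _gene_stubs(config)
    used = set(repertoire.junctions) if repertoire is not None else set()
    records = []
    for i in range(config.n_negation):
        v = config.v_gene_pool[int(rng.integers(len(config.v_gene_pool)))]
        j = config.j_gene_pool[int(rng.integers(len(config.j_gene_pool)))]
        junction = _fresh_junction(rng, config, used)
        records.append(SequenceRecord(
            id=f"neg{i}", sequence=v_stubs[v] + junction + j_stubs[j],
            v_call=v, j_call=j, junction=junction, productive=True,
        ))
    return NegationSet(records=records)


def inject_annotation_ambiguity(rep: Repertoire, v_ambiguous_rate: float = 0.0,
                                corrupt_rate: float = 0.0, seed: int = 0) -> Repertoire:
    """Emulate V-call artifacts of 5'-truncated reads.

    With probability ``v_ambiguous_rate`` a record gains 1-5 tied
    alternative V candidates (the true call stays primary).  With
    probability ``corrupt_rate`` the primary V call is replaced by a
    uniformly drawn *different* gene from the repertoire's pool, the true
    call being demoted into the alternatives.  Truth labels are untouched.
    """
    rng = np.random.default_rng(seed)
    pool = sorted({r.v_call for r in rep.records})
    out = []
    for r in rep.records:
        rec = r
        if v_ambiguous_rate > 0 and rng.random() < v_ambiguous_rate:
            others = [g for g in pool if g != rec.v_call]
            n_alt = min(int(rng.integers(1, 6)), len(others))
            alts = list(rng.choice(others, size=n_alt, replace=False))
            rec = replace(rec, v_alternatives=tuple(alts))
        if corrupt_rate > 0 and rng.random() < corrupt_rate:
            others = [g for g in pool if g != rec.v_call]
            if others:
                wrong = others[int(rng.integers(len(others)))]
                demoted = (rec.v_call,) + tuple(a for a in rec.v_alternatives if a != wrong)
                rec = replace(rec, v_call=wrong, v_alternatives=demoted)
        out.append(rec)
    return rep.with_records(out)


def truth_partition(truth: GroundTruth):
    """Ground-truth labels as a :class:`~clonediv.clustering.ClonalPartition`."""
    from .clustering import ClonalPartition

    return ClonalPartition(assignment=dict(truth.assignment), method="ground_truth",
                           threshold=None, params={})
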