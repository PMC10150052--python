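import numpy as np
import pytest

from clonediv import (
    NegationSet,
    Repertoire,
    SequenceRecord,
    SimulationConfig,
    collapse_identical_junctions,
    filter_productive,
    simulate_negation_set,
    simulate_repertoire,
    truth_partition,
)


def make_record(rid, junction="TGTGCGAGA", v="IGHV1-2", j="IGHJ4",
                sequence=None, productive=True, count=1, **kw):
    if sequence is None:
        sequence = "A" * 40 + junction + "G" * 20
    return SequenceRecord(id=rid, sequence=sequence, v_call=v, j_call=j,
                         junction=junction, productive=productive, count=count, **kw)


def make_repertoire(junctions, v="IGHV1-2", j="IGHJ4", **kw):
    return Repertoire(records=[make_record(f"s{i}", junction=jn, v=v, j=j, **kw)
                               for i, jn in enumerate(junctions)])


@pytest.fixture
def tiny_repertoire():
    return make_repertoire(["TGTGCGAGA", "TGTGCGAGA", "TGTACTTTT"])


@pytest.fixture(scope="session")
def default_sim():
    """One simulation under the study conditions, prepared for clustering."""
    cfg = SimulationConfig(seed=11)
    rep, truth = simulate_repertoire(cfg)
    neg = simulate_negation_set(cfg, rep)
    collapsed = collapse_identical_junctions(filter_productive(rep), seed=11)
    return {
        "config": cfg,
        "repertoire": rep,
        "collapsed": collapsed,
        "truth": truth,
        "truth_partition": truth_partition(truth),
        "negation": neg,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
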