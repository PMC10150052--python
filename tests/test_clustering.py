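import numpy as np
import pytest

from clonediv import (
    AlignmentFreeClonotyper,
    CalibrationError,
    JunctionOnlyClonotyper,
    NegationSet,
    Repertoire,
    VJJunctionClonotyper,
    calibrate_threshold_bimodal,
    calibrate_threshold_negation,
    cluster_junction_only,
    cluster_vj_junction,
    identify_clones,
)
from clonediv.clustering import _complete_linkage_labels, _quantile_threshold

from conftest import make_record, make_repertoire


def partition_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return sorted(map(frozenset, groups.values()), key=lambda s: min(s))


def brute_force_complete_linkage(D, threshold):
    """Independent agglomeration oracle: merge the closest pair of clusters
    under the complete-linkage criterion until the next merge would exceed
    the threshold."""
    clusters = [{i} for i in range(D.shape[0])]
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best_d:
                    best, best_d = (a, b), d
        if best_d > threshold:
            break
        a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(map(frozenset, clusters), key=lambda s: min(s))


class TestJunctionOnly:
    def test_identical_junctions_cocluster(self):
        rep = make_repertoire(["TGTAAA", "TGTAAA", "TGTCCC"])
        part = cluster_junction_only(rep)
        assert sorted(part.sizes().values()) == [1, 2]

    def test_all_distinct_gives_singletons(self):
        rep = make_repertoire(["AAA", "CCC", "GGG"])
        assert cluster_junction_only(rep).n_clones == 3

    def test_consistent_with_collapse(self, default_sim):
        part = cluster_junction_only(default_sim["collapsed"])
        assert all(s == 1 for s in part.sizes().values())

    def test_estimator_api(self, tiny_repertoire):
        est = JunctionOnlyClonotyper()
        labels = est.fit_predict(tiny_repertoire)
        assert len(labels) == 3
        assert est.partition_.method == "junction_only"
        assert est.get_params() == {}


class TestNegationCalibration:
    def test_quantile_is_lowest_order_statistic_at_one_percent(self):
        nn = np.linspace(0.30, 0.50, 100)
        assert _quantile_threshold(nn, 0.01) == pytest.approx(0.30)

    def test_delta_to_zero_bounded_by_minimum(self):
        nn = np.linspace(0.2, 0.9, 50)
        assert _quantile_threshold(nn, 1e-9) <= nn.min()

    def test_identical_distances_give_that_value(self):
        assert _quantile_threshold(np.full(30, 0.42), 0.01) == pytest.approx(0.42)

    def test_empty_negation_set_errors(self, tiny_repertoire):
        with pytest.raises(CalibrationError, match="empty"):
            calibrate_threshold_negation(tiny_repertoire, NegationSet(records=[]))

    def test_no_vj_counterpart_suggests_alignment_free(self):
        rep = make_repertoire(["TGTGCGAGA"], v="IGHV1-2")
        neg = NegationSet(records=[make_record("n0", v="IGHV9-99")])
        with pytest.raises(CalibrationError, match="alignment-free"):
            calibrate_threshold_negation(rep, neg)

    def test_negation_without_counterpart_scores_distance_one(self):
        rep = make_repertoire(["TGTGCGAGA"], v="IGHV1-2")
        neg = NegationSet(records=[
            make_record("n0", junction="TTTTTTTTT", v="IGHV1-2"),
            make_record("n1", v="IGHV9-99"),
        ])
        cal = calibrate_threshold_negation(rep, neg, delta=0.5)
        assert cal.negation_nn_distances[1] == 1.0

    def test_specificity_close_to_one_minus_delta(self, default_sim):
        cal = calibrate_threshold_negation(
            default_sim["collapsed"], default_sim["negation"], delta=0.05)
        nn = cal.negation_nn_distances
        frac_below = float((nn < cal.threshold).mean())
        assert frac_below <= 0.05 + 2 / np.sqrt(len(nn))


class TestBimodalCalibration:
    def _mixture_repertoire(self, rng):
        # two clones of near-identical junctions + unrelated singletons:
        # NN distances mix a tight low mode and a high mode
        base1 = "TGTGCGAGAGGTTACTACTTTGACTACTGG"
        base2 = "TGTGCGAAAGATAGCAGCAGCTGGTACTGG"
        records = []
        for i in range(30):
            b = list(base1 if i % 2 == 0 else base2)
            pos = int(rng.integers(len(b)))
            b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
            records.append(make_record(f"c{i}", junction="".join(b)))
        for i in range(30):
            records.append(make_record(
                f"u{i}", junction="".join(rng.choice(list("ACGT"), size=30))))
        return Repertoire(records=records)

    def test_threshold_lands_in_the_valley(self, rng):
        rep = self._mixture_repertoire(rng)
        cal = calibrate_threshold_bimodal(rep)
        assert 0.1 < cal.threshold < 0.5

    def test_too_few_distances_error(self, tiny_repertoire):
        with pytest.raises(CalibrationError, match=">= 50"):
            calibrate_threshold_bimodal(tiny_repertoire)

    def test_single_tight_mode_fails(self):
        rep = make_repertoire(["TGTGCGAGA"] * 60)
        with pytest.raises(CalibrationError):
            calibrate_threshold_bimodal(rep)

    def test_invariant_under_input_order(self, rng):
        rep = self._mixture_repertoire(rng)
        shuffled = Repertoire(records=rep.records[::-1])
        a = calibrate_threshold_bimodal(rep).threshold
        b = calibrate_threshold_bimodal(shuffled).threshold
        assert a == pytest.approx(b)


class TestVJJunction:
    def test_same_vj_identical_junctions_one_clone(self):
        rep = make_repertoire(["TGTGCGAGA", "TGTGCGAGA"])
        assert cluster_vj_junction(rep, 0.1).n_clones == 1

    def test_different_v_genes_never_merge(self):
        rep = Repertoire(records=[
            make_record("a", v="IGHV1-2"), make_record("b", v="IGHV3-23")])
        assert cluster_vj_junction(rep, 1.0).n_clones == 2

    def test_complete_linkage_three_point_case(self):
        # pairwise distances {0.05, 0.05, 0.30}: the far point stays out
        D = np.array([[0.0, 0.05, 0.05],
                      [0.05, 0.0, 0.30],
                      [0.05, 0.30, 0.0]])
        labels = _complete_linkage_labels(D, 0.1)
        assert len(set(labels)) == 2

    def test_max_intra_clone_distance_bounded_by_threshold(self, default_sim):
        from clonediv.metrics import normalized_levenshtein
        part = cluster_vj_junction(default_sim["collapsed"], 0.2)
        juncs = {r.id: r.junction for r in default_sim["collapsed"]}
        for members in part.clones.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert normalized_levenshtein(juncs[a], juncs[b]) <= 0.2

    def test_matches_brute_force_oracle(self, rng):
        # random continuous distance matrices: agglomeration order is unique
        for _ in range(60):
            n = int(rng.integers(2, 13))
            D = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            D[iu] = rng.random(len(iu[0]))
            D += D.T
            t = float(rng.random())
            got = partition_sets(_complete_linkage_labels(D, t))
            assert got == brute_force_complete_linkage(D, t)

    def test_junction_only_refines_vj_junction(self, default_sim):
        jo = cluster_junction_only(default_sim["collapsed"])
        vjj = cluster_vj_junction(default_sim["collapsed"], 0.15)
        vjj_label = vjj.assignment
        for members in jo.clones.values():
            assert len({vjj_label[m] for m in members}) == 1


class TestAlignmentFree:
    def test_identical_sequences_one_clone(self):
        rep = make_repertoire(["TGTGCGAGA"] * 5)
        part = identify_clones(rep, "alignment_free", threshold=0.05, k=3, L=20)
        assert part.n_clones == 1

    def test_disjoint_kmer_families_never_merge(self):
        rep = Repertoire(records=[
            make_record("a", sequence="A" * 40, junction="AAAA"),
            make_record("b", sequence="C" * 40, junction="CCCC"),
        ])
        part = identify_clones(rep, "alignment_free", threshold=0.99, k=5, L=40)
        assert part.n_clones == 2

    def test_partition_depends_on_corpus(self):
        # idf weights are corpus-dependent: adding sequences can change clusters
        a = make_record("a", sequence="ACGTACGTAAATTTCCCGGG", junction="AAA")
        b = make_record("b", sequence="ACGTACGTAAATTTCCCTTA", junction="CCC")
        extras = [make_record(f"x{i}", sequence="ACGTACGTAAATTT" + "ACGTCA",
                              junction="GGG") for i in range(6)]
        small = Repertoire(records=[a, b])
        big = Repertoire(records=[a, b] + extras)
        t = 0.8  # small corpus: d(a,b)=1 (shared k-mers have idf 0); big: ~0.69
        p_small = identify_clones(small, "alignment_free", threshold=t, k=4, L=20)
        p_big = identify_clones(big, "alignment_free", threshold=t, k=4, L=20)
        same_small = p_small.assignment["a"] == p_small.assignment["b"]
        same_big = p_big.assignment["a"] == p_big.assignment["b"]
        assert same_small != same_big

    def test_ignores_gene_annotations(self, default_sim):
        from clonediv import adjusted_mutual_information, inject_annotation_ambiguity
        rep = default_sim["collapsed"]
        corrupted = inject_annotation_ambiguity(rep, corrupt_rate=1.0, seed=5)
        p1 = identify_clones(rep, "alignment_free", threshold=0.5)
        p2 = identify_clones(corrupted, "alignment_free", threshold=0.5)
        assert adjusted_mutual_information(p1, p2) == pytest.approx(1.0)


class TestIdentifyClones:
    def test_unknown_method_rejected(self, tiny_repertoire):
        with pytest.raises(ValueError, match="unknown method"):
            identify_clones(tiny_repertoire, "nope")

    def test_determinism(self, default_sim):
        a = identify_clones(default_sim["collapsed"], "vj_junction",
                            negation=default_sim["negation"])
        b = identify_clones(default_sim["collapsed"], "vj_junction",
                            negation=default_sim["negation"])
        assert a.assignment == b.assignment

    def test_zero_mutation_recovers_truth_for_all_methods(self):
        from clonediv import (SimulationConfig, adjusted_mutual_information,
                              collapse_identical_junctions, simulate_negation_set,
                              simulate_repertoire, truth_partition)
        cfg = SimulationConfig(n_clones=30, shm_rate=0.0, singleton_fraction=0.2,
                               n_negation=100, seed=3)
        rep, truth = simulate_repertoire(cfg)
        neg = simulate_negation_set(cfg, rep)
        collapsed = collapse_identical_junctions(rep, seed=3)
        tp = truth_partition(truth)
        for method in ("junction_only", "vj_junction", "alignment_free"):
            part = identify_clones(collapsed, method, negation=neg)
            expanded = part.expand(collapsed.collapse_map)
            assert adjusted_mutual_information(expanded, tp) == pytest.approx(1.0)

    def test_provenance_recorded(self, default_sim):
        part = identify_clones(default_sim["collapsed"], "vj_junction",
                               negation=default_sim["negation"], delta=0.02)
        assert part.method == "vj_junction"
        assert part.threshold is not None
        assert part.params["delta"] == 0.02
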