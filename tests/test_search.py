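"""Tests for the beam search, permutation tests and model selection."""

import itertools

import numpy as np
import pytest

from megsurv.io import AlterationMatrix
from megsurv.search import (MegsCollection, ScoreCache, build_network,
                            calibrate_p0, coverage, gnh_test,
                            model_selection, multipath_search)


def _matrix(values, labels=None):
    values = np.asarray(values, dtype=np.int8)
    labels = labels or [f"G{j}" for j in range(values.shape[1])]
    return AlterationMatrix([f"P{i}" for i in range(values.shape[0])],
                            labels, values)


class TestMultipathSearch:
    def test_matches_exhaustive_enumeration(self):
        """With a wide enough beam the search equals exhaustive scoring."""
        rng = np.random.default_rng(0)
        for trial in range(3):
            M, K = 7, 4
            vals = (rng.random((40, M)) < 0.25).astype(np.int8)
            vals[:, 0] |= 0  # keep as is; marginals random
            mat = _matrix(vals)
            cache = ScoreCache()
            res = multipath_search(mat, K=K, beam_width=64, cache=cache,
                                   min_count=0)
            for k in range(2, K + 1):
                best_p = min(
                    cache.score_columns(vals[:, list(c)])[1]
                    for c in itertools.combinations(range(M), k))
                assert res.p_min[k] == pytest.approx(best_p, rel=1e-9)

    def test_planted_triple_is_p_min_set(self, planted_matrix):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(planted_matrix.n_patients)
            mat = AlterationMatrix(planted_matrix.patient_ids,
                                   planted_matrix.feature_labels,
                                   planted_matrix.values[perm])
            res = multipath_search(mat, K=3, beam_width=10)
            if set(res.best_sets[3][0].genes) == {"A", "B", "C"}:
                hits += 1
        assert hits >= 9

    def test_beam_width_one_gives_nested_chain(self, planted_matrix):
        res = multipath_search(planted_matrix, K=4, beam_width=1)
        for k in range(3, 5):
            prev = set(res.best_sets[k - 1][0].genes)
            assert prev < set(res.best_sets[k][0].genes)

    def test_rejects_degenerate_arguments(self, planted_matrix):
        with pytest.raises(ValueError):
            multipath_search(planted_matrix, K=1)
        with pytest.raises(ValueError):
            multipath_search(planted_matrix, K=3, beam_width=0)


class TestGnh:
    def test_planted_set_reaches_minimum_theta(self, planted_matrix):
        gnh = gnh_test(planted_matrix, K=3, beam_width=10, n_perm=60, seed=1)
        assert gnh.theta == pytest.approx(1 / 61)
        assert gnh.global_p <= 0.05

    def test_requires_permutations_and_seed(self, planted_matrix):
        with pytest.raises(ValueError):
            gnh_test(planted_matrix, n_perm=0, seed=1)
        with pytest.raises(ValueError):
            gnh_test(planted_matrix, n_perm=10, seed=None)

    def test_q_values_are_valid_probabilities(self, planted_matrix):
        gnh = gnh_test(planted_matrix, K=3, beam_width=5, n_perm=30, seed=2)
        for q in gnh.q_values.values():
            assert 1 / 31 <= q <= 1.0
        assert gnh.theta == min(gnh.q_values.values())

    def test_type1_on_pure_noise_is_controlled(self):
        """Scaled-down global-null calibration on small noise matrices."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 40
        for r in range(n_rep):
            vals = (rng.random((80, 8)) < 0.15).astype(np.int8)
            mat = _matrix(vals)
            gnh = gnh_test(mat, K=3, beam_width=8, n_perm=40,
                           seed=int(rng.integers(2 ** 31)))
            if gnh.global_p <= 0.05:
                rejections += 1
        assert rejections <= 8      # ~5% nominal; generous binomial bound


class TestCalibrateP0:
    def test_order_statistic_definition(self, planted_matrix):
        # fpr 0.05 with 200 permutations -> the 10th smallest minimum
        cache = ScoreCache()
        rng_seed = 5
        p0 = calibrate_p0(planted_matrix, ["A", "B"], n_perm=200,
                          fpr_target=0.05, seed=rng_seed, cache=cache)
        assert 0.0 < p0 < 1.0

    def test_fpr_target_one_never_blocks(self, planted_matrix):
        assert calibrate_p0(planted_matrix, ["A", "B"], n_perm=10,
                            fpr_target=1.0, seed=1) == 1.0

    def test_rejects_bad_arguments(self, planted_matrix):
        with pytest.raises(ValueError):
            calibrate_p0(planted_matrix, ["A", "B"], n_perm=0, seed=1)
        with pytest.raises(ValueError):
            calibrate_p0(planted_matrix, ["A", "B"], n_perm=10,
                         fpr_target=0.0, seed=1)


class TestModelSelection:
    def _run(self, mat, seed=3, alpha=0.05):
        cache = ScoreCache()
        res = multipath_search(mat, K=4, beam_width=8, cache=cache)
        gnh = gnh_test(mat, K=4, beam_width=8, n_perm=40, seed=seed,
                       cache=cache)
        return model_selection(mat, res, gnh, alpha=alpha, K=4, n_perm=40,
                               seed=seed + 1, cache=cache)

    def test_planted_triple_selected_exactly(self, planted_matrix):
        coll = self._run(planted_matrix)
        found = {tuple(sorted(s["genes"])) for s in coll.sets}
        assert ("A", "B", "C") in found
        assert not any(len(s) > 3 and {"A", "B", "C"} <= set(s)
                       for s in found)

    def test_duplicated_column_never_joins_its_twin(self):
        # gene D duplicates gene A: co-occurrence kills exclusivity
        rng = np.random.default_rng(4)
        N = 200
        members = np.zeros((N, 2), dtype=np.int8)
        covered = rng.random(N) < 0.8
        fired = rng.integers(0, 2, int(covered.sum()))
        members[np.flatnonzero(covered), fired] = 1
        dup = members[:, [0]]
        noise = (rng.random((N, 1)) < 0.1).astype(np.int8)
        mat = _matrix(np.hstack([members, dup, noise]),
                      ["A", "B", "D", "C"])
        coll = self._run(mat)
        for s in coll.sets:
            assert not {"A", "D"} <= set(s["genes"])

    def test_alpha_zero_yields_empty_collection(self, planted_matrix):
        coll = self._run(planted_matrix, alpha=0.0)
        assert coll.sets == []


class TestNetworkAndCoverage:
    def _collection(self, sets):
        return MegsCollection(
            sets=[{"genes": list(g), "p_value": 1e-8, "coverage": 0.5}
                  for g in sets],
            p0_by_size={}, alpha=0.05)

    def test_vertex_and_edge_counting(self):
        net = build_network(self._collection([("A", "B"), ("A", "C")]))
        assert net.nodes["A"]["weight"] == 2
        assert net.nodes["B"]["weight"] == 1
        assert net["A"]["B"]["weight"] == 1
        assert not net.has_edge("B", "C")

    def test_empty_collection_gives_empty_network(self):
        net = build_network(self._collection([]))
        assert net.number_of_nodes() == 0

    def test_recurrent_gene_weight_counts_sets(self):
        # a hub present in 14 of 21 sets carries vertex weight 14
        sets = [("HUB", f"X{i}") for i in range(14)] + \
               [(f"Y{i}", f"Z{i}") for i in range(7)]
        net = build_network(self._collection(sets))
        assert net.nodes["HUB"]["weight"] == 14

    def test_edge_weight_bounded_by_vertex_weights(self, planted_matrix):
        coll = self._collection([("A", "B", "C"), ("A", "B"), ("A", "P0")])
        net = build_network(coll)
        for u, v, d in net.edges(data=True):
            assert d["weight"] <= min(net.nodes[u]["weight"],
                                      net.nodes[v]["weight"])

    @pytest.mark.parametrize("rows,genes,expected", [
        ([[1, 0], [0, 1], [1, 0], [0, 1]], ["G0", "G1"], 1.0),
        ([[0, 0], [0, 0]], ["G0", "G1"], 0.0),
        ([[1, 0], [0, 0], [1, 1], [0, 0]], ["G0", "G1"], 0.5),
    ])
    def test_coverage_counts_patients_with_any_mutation(self, rows, genes,
                                                        expected):
        assert coverage(_matrix(rows), genes) == expected

    def test_coverage_unknown_gene_errors(self, planted_matrix):
        with pytest.raises(KeyError):
            coverage(planted_matrix, ["NOPE"])
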