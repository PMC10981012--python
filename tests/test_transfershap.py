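"""Shapley back-ends, TransferSHAP aggregation and pair comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirtransfer import models as M
from mirtransfer import transfershap as TS
from mirtransfer.records import FeatureTable


class LinearStub:
    """Stand-in TransferModel with analytic source/target predictors."""

    def __init__(self, w_source, w_target):
        self.family = M.ANN
        self.w_s = np.asarray(w_source, float)
        self.w_t = np.asarray(w_target, float)
        self.source_state = {}
        self.transfer_state = {}

    def predict_source(self, X):
        return np.asarray(X, float) @ self.w_s

    def predict(self, X):
        return np.asarray(X, float) @ self.w_t


def table(X, prefix="o"):
    n, m = X.shape
    return FeatureTable.from_arrays(
        X, np.zeros(n, int), [f"f{i}" for i in range(m)],
        ids=[f"{prefix}{i}" for i in range(n)])


def exact_oracle(predict, X, bg):
    """Independent coalition-enumeration oracle (plain loops)."""
    n, m = X.shape
    phi = np.zeros((n, m))
    for i in range(n):
        for k in range(m):
            for subset in itertools.chain.from_iterable(
                    itertools.combinations([j for j in range(m) if j != k], r)
                    for r in range(m)):
                s = len(subset)
                w = (math.factorial(s) * math.factorial(m - s - 1)
                     / math.factorial(m))
                with_k, without_k = [], []
                for b in bg:
                    z1, z0 = b.copy(), b.copy()
                    z1[list(subset) + [k]] = X[i, list(subset) + [k]]
                    z0[list(subset)] = X[i, list(subset)]
                    with_k.append(z1)
                    without_k.append(z0)
                phi[i, k] += w * (predict(np.array(with_k)).mean()
                                  - predict(np.array(without_k)).mean())
    return phi


class TestShapleyMatrix:
    def test_ignored_feature_has_zero_column(self):
        model = LinearStub([1.0, 0.0, 2.0], [1.0, 0.0, 2.0])
        X = np.random.default_rng(0).normal(0, 1, (6, 3))
        phi = TS.shapley_matrix(model, "target", table(X), TS.EXACT_SMALL)
        assert np.allclose(phi.values[:, 1], 0.0, atol=1e-12)

    def test_additive_model_closed_form(self):
        # g(x) = x0 + x1: phi_i = x_i - mean(background x_i)
        model = LinearStub([1.0, 1.0], [1.0, 1.0])
        r = np.random.default_rng(1)
        X = r.normal(0, 1, (5, 2))
        bg = r.normal(0, 1, (20, 2))
        phi = TS.shapley_matrix(model, "target", table(X), TS.EXACT_SMALL,
                                background=bg)
        assert np.allclose(phi.values, X - bg.mean(axis=0), atol=1e-10)

    def test_exact_matches_enumeration_oracle(self):
        model = LinearStub([0.5, -1.0, 2.0], [0.5, -1.0, 2.0])
        r = np.random.default_rng(2)
        X = r.normal(0, 1, (4, 3))
        bg = r.normal(0, 1, (8, 3))
        phi = TS.shapley_matrix(model, "target", table(X), TS.EXACT_SMALL,
                                background=bg)
        oracle = exact_oracle(model.predict, X, bg)
        assert np.allclose(phi.values, oracle, atol=1e-10)

    def test_exact_local_accuracy(self, separable_table):
        cfg = M.AnnConfig(layer_widths=(8, 1), dropout_rates=(0.0,),
                          epochs=20, rng_seed=0)
        small = FeatureTable(separable_table.df.iloc[:50, :].copy())
        mdl = M.train_ann(small, cfg)
        eval_tab = FeatureTable(small.df.iloc[:8].copy())
        phi = TS.shapley_matrix(mdl, "target", eval_tab, TS.EXACT_SMALL)
        out = mdl.predict(eval_tab)
        assert np.allclose(phi.values.sum(axis=1) + phi.base_values, out,
                           atol=1e-6)

    def test_sampling_close_to_exact_on_toy(self):
        class SigmoidStub(LinearStub):
            def predict(self, X):
                return 1 / (1 + np.exp(-super().predict(X)))

            predict_source = predict

        model = SigmoidStub([1.0, -2.0, 0.5, 0.0, 1.5, -0.5],
                            [1.0, -2.0, 0.5, 0.0, 1.5, -0.5])
        r = np.random.default_rng(3)
        X = r.normal(0, 1, (5, 6))
        bg = r.normal(0, 1, (30, 6))
        exact = TS.shapley_matrix(model, "target", table(X), TS.EXACT_SMALL,
                                  background=bg)
        approx = TS.shapley_matrix(model, "target", table(X), TS.SAMPLING,
                                   background=bg, n_permutations=2000,
                                   rng_seed=0)
        assert np.abs(exact.values - approx.values).max() < 0.05

    def test_tree_exact_local_accuracy_in_margin_space(self, separable_table):
        mdl = M.train_xgb(separable_table, num_boost_round=20)
        eval_tab = FeatureTable(separable_table.df.iloc[:10].copy())
        phi = TS.shapley_matrix(mdl, "target", eval_tab, TS.TREE_EXACT)
        margins = np.log(mdl.predict(eval_tab)
                         / (1 - mdl.predict(eval_tab)))
        assert np.allclose(phi.values.sum(axis=1) + phi.base_values,
                           margins, atol=1e-4)

    def test_exact_refuses_too_many_features(self):
        model = LinearStub(np.ones(15), np.ones(15))
        X = np.zeros((2, 15))
        with pytest.raises(ValueError, match="sampling"):
            TS.shapley_matrix(model, "target", table(X), TS.EXACT_SMALL)


def random_matrices(n=5, m=3, seed=0):
    r = np.random.default_rng(seed)
    names = tuple(f"f{i}" for i in range(m))
    obs = tuple(f"o{i}" for i in range(n))
    mk = lambda: TS.ShapleyMatrix(r.normal(0, 1, (n, m)), obs, names,
                                  np.zeros(n))
    return mk(), mk()


class TestTransfershap:
    def test_identity_gives_zero_vector(self):
        a, _ = random_matrices()
        res = TS.transfershap(a, a)
        assert all(v == 0.0 for v in res.importance.values())

    def test_single_cell_difference(self):
        names, obs = ("f0",), ("o0",)
        a = TS.ShapleyMatrix(np.array([[0.2]]), obs, names, np.zeros(1))
        b = TS.ShapleyMatrix(np.array([[0.5]]), obs, names, np.zeros(1))
        res = TS.transfershap(a, b)
        assert res.importance["f0"] == pytest.approx(0.3)

    def test_matches_double_loop_oracle(self):
        a, b = random_matrices(seed=5)
        res = TS.transfershap(a, b)
        for k, f in enumerate(a.feature_names):
            want = sum(abs(b.values[i, k] - a.values[i, k])
                       for i in range(len(a.observation_ids)))
            assert res.importance[f] == pytest.approx(want)

    def test_symmetric_in_magnitude(self):
        a, b = random_matrices(seed=6)
        assert TS.transfershap(a, b).importance \
            == TS.transfershap(b, a).importance

    def test_invariant_to_observation_order(self):
        a, b = random_matrices(seed=7)
        perm = [3, 1, 4, 0, 2]
        ap = TS.ShapleyMatrix(a.values[perm],
                              tuple(a.observation_ids[i] for i in perm),
                              a.feature_names, a.base_values[perm])
        bp = TS.ShapleyMatrix(b.values[perm],
                              tuple(b.observation_ids[i] for i in perm),
                              b.feature_names, b.base_values[perm])
        assert TS.transfershap(a, b).importance \
            == pytest.approx(TS.transfershap(ap, bp).importance)

    def test_scales_linearly(self):
        a, b = random_matrices(seed=8)
        a2 = TS.ShapleyMatrix(3 * a.values, a.observation_ids,
                              a.feature_names, a.base_values)
        b2 = TS.ShapleyMatrix(3 * b.values, b.observation_ids,
                              b.feature_names, b.base_values)
        r1 = TS.transfershap(a, b).importance
        r2 = TS.transfershap(a2, b2).importance
        for f in r1:
            assert r2[f] == pytest.approx(3 * r1[f])

    def test_misaligned_observations_rejected(self):
        a, b = random_matrices()
        bad = TS.ShapleyMatrix(b.values, tuple(f"x{i}" for i in range(5)),
                               b.feature_names, b.base_values)
        with pytest.raises(ValueError, match="observation"):
            TS.transfershap(a, bad)

    def test_constant_vector_normalises_to_zeros_with_warning(self):
        a, _ = random_matrices()
        with pytest.warns(UserWarning, match="constant"):
            res = TS.transfershap(a, a)
        assert set(res.normalized_importance.values()) == {0.0}


def make_result(vec, pair, feats=None):
    feats = feats or [f"f{i}" for i in range(len(vec))]
    v = np.asarray(vec, float)
    lo, hi = v.min(), v.max()
    norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return TS.TransferSHAPResult(dict(zip(feats, v)), dict(zip(feats, norm)),
                                 pair, "xgb")


class TestComparePairs:
    def test_self_correlation_is_one(self):
        a = make_result([1, 2, 3, 4], ("a", "b"))
        b = make_result([4, 1, 2, 3], ("b", "a"))
        corr, _, _ = TS.compare_pairs([a, b, a])
        assert corr.iloc[0, 2] == pytest.approx(1.0)

    def test_monotone_transforms_correlate_perfectly(self):
        base = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        a = make_result(base, ("a", "b"))
        b = make_result(np.exp(3 * base), ("b", "a"))
        corr, _, _ = TS.compare_pairs([a, b])
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_matrix_matches_rank_then_pearson_oracle(self):
        r = np.random.default_rng(10)
        vecs = [r.random(6) for _ in range(4)]
        results = [make_result(v, (f"s{i}", f"t{i}"))
                   for i, v in enumerate(vecs)]
        corr, _, _ = TS.compare_pairs(results)
        for i in range(4):
            for j in range(4):
                ri = rankdata(list(results[i].normalized_importance.values()))
                rj = rankdata(list(results[j].normalized_importance.values()))
                want = np.corrcoef(ri, rj)[0, 1]
                assert corr.iloc[i, j] == pytest.approx(want)

    def test_three_species_give_six_by_six_matrix(self):
        r = np.random.default_rng(11)
        results = [make_result(r.random(5), (s, t))
                   for s in "abc" for t in "abc" if s != t]
        corr, Z, order = TS.compare_pairs(results)
        assert corr.shape == (6, 6)
        assert len(order) == 6
        assert Z.shape == (5, 4)
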