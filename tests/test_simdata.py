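"""Synthetic data generators: determinism, balance, planted structure."""

import io

import numpy as np
import pytest
from scipy import stats

from mirtransfer import duplexseed as dx
from mirtransfer import simdata as sd
from mirtransfer.simdata import (
    GroundTruthRule, SpeciesSpec, make_shifted_rule, simulate_feature_tables,
    simulate_sequences, table_from_sequences,
)


class TestSpeciesSpec:
    @pytest.mark.parametrize("kw", [
        dict(n_mirnas=5, n_positive=3),
        dict(shift=1.5),
        dict(noncanonical_fraction=-0.1),
        dict(utr_length_range=(300, 100)),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            SpeciesSpec("bad", **kw)


class TestSequenceMode:
    def test_counts_and_mirna_usage(self):
        spec = SpeciesSpec("s", n_mirnas=3, n_positive=10, rng_seed=4)
        catalog, utrs, pos = simulate_sequences(spec)
        assert len(catalog) == 3
        assert len(pos) == 10
        assert all(20 <= len(s) <= 24 and set(s) <= set("ACGU")
                   for s in catalog.values())
        assert {p.mirna_id for p in pos} <= set(catalog)

    def test_zero_noncanonical_fraction_forces_canonical(self):
        spec = SpeciesSpec("s", n_mirnas=4, n_positive=15, rng_seed=1,
                           noncanonical_fraction=0.0, shift=0.5)
        _, _, pos = simulate_sequences(spec)
        assert all(p.seed_type == dx.CANONICAL for p in pos)

    def test_every_positive_reclassifies_as_recorded(self):
        spec = SpeciesSpec("s", n_mirnas=5, n_positive=20, rng_seed=2,
                           noncanonical_fraction=0.4)
        catalog, utrs, pos = simulate_sequences(spec)
        for p in pos:
            got = dx.classify_seed(dx.predict_duplex(p.mirna_seq, p.site_seq))
            assert got == p.seed_type
            assert got in (dx.CANONICAL, dx.NON_CANONICAL)
            # the recorded site is embedded at the recorded offset
            utr = utrs[p.utr_id]
            assert utr[p.site_offset:p.site_offset + len(p.site_seq)] \
                == p.site_seq

    def test_byte_identical_under_same_seed(self):
        from mirtransfer.io import write_fasta

        spec = SpeciesSpec("s", n_mirnas=4, n_positive=8, rng_seed=9)
        blobs = []
        for _ in range(2):
            catalog, utrs, _ = simulate_sequences(spec)
            buf = io.StringIO()
            import Bio.SeqIO as SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord
            SeqIO.write([SeqRecord(Seq(s), id=n, description="")
                         for n, s in {**catalog, **utrs}.items()],
                        buf, "fasta")
            blobs.append(buf.getvalue().encode())
        assert blobs[0] == blobs[1]

    def test_impossible_spec_fails_with_named_constraint(self):
        with pytest.raises(ValueError, match="40"):
            SpeciesSpec("s", n_mirnas=2, n_positive=4, utr_length_range=(20, 30))


class TestFeatureMode:
    def _rule(self, feats, subsets, shifts, seed=0, **kw):
        return make_shifted_rule(feats, subsets, shifts,
                                 np.random.default_rng(seed), **kw)

    def test_exact_balance_and_row_count(self):
        feats = [f"f{i}" for i in range(6)]
        rule = self._rule(feats, {"a": ["f0"]}, {"a": 0.3})
        specs = [SpeciesSpec("a", rng_seed=1)]
        t = simulate_feature_tables(rule, specs, 200)["a"]
        assert len(t) == 200
        assert t.df["label"].sum() == 100

    def test_unknown_species_rejected(self):
        feats = ["f0", "f1"]
        rule = self._rule(feats, {"a": ["f0"]}, {"a": 0.0})
        with pytest.raises(ValueError, match="missing"):
            simulate_feature_tables(rule, [SpeciesSpec("zz")], 100)

    def test_unshifted_features_have_identical_marginals(self):
        # shift confined to S={f1,f2}: everything else matches across
        # species (two-sample KS, alpha=0.01)
        feats = [f"f{i}" for i in range(8)]
        rule = self._rule(feats, {"a": ["f1", "f2"], "b": ["f1", "f2"]},
                          {"a": 0.8, "b": 0.8}, mean_scale=2.0)
        specs = [SpeciesSpec("a", rng_seed=3), SpeciesSpec("b", rng_seed=4)]
        tabs = simulate_feature_tables(rule, specs, 2000)
        outside = [f for f in feats if f not in ("f1", "f2")]
        for f in outside:
            k = feats.index(f)
            p = stats.ks_2samp(tabs["a"].X[:, k], tabs["b"].X[:, k]).pvalue
            assert p > 0.01, f
        # and the shifted ones genuinely differ
        assert stats.ks_2samp(tabs["a"].X[:, 1], tabs["b"].X[:, 1]).pvalue \
            > 0.01  # same shift in both species here

    def test_logistic_fit_recovers_weight_signs(self):
        # generator sanity: one species, clear weights, n=5000
        from sklearn.linear_model import LogisticRegression

        feats = [f"f{i}" for i in range(6)]
        w = {f: s for f, s in zip(feats, [0.8, -0.8, 0.5, -0.5, 0.7, -0.7])}
        rule = GroundTruthRule(w, {"a": {}})
        t = simulate_feature_tables(rule, [SpeciesSpec("a", rng_seed=7)],
                                    5000)["a"]
        fit = LogisticRegression(max_iter=500).fit(t.X, t.y)
        signs = np.sign(fit.coef_[0])
        want = np.sign([w[f] for f in feats])
        assert (signs == want).mean() >= 0.95

    def test_pooled_training_matches_per_species_when_no_shift(self):
        # delta=0 for all species: training on the pool is statistically
        # indistinguishable from training per species (paired over seeds)
        from mirtransfer import models as M
        import pandas as pd

        feats = [f"f{i}" for i in range(8)]
        diffs = []
        for seed in range(10):
            rule = self._rule(feats, {"a": [], "b": []},
                              {"a": 0.0, "b": 0.0}, seed=seed)
            specs = [SpeciesSpec("a", rng_seed=seed * 2 + 1),
                     SpeciesSpec("b", rng_seed=seed * 2 + 2)]
            tabs = simulate_feature_tables(rule, specs, 600)
            test = simulate_feature_tables(
                rule, [SpeciesSpec("a", rng_seed=seed * 2 + 900)], 400)["a"]
            per = M.train_xgb(tabs["a"], {"seed": seed}, num_boost_round=50)
            pool_df = pd.concat([tabs["a"].df, tabs["b"].df],
                                ignore_index=True)
            pool = M.train_xgb(type(tabs["a"])(pool_df), {"seed": seed},
                               num_boost_round=50)
            acc = lambda m: ((m.predict(test) >= .5) ==
                             test.y.astype(bool)).mean()
            diffs.append(acc(pool) - acc(per))
        t = stats.ttest_1samp(diffs, 0.0)
        assert t.pvalue > 0.05 or np.mean(diffs) > 0  # pooling never hurts


class TestTableFromSequences:
    def _data(self, seed=0):
        spec = SpeciesSpec("s", n_mirnas=4, n_positive=6, rng_seed=seed)
        catalog, utrs, pos = simulate_sequences(spec)
        rng = np.random.default_rng(seed + 1)
        negs = sd.generate_negatives(pos, catalog, utrs, rng)
        return catalog, utrs, pos, negs

    def test_balanced_table(self):
        catalog, utrs, pos, negs = self._data()
        t = table_from_sequences(catalog, utrs, pos, negs)
        assert len(t) == 12
        assert t.df["label"].sum() == 6

    def test_empty_negatives_rejected(self):
        catalog, utrs, pos, _ = self._data()
        with pytest.raises(ValueError, match="balanced"):
            table_from_sequences(catalog, utrs, pos, [])

    def test_dangling_reference_names_record(self):
        catalog, utrs, pos, negs = self._data()
        bad = dict(catalog)
        bad.pop(pos[0].mirna_id)
        with pytest.raises(KeyError, match=pos[0].interaction_id):
            table_from_sequences(bad, utrs, pos, negs)
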