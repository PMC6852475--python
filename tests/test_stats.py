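"""AUC, permutation null, empirical-Bayes mixture and ANOVA contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srcconn import (EmpiricalBayes, auc_statistic, ebi_fit,
                     permutation_null, subgroup_anova)
from srcconn.stats import (FeatureMatrix, auc_per_feature,
                           inverse_normal_transform, pool_band_power,
                           results_table)
from srcconn.containers import BandPower, CANONICAL_BANDS


def brute_force_auc(a, b):
    wins = sum(1.0 if y > x else 0.5 if y == x else 0.0
               for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAuc:
    def test_known_values(self):
        assert auc_statistic([1, 3], [2, 4]) == 0.75
        assert auc_statistic([1, 2], [3, 4]) == 1.0
        assert auc_statistic([1, 2, 3], [1, 2, 3]) == 0.5

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=1, max_size=12),
           st.lists(st.integers(0, 8), min_size=1, max_size=12))
    def test_matches_brute_force(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        assert auc_statistic(a, b) == pytest.approx(
            brute_force_auc(a, b), abs=1e-12)

    def test_missing_values_dropped(self):
        assert auc_statistic([1, 2, np.nan], [3, np.nan]) == 1.0

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 15))
        is_b = np.zeros(20, bool)
        is_b[10:] = True
        per = auc_per_feature(vals, is_b)
        for j in range(15):
            assert per[j] == pytest.approx(
                auc_statistic(vals[~is_b, j], vals[is_b, j]))


@pytest.fixture(scope="module")
def null():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(30, 40))
    is_b = np.zeros(30, bool)
    is_b[15:] = True
    return permutation_null(vals, is_b, n_perm=2000, seed=3)


class TestPermutationNull:

    def test_mean_half(self, null):
        assert np.abs(null.mean(axis=0) - 0.5).max() < 0.02

    def test_variance_near_closed_form(self, null):
        var_theory = (15 + 15 + 1) / (12 * 15 * 15)
        ratio = null.var(axis=0).mean() / var_theory
        assert 0.8 < ratio < 1.2

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 5))
        is_b = np.arange(12) >= 6
        a = permutation_null(vals, is_b, 100, seed=9)
        b = permutation_null(vals, is_b, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            permutation_null(np.zeros((10, 2)), np.arange(10) >= 5, 50)


class TestEbi:
    def test_null_data_calibrated(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(40, 2000))
        is_b = np.arange(40) >= 20
        obs = auc_per_feature(vals, is_b)
        res = ebi_fit(obs, permutation_null(vals, is_b, 300, seed=1), q=0.10)
        assert res.pi0 >= 0.9
        assert res.mask.sum() <= 0.10 * 2000

    def test_strong_effects_fdr_controlled(self):
        """pi0 = 0.9 mixture, true AUC ~ 0.85: realised FDR <= 0.15."""
        rng = np.random.default_rng(5)
        fdps, sens = [], []
        for rep in range(10):
            vals = rng.normal(size=(80, 500))
            vals[40:, :50] += 1.5  # 10% non-null, AUC ~ 0.85
            is_b = np.arange(80) >= 40
            obs = auc_per_feature(vals, is_b)
            res = ebi_fit(obs, permutation_null(vals, is_b, 200,
                                                seed=rep), q=0.10)
            disc = res.mask
            if disc.sum():
                fdps.append(disc[50:].sum() / disc.sum())
                sens.append(disc[:50].mean())
        assert np.mean(fdps) <= 0.15
        assert np.mean(sens) > 0.5

    def test_posterior_complements_fdr(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(20, 100))
        is_b = np.arange(20) >= 10
        obs = auc_per_feature(vals, is_b)
        res = ebi_fit(obs, permutation_null(vals, is_b, 100, seed=0))
        np.testing.assert_allclose(res.p1 + res.fdr, 1.0, atol=1e-12)

    def test_degenerate_observations_no_discoveries(self):
        obs = np.full(200, 0.5)
        null = np.random.default_rng(0).uniform(0.3, 0.7, (100, 200))
        res = ebi_fit(obs, null)
        assert res.pi0 == 1.0
        assert res.mask.sum() == 0

    def test_mask_monotone_in_q(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(40, 300))
        vals[20:, :30] += 1.2
        is_b = np.arange(40) >= 20
        obs = auc_per_feature(vals, is_b)
        null = permutation_null(vals, is_b, 200, seed=2)
        m1 = ebi_fit(obs, null, q=0.05).mask
        m2 = ebi_fit(obs, null, q=0.20).mask
        assert set(np.nonzero(m1)[0]) <= set(np.nonzero(m2)[0])

    def test_estimator_front_end(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(30, 120))
        groups = np.array(["ctrl"] * 15 + ["pat"] * 15)
        eb = EmpiricalBayes(n_perm=100, seed=1).fit(vals, groups)
        assert eb.auc_.shape == (120,)
        assert 0 <= eb.pi0_ <= 1
        params = eb.get_params()
        assert params["q"] == 0.10

    def test_subject_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(24, 60))
        is_b = np.arange(24) >= 12
        perm = rng.permutation(24)
        a = auc_per_feature(vals, is_b)
        b = auc_per_feature(vals[perm], is_b[perm])
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPooling:
    def test_power_pooling_counts(self):
        rng = np.random.default_rng(0)
        powers = [BandPower(f"s{i}", rng.uniform(0.1, 1, (90, 6)),
                            CANONICAL_BANDS) for i in range(8)]
        fm = pool_band_power(powers, ["a"] * 4 + ["b"] * 4)
        assert fm.values.shape == (8, 540)
        assert list(fm.index["band"].unique()) == [b.name for b in
                                                   CANONICAL_BANDS]

    def test_results_table_layout(self):
        rng = np.random.default_rng(1)
        powers = [BandPower(f"s{i}", rng.uniform(0.1, 1, (4, 6)),
                            CANONICAL_BANDS) for i in range(60)]
        vals = np.stack([p.values.T.ravel() for p in powers])
        vals[30:, 0] += 2.0
        fm = FeatureMatrix(values=vals,
                           index=pool_band_power(powers,
                                                 ["a"] * 30 + ["b"] * 30).index,
                           groups=["a"] * 30 + ["b"] * 30,
                           subject_ids=[p.subject for p in powers])
        eb = EmpiricalBayes(n_perm=100, seed=0).fit(fm.values,
                                                    np.array(fm.groups))
        tbl = results_table(fm, eb.result_)
        assert {"quantity", "band", "auc", "fdr", "p1",
                "significant"} <= set(tbl.columns)
        assert len(tbl) == 24


class TestAnova:
    def test_inverse_normal_transform_properties(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=101)
        z = inverse_normal_transform(x)
        med = np.argsort(x)[len(x) // 2]
        assert abs(z[med]) < 0.02          # median maps near 0
        order = np.argsort(x)
        assert (np.diff(z[order]) > 0).all()  # strictly increasing in rank

    def test_planted_onset_effect_detected(self):
        rng = np.random.default_rng(1)
        n = 40
        onset = np.array(["bulbar", "spinal"] * (n // 2))
        geno = rng.permutation(np.array(["pos", "neg"] * (n // 2)))
        values = rng.normal(size=n) + 3.0 * (onset == "bulbar")
        p = subgroup_anova(values, onset, geno)
        assert p["onset"] < 0.001
        assert p["genotype"] > 0.001

    def test_single_level_factor_undefined(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=20)
        onset = ["bulbar"] * 20
        geno = ["pos", "neg"] * 10
        p = subgroup_anova(values, onset, geno)
        assert np.isnan(p["onset"])
        assert np.isfinite(p["genotype"])
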