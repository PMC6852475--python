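"""Edge selection, NMF factorisation, ensemble and module-map contracts."""

import numpy as np
import pandas as pd
import pytest

from srcconn import ConnectivityMatrix, EnsembleNMF, band_by_name, \
    module_map, nmf_once, select_edges, select_rank_bic
from srcconn.nmf import test_module_weights as module_weight_test
from srcconn.nmf import _greedy_align

THETA = band_by_name("theta")


def _matrices_from_values(values, n_rois):
    """subjects x edges values -> list of symmetric ConnectivityMatrix."""
    iu = np.triu_indices(n_rois, k=1)
    mats = []
    for s, row in enumerate(values):
        w = np.zeros((n_rois, n_rois))
        w[iu] = row
        mats.append(ConnectivityMatrix(f"s{s}", "AEC", THETA, w + w.T))
    return mats


class TestSelectEdges:
    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        n_rois, n_sub = 40, 40  # 780 edges
        values = rng.uniform(0.1, 0.5, size=(n_sub, 780))
        mats = _matrices_from_values(values, n_rois)
        groups = ["a"] * 20 + ["b"] * 20
        sel = select_edges(mats, groups, alpha=0.05)
        rate = sel.edges.shape[0] / 780
        # binomial 99% envelope around 5% for 780 draws
        assert 0.03 < rate < 0.075

    def test_strong_edges_selected(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.1, 0.3, size=(40, 66))
        values[20:, :5] += 0.3
        mats = _matrices_from_values(values, 12)
        sel = select_edges(mats, ["a"] * 20 + ["b"] * 20, alpha=0.05)
        chosen = {tuple(e) for e in sel.edges}
        iu = np.triu_indices(12, k=1)
        planted = {(iu[0][k], iu[1][k]) for k in range(5)}
        assert planted <= chosen

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(2)
        mats = _matrices_from_values(rng.uniform(0, 1, (20, 66)), 12)
        sel = select_edges(mats, ["a"] * 10 + ["b"] * 10, alpha=0.0)
        assert sel.edges.shape[0] == 0


class TestNmfOnce:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        v = np.outer(rng.uniform(0.5, 2, 15), rng.uniform(0.5, 2, 30))
        _, _, err, _ = nmf_once(v, k=1, seed=1, max_iter=2000, tol=1e-12)
        assert err / np.linalg.norm(v) ** 2 <= 1e-6

    def test_error_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=(20, 40))
        _, _, _, trace = nmf_once(v, k=3, seed=2)
        assert (np.diff(trace) <= 1e-9 * trace[0]).all()

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(size=(10, 20))
        w1, h1, _, _ = nmf_once(v, 2, seed=3, max_iter=1000)
        w2, h2, _, _ = nmf_once(2 * v, 2, seed=3, max_iter=1000)
        np.testing.assert_allclose(w2 @ h2, 2 * (w1 @ h1), rtol=0.05)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            nmf_once(np.array([[1.0, -0.1]]), 1)

    def test_matches_sklearn_objective(self):
        """Independent solver cross-check: same reconstruction quality."""
        from sklearn.decomposition import NMF
        rng = np.random.default_rng(3)
        w0 = rng.uniform(0.2, 1, (30, 2))
        h0 = rng.uniform(0.2, 1, (2, 50))
        v = w0 @ h0 + rng.uniform(0, 0.05, (30, 50))
        _, _, ours, _ = nmf_once(v, 2, seed=4, max_iter=2000, tol=1e-10)
        sk = NMF(n_components=2, solver="mu", max_iter=2000, tol=1e-10,
                 init="random", random_state=4).fit(v)
        theirs = sk.reconstruction_err_ ** 2
        assert ours <= theirs * 1.05


class TestRankSelection:
    def test_rank_two_structure_found(self):
        rng = np.random.default_rng(4)
        w = np.abs(rng.normal(size=(40, 2)))
        h = np.zeros((2, 60))
        h[0, :30] = rng.uniform(0.5, 1, 30)
        h[1, 30:] = rng.uniform(0.5, 1, 30)
        v = w @ h + np.abs(rng.normal(scale=0.1, size=(40, 60)))
        k, trace = select_rank_bic(v, [1, 2, 3, 4], n_restarts=5, seed=0)
        assert k == 2
        assert set(trace) == {1, 2, 3, 4}

    def test_white_noise_rank_one(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(size=(40, 60))
        k, _ = select_rank_bic(v, [1, 2, 3], n_restarts=5, seed=0)
        assert k == 1


@pytest.fixture(scope="module")
def planted_v():
    rng = np.random.default_rng(6)
    groups = np.array(["ctrl"] * 20 + ["pat"] * 20)
    w = np.abs(rng.normal(0.2, 0.05, size=(40, 2)))
    w[20:, 0] += 1.0  # module 0 expressed by patients
    w[:20, 1] += 1.0  # module 1 expressed by controls
    h = np.zeros((2, 80))
    h[0, :40] = rng.uniform(0.5, 1, 40)
    h[1, 40:] = rng.uniform(0.5, 1, 40)
    v = w @ h + np.abs(rng.normal(scale=0.05, size=(40, 80)))
    return v, groups


class TestEnsemble:
    def test_every_subject_gets_weights(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=0).fit(v, groups)
        assert model.W_.shape == (40, 2)
        assert (model.W_ >= 0).all()
        assert (model.H_ >= 0).all()

    def test_single_resample_equals_single_fit_shape(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=1, n_restarts=3,
                            seed=1).fit(v, groups)
        assert model.H_.shape == (2, 80)
        # rows are unit-normalised when only one resample contributes
        np.testing.assert_allclose(np.linalg.norm(model.H_, axis=1), 1.0,
                                   rtol=1e-9)

    def test_ensemble_stability_across_master_seeds(self, planted_v):
        v, groups = planted_v
        h = []
        for seed in (3, 4):
            m = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=seed).fit(v, groups)
            h.append(m.H_)
        aligned, _ = _greedy_align(h[0], h[1], np.zeros((1, 2)))
        for a, b in zip(h[0], aligned):
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos >= 0.95

    def test_module_mass_on_planted_sets(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=0).fit(v, groups)
        maps = module_map(model)
        masses = []
        for planted_cols in (range(0, 40), range(40, 80)):
            best = max(mm.scores[list(planted_cols)].sum() / mm.scores.sum()
                       for mm in maps)
            masses.append(best)
        assert min(masses) >= 0.8


class TestModuleMap:
    def test_sign_reflects_group_direction(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=0).fit(v, groups)
        maps = {mm.module: mm for mm in module_map(model)}
        # module expressed by patients is positive, by controls negative
        signs = sorted(mm.sign for mm in maps.values())
        assert signs == [-1, 1]

    def test_sign_flips_with_labels(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=0).fit(v, groups)
        flipped = np.where(groups == "ctrl", "pat", "ctrl")
        m1 = module_map(model)
        # relabel: group levels swap roles
        model.groups_ = flipped
        m2 = module_map(model)
        for a, b in zip(m1, m2):
            assert a.sign == -b.sign

    def test_scores_normalised(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=5, n_restarts=5,
                            seed=0).fit(v, groups)
        for mm in module_map(model):
            assert mm.scores.min() == 0.0
            assert mm.scores.max() == 1.0


class TestModuleWeightTests:
    def test_separated_weights_significant(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=10, n_restarts=5,
                            seed=0).fit(v, groups)
        df = module_weight_test(model, n_boot=500, seed=1)
        assert (df["p"] < 0.05).all()
        assert (df["power"] > 0.9).all()
        assert df["significant"].all()

    def test_null_weights_uncalibrated_power(self):
        rng = np.random.default_rng(7)
        groups = np.array(["a"] * 12 + ["b"] * 12)
        model = EnsembleNMF(k=2)
        model.H_ = rng.uniform(size=(2, 30))
        model.W_ = rng.uniform(size=(24, 2))
        model.groups_ = groups
        df = module_weight_test(model, n_boot=500, seed=2)
        assert (df["p"] > 0.01).all()  # no genuine separation

    def test_seed_reproducibility(self, planted_v):
        v, groups = planted_v
        model = EnsembleNMF(k=2, n_resamples=5, n_restarts=5,
                            seed=0).fit(v, groups)
        a = module_weight_test(model, n_boot=200, seed=5)
        b = module_weight_test(model, n_boot=200, seed=5)
        pd.testing.assert_frame_equal(a, b)
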