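"""Magnitude transform, multiplicative-update NNMF, CV rank selection,
stability selection, and the StarNMF estimator."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.decomposition import NMF as SKNMF

import jierp
from jierp.factorization import (
    StarNMF,
    matched_cosine_similarity,
    nnmf_factorize,
    select_rank_cv,
    stable_factorize,
)


def tensor_from_amplitude(amp, valid=None, t0=-200):
    amp = np.asarray(amp, dtype=float)
    if valid is None:
        valid = np.ones(amp.shape[:2], dtype=bool)
    amp = amp.copy()
    amp[~valid] = np.nan
    return jierp.JierpTensor(
        amplitude=amp,
        trial_count=np.where(valid, 20, 0),
        valid=valid,
        time_ms=np.arange(t0, t0 + amp.shape[2]),
        grid=jierp.BinGrid(),
    )


def planted_matrix(rng, rank=3, shape=(25, 299), noise=0.0):
    W = rng.random((shape[0], rank))
    H = rng.random((rank, shape[1]))
    M = W @ H
    if noise:
        M = np.abs(M + noise * rng.standard_normal(shape))
    return M, W, H


class TestMagnitudeTransform:
    def test_minimum_exactly_zero_and_differences_preserved(self):
        rng = np.random.default_rng(0)
        j = tensor_from_amplitude(rng.normal(size=(5, 5, 500)))
        mat = jierp.magnitude_transform(j)
        assert mat.M.min() == 0.0
        assert mat.M.shape == (25, 299)
        # oracle: z of |amplitude| across bins, before the shift
        post = (j.time_ms >= 1) & (j.time_ms <= 299)
        mag = np.abs(j.amplitude[:, :, post]).reshape(25, -1)
        z = (mag - mag.mean(0)) / mag.std(0, ddof=1)
        diffs = mat.M[3] - mat.M[11]
        assert np.allclose(diffs, z[3] - z[11], atol=1e-12)

    def test_three_bin_toy_z_values(self):
        """|amplitudes| {1,2,3} at every latency: z = {-1, 0, 1} pre-shift,
        so the shifted rows are {0, 1, 2}."""
        valid = np.zeros((5, 5), dtype=bool)
        valid[0, 0] = valid[0, 1] = valid[0, 2] = True
        amp = np.zeros((5, 5, 500))
        for i, v in enumerate((1.0, 2.0, 3.0)):
            amp[0, i, :] = v
        mat = jierp.magnitude_transform(tensor_from_amplitude(amp, valid))
        assert np.allclose(mat.M[0], 0.0)
        assert np.allclose(mat.M[1], 1.0)
        assert np.allclose(mat.M[2], 2.0)
        assert mat.bins == [(0, 0), (0, 1), (0, 2)]
        assert (1, 1) in mat.excluded_bins

    def test_post_stimulus_restriction(self):
        j = tensor_from_amplitude(np.random.default_rng(1).normal(size=(5, 5, 500)))
        mat = jierp.magnitude_transform(j)
        assert mat.time_ms[0] == 1 and mat.time_ms[-1] == 299


class TestMultiplicativeUpdates:
    def test_exact_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(2)
        M = np.outer(rng.random(25), rng.random(299))
        f = nnmf_factorize(M, rank=1, seed=0)
        assert f.frobenius_error / np.linalg.norm(M) < 1e-3

    def test_error_monotonically_non_increasing(self):
        rng = np.random.default_rng(3)
        M = rng.random((25, 100))
        f = nnmf_factorize(M, rank=4, seed=1)
        assert np.all(np.diff(f.error_history) <= 1e-9 * f.error_history[0])

    def test_seeded_determinism(self):
        M = np.random.default_rng(4).random((20, 30))
        a = nnmf_factorize(M, 3, seed=5)
        b = nnmf_factorize(M, 3, seed=5)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    def test_error_nests_with_rank(self):
        """Best-of-restarts error at rank r+1 <= error at rank r."""
        M = np.random.default_rng(5).random((15, 40))
        best = {}
        for r in (2, 3, 4):
            best[r] = min(
                nnmf_factorize(M, r, seed=s).frobenius_error for s in range(5)
            )
        assert best[3] <= best[2] + 1e-9
        assert best[4] <= best[3] + 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nnmf_factorize(-np.ones((4, 4)), 2)
        with pytest.raises(ValueError):
            nnmf_factorize(np.ones((4, 4)), 9)


class TestRankSelectionCV:
    def test_error_curve_reported_for_every_rank(self):
        M, _, _ = planted_matrix(np.random.default_rng(6), rank=2, noise=0.01)
        sel = select_rank_cv(M, rank_range=(2, 6), seed=0)
        assert sel.ranks.tolist() == [2, 3, 4, 5, 6]
        assert sel.cv_error.shape == (5,)
        assert np.all(np.isfinite(sel.cv_error))

    def test_noiseless_rank_one_selects_floor(self):
        M = np.outer(np.random.default_rng(7).random(25), np.random.default_rng(8).random(60))
        sel = select_rank_cv(M, rank_range=(2, 5), seed=1)
        assert sel.best_rank == 2  # flat curve beyond truth: 1-SE picks the floor

    def test_planted_rank_three_recovered(self):
        M, _, _ = planted_matrix(np.random.default_rng(9), rank=3, noise=0.01)
        sel = select_rank_cv(M, rank_range=(2, 6), seed=2)
        assert sel.best_rank == 3


class TestStableFactorize:
    def test_exact_low_rank_highly_stable(self):
        M, _, _ = planted_matrix(np.random.default_rng(10), rank=3)
        f = stable_factorize(M, 3, n_reps=10, seed=0, tol=1e-6, max_iter=1000)
        assert f.stability_score > 0.99

    def test_single_repetition_flagged(self):
        M, _, _ = planted_matrix(np.random.default_rng(11), rank=2)
        f = stable_factorize(M, 2, n_reps=1, seed=0)
        assert f.stability_score is None
        assert f.meta["stability_undefined"]

    def test_similarity_invariant_to_permutation_and_scale(self):
        W = np.random.default_rng(12).random((25, 4))
        perm = [2, 0, 3, 1]
        scales = np.array([0.1, 3.0, 7.5, 0.4])
        assert matched_cosine_similarity(W, W[:, perm] * scales) == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            stable_factorize(np.zeros((5, 5)), 2)

    def test_planted_pattern_recovery_under_noise(self):
        """Three planted (meta-JIERP, meta-time) pairs with ~8% noise: the
        stability-selected solution recovers each planted meta-JIERP with
        matched cosine similarity >= 0.9."""
        rng = np.random.default_rng(13)
        t = np.arange(1, 300)

        def bump(mu, s):
            return np.exp(-((t - mu) ** 2) / (2 * s**2))

        W = np.stack(
            [
                np.tile([0.1, 0.3, 0.7, 1.0, 1.0], 5),  # low short / high long k
                np.tile([0.2, 0.9, 1.0, 0.9, 0.2], 5),  # mid-interval pattern
                np.tile([1.0, 0.4, 0.15, 0.1, 0.1], 5),  # high short k
            ],
            axis=1,
        )
        H = np.stack([bump(50, 15) + bump(220, 40), bump(40, 10) + bump(120, 20),
                      bump(100, 15)])
        M0 = W @ H
        noise = rng.standard_normal(M0.shape)
        noise *= 0.08 * np.linalg.norm(M0) / np.linalg.norm(noise)
        M = np.clip(M0 + noise, 0.0, None)
        f = stable_factorize(M, 3, n_reps=20, seed=3)
        C = (W / np.linalg.norm(W, axis=0)).T @ (
            f.W / np.linalg.norm(f.W, axis=0)
        )
        from scipy.optimize import linear_sum_assignment

        ri, ci = linear_sum_assignment(-C)
        assert np.all(C[ri, ci] >= 0.9)


class TestStarNMFEstimator:
    def test_fit_attributes_and_reconstruction(self):
        M, _, _ = planted_matrix(np.random.default_rng(14), rank=2, noise=0.01)
        est = StarNMF(rank=2, n_reps=8, random_state=0).fit(M)
        assert est.rank_ == 2
        assert est.components_.shape == (2, 299)
        assert est.basis_.shape == (25, 2)
        rel = est.reconstruction_err_ / np.linalg.norm(M)
        assert rel < 0.05
        assert 0.0 <= est.stability_score_ <= 1.0

    def test_cv_rank_selection_path(self):
        M, _, _ = planted_matrix(np.random.default_rng(15), rank=2, noise=0.01)
        est = StarNMF(rank="cv", rank_range=(2, 4), n_reps=5, random_state=1).fit(M)
        assert est.rank_selection_ is not None
        assert est.rank_ == est.rank_selection_.best_rank

    def test_transform_projects_onto_components(self):
        M, _, _ = planted_matrix(np.random.default_rng(16), rank=2, noise=0.0)
        est = StarNMF(rank=2, n_reps=5, random_state=0).fit(M)
        W = est.transform(M)
        assert W.shape == (25, 2)
        rel = np.linalg.norm(M - est.inverse_transform(W)) / np.linalg.norm(M)
        assert rel < 0.05

    def test_sklearn_clone_compatible(self):
        est = StarNMF(rank=3, n_reps=7, random_state=42)
        params = clone(est).get_params()
        assert params["rank"] == 3 and params["n_reps"] == 7

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            StarNMF(rank=2).fit(-np.ones((5, 5)))


class TestAgainstSklearnNMF:
    def test_reconstruction_error_comparable_to_reference(self):
        """Independent cross-check: our multiplicative updates reach a
        reconstruction error comparable to sklearn's NMF (mu solver)."""
        M = np.random.default_rng(17).random((25, 80))
        ours = min(
            nnmf_factorize(M, 4, seed=s, max_iter=1000, tol=1e-7).frobenius_error
            for s in range(3)
        )
        ref = SKNMF(
            n_components=4, solver="mu", init="random", random_state=0,
            max_iter=1000, tol=1e-7,
        ).fit(M)
        ref_err = np.linalg.norm(M - ref.transform(M) @ ref.components_)
        assert ours <= 1.05 * ref_err
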