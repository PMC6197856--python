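"""Empirical Bayesian beamformer: data reduction, prior, ReML and MAP."""

import numpy as np
import pytest

from laminarmeg.forward import LeadField, coherence_smooth, shuffle_lead_fields
from laminarmeg.inversion import (
    NoiseModel,
    ebb_prior,
    invert,
    multi_reg_invert,
    patch_size_sweep,
    reml_mix,
    svd_reduce,
)
from laminarmeg.synthetic import make_sensor_array, make_two_layer_model


class TestSvdReduce:
    def test_rank_one_data_fully_captured(self, rng):
        pattern = rng.standard_normal(8)
        course = rng.standard_normal(50)
        X = np.stack([np.outer(pattern, course)] * 3)
        red = svd_reduce(X, n_spatial=1, n_temporal=1)
        assert red.variance_captured == pytest.approx(1.0, abs=1e-10)

    def test_full_modes_lossless(self, rng):
        X = rng.standard_normal((2, 6, 20))
        red = svd_reduce(X, n_spatial=6, n_temporal=20)
        # reconstruct: Aᵀ Y Tᵀ→ original
        A, T = red.spatial_projector, red.temporal_projector
        back = np.einsum("ck,tkm,ms->tcs", A.T, red.Y, T)
        # projectors are orthonormal and complete at full rank
        np.testing.assert_allclose(A @ A.T, np.eye(6), atol=1e-10)
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_variance_captured_matches_svd_oracle(self, rng):
        X = rng.standard_normal((1, 10, 50))
        red = svd_reduce(X, n_spatial=4, n_temporal=50)
        s = np.linalg.svd(X[0], compute_uv=False)
        expected = (s[:4] ** 2).sum() / (s**2).sum()
        assert red.variance_captured == pytest.approx(expected, rel=1e-10)

    def test_rank_deficient_truncates_with_warning(self, rng):
        X = np.zeros((1, 6, 30))
        X[0, :2] = rng.standard_normal((2, 30))
        with pytest.warns(UserWarning, match="truncated"):
            red = svd_reduce(X, n_spatial=5, n_temporal=4)
        assert red.n_spatial == 2


class TestEbbPrior:
    def test_white_covariance_closed_form(self, rng):
        """YYᵀ = σ²·I ⇒ Q(i) = σ² / ‖Li‖⁴."""
        n_ch, n_src = 6, 10
        L = rng.standard_normal((n_ch, n_src))
        sigma2 = 2.5
        Y = np.sqrt(sigma2) * np.eye(n_ch)  # YYᵀ = σ²I exactly
        prior = ebb_prior(Y, L, lam=0)
        norms2 = (L**2).sum(axis=0)
        np.testing.assert_allclose(prior.q, sigma2 / norms2**2, rtol=1e-10)

    def test_column_scaling_law(self, rng):
        """Scaling every column by c scales Q by 1/c⁴: both the 1/LiᵀLi
        normalization and the beamformer power term contribute a 1/c²
        factor (direct substitution into the prior formula)."""
        L = rng.standard_normal((5, 7))
        Y = rng.standard_normal((5, 40))
        c = 3.7
        q1 = ebb_prior(Y, L).q
        q2 = ebb_prior(Y, c * L).q
        np.testing.assert_allclose(q2, q1 / c**4, rtol=1e-10)

    def test_hand_computed_toy(self):
        """3-channel, 2-source toy against an explicit hand evaluation."""
        L = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        Y = np.array([[1.0, 0.0, 1.0], [0.0, 2.0, 0.0], [0.0, 0.0, 3.0]])
        C = Y @ Y.T
        Cinv = np.linalg.inv(C)
        expected = [
            1.0 / ((L[:, i] @ L[:, i]) * (L[:, i] @ Cinv @ L[:, i]))
            for i in range(2)
        ]
        prior = ebb_prior(Y, L, lam=0)
        np.testing.assert_allclose(prior.q, expected, rtol=1e-12)

    def test_singular_covariance_requires_regularization(self, rng):
        L = rng.standard_normal((6, 4))
        Y = np.zeros((6, 10))
        Y[0] = rng.standard_normal(10)  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            ebb_prior(Y, L, lam=0)
        prior = ebb_prior(Y, L, lam=5)
        assert np.all(np.isfinite(prior.q))


class TestReml:
    def test_hyperparameter_recovery(self, rng):
        """Data with covariance exactly 2·I + 3·LQLᵀ recovers (2, 3) within
        10% at large sample."""
        n_ch, n_src = 12, 20
        L = rng.standard_normal((n_ch, n_src))
        q = rng.uniform(0.5, 1.5, n_src)
        from laminarmeg.inversion import SourcePrior

        C_true = 2.0 * np.eye(n_ch) + 3.0 * (L * q) @ L.T
        chol = np.linalg.cholesky(C_true)
        Y = chol @ rng.standard_normal((n_ch, 20000))
        res = reml_mix(Y, L, SourcePrior(q=q))
        assert res.h_eps == pytest.approx(2.0, rel=0.10)
        assert res.h_q == pytest.approx(3.0, rel=0.10)

    def test_pure_noise_kills_source_component(self, rng):
        """With an exactly white sample covariance the ML source scale
        collapses to (numerically) zero."""
        n_ch, n_src = 10, 15
        L = rng.standard_normal((n_ch, n_src))
        from laminarmeg.inversion import SourcePrior

        q = np.ones(n_src) / np.trace(L @ L.T)
        Y = np.tile(np.eye(n_ch), 1000)  # YYᵀ ∝ I exactly
        res = reml_mix(Y, L, SourcePrior(q=q))
        assert res.h_q * np.trace((L * q) @ L.T) < 1e-3 * res.h_eps * n_ch

    def test_generating_model_beats_shuffled(self):
        """ReML free energy prefers the veridical forward model over one
        whose columns were shuffled before patch smoothing, 20/20.

        Note a bare column permutation leaves L·diag(q)·Lᵀ invariant for any
        per-column prior, so the geometry must enter through the coherence
        (patch) smoothing, exactly as in the full pipeline.
        """
        model = make_two_layer_model(subdivisions=2, wrinkle_amplitude=0.007)
        sens = make_sensor_array(n=40, helmet_radius=0.105)
        from laminarmeg.forward import build_lead_field

        lf = build_lead_field(model, sens)
        fwhm = 0.02
        lf_sm = coherence_smooth(lf, model, fwhm)
        rms = lf.column_rms()
        good = np.where(rms > 0.3 * np.median(rms))[0]
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            src = r.choice(good, 5, replace=False)
            Y = lf_sm.L[:, src] @ r.standard_normal((5, 1000))
            Y += 0.1 * np.sqrt((Y**2).mean()) * r.standard_normal(Y.shape)
            F_true = reml_mix(Y, lf_sm, ebb_prior(Y, lf_sm, lam=0)).free_energy
            shuf = coherence_smooth(
                shuffle_lead_fields(lf, seed=rep), model, fwhm
            )
            F_shuf = reml_mix(Y, shuf, ebb_prior(Y, shuf, lam=0)).free_energy
            wins += F_true >= F_shuf
        assert wins == 20

    def test_free_energy_rotation_invariant(self, rng):
        n_ch = 8
        L = rng.standard_normal((n_ch, 12))
        Y = rng.standard_normal((n_ch, 500))
        from laminarmeg.inversion import SourcePrior

        q = np.ones(12)
        F = reml_mix(Y, L, SourcePrior(q=q)).free_energy
        Q, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
        F_rot = reml_mix(Q @ Y, Q @ L, SourcePrior(q=q)).free_energy
        assert F_rot == pytest.approx(F, rel=1e-6)


class TestInvert:
    def test_map_formula_equivalence(self, rng):
        """Ĵ matches the dense textbook evaluation on random matrices."""
        n_ch, n_src = 5, 8
        L = rng.standard_normal((n_ch, n_src))
        Y = rng.standard_normal((n_ch, 12))
        from laminarmeg.inversion import SourcePrior

        q = rng.uniform(0.1, 2.0, n_src)
        prior = SourcePrior(q=q)
        res = reml_mix(Y, L, prior)
        est = invert(Y, L, res)
        Qm = res.h_q * np.diag(q)
        C = res.h_eps * np.eye(n_ch) + L @ Qm @ L.T
        J_expected = Qm @ L.T @ np.linalg.inv(C) @ Y
        np.testing.assert_allclose(est.J, J_expected, rtol=1e-10)

    def test_zero_data_zero_estimate(self, rng):
        L = rng.standard_normal((5, 8))
        from laminarmeg.inversion import SourcePrior, InversionResult

        res = InversionResult(
            h_eps=1.0, h_q=1.0, free_energy=0.0, lam=0.0,
            prior=SourcePrior(q=np.ones(8)), noise=NoiseModel(), n_iter=0,
            converged=True,
        )
        est = invert(np.zeros((5, 10)), L, res)
        np.testing.assert_array_equal(est.J, 0)

    def test_orthogonal_columns_identify_active_source(self, rng):
        """Noiseless single source with orthogonal lead fields peaks at the
        true source."""
        L = np.eye(6)[:, :4]  # orthonormal columns
        s = rng.standard_normal(30)
        Y = np.outer(L[:, 2], s)
        prior = ebb_prior(Y + 1e-8 * rng.standard_normal(Y.shape), L, lam=5)
        res = reml_mix(Y, L, prior)
        est = invert(Y, L, res)
        power = (est.J**2).sum(axis=1)
        assert np.argmax(power) == 2

    def test_linear_in_data(self, rng):
        L = rng.standard_normal((6, 9))
        Y = rng.standard_normal((6, 15))
        from laminarmeg.inversion import SourcePrior

        res = reml_mix(Y, L, SourcePrior(q=np.ones(9)))
        J1 = invert(Y, L, res).J
        J2 = invert(3.0 * Y, L, res).J
        np.testing.assert_allclose(J2, 3.0 * J1, rtol=1e-10)


class TestMultiRegularization:
    def test_single_lambda_equals_plain_path(self, rng):
        L = rng.standard_normal((6, 10))
        Y = rng.standard_normal((6, 100))
        prior = ebb_prior(Y, L, lam=0)
        direct = reml_mix(Y, L, prior)
        res, est = multi_reg_invert(Y, L, lambdas=(0,))
        assert res.free_energy == pytest.approx(direct.free_energy, rel=1e-10)

    def test_all_candidates_scored_winner_argmax(self, rng):
        L = rng.standard_normal((6, 10))
        Y = rng.standard_normal((6, 100))
        lambdas = (0, 5, 10, 50, 100, 1000)
        res, _ = multi_reg_invert(Y, L, lambdas=lambdas)
        assert set(res.all_free_energies) == set(lambdas)
        assert res.lam == max(res.all_free_energies,
                              key=res.all_free_energies.get)

    def test_zero_lambda_wins_on_well_conditioned_data(self):
        """λ=0 gives the highest evidence in ≥15/20 repetitions on
        well-conditioned source-driven data."""
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            n_ch = 10
            L = r.standard_normal((n_ch, 25))
            q = np.zeros(25)
            q[r.choice(25, 3, replace=False)] = 1.0
            C = 0.2 * np.eye(n_ch) + (L * q) @ L.T
            Y = np.linalg.cholesky(C) @ r.standard_normal((n_ch, 3000))
            res, _ = multi_reg_invert(Y, L, lambdas=(0, 5, 10, 50, 100, 1000))
            wins += res.lam == 0
        assert wins >= 15


def test_inversion_result_hdf5_round_trip(tmp_path, rng):
    from laminarmeg.inversion import SourcePrior

    L = rng.standard_normal((6, 9))
    Y = rng.standard_normal((6, 50))
    res, est = multi_reg_invert(Y, L, lambdas=(0, 5))
    p = tmp_path / "inv.h5"
    res.save(p, estimate=est)
    back, est_back = type(res).load(p)
    assert back.free_energy == res.free_energy
    assert back.hyperparameters == res.hyperparameters
    assert back.all_free_energies == res.all_free_energies
    np.testing.assert_array_equal(back.prior.q, res.prior.q)
    np.testing.assert_array_equal(est_back.J, est.J)


class TestPatchSizeSweep:
    @pytest.fixture(scope="class")
    def sweep_setup(self):
        model = make_two_layer_model(subdivisions=2, wrinkle_amplitude=0.007)
        sens = make_sensor_array(n=40, helmet_radius=0.105)
        from laminarmeg.forward import build_lead_field

        lf = build_lead_field(model, sens)
        return model, lf

    def test_relative_free_energies_sum_to_zero(self, sweep_setup, rng):
        model, lf = sweep_setup
        Y = rng.standard_normal((40, 200))
        df = patch_size_sweep(Y, lf, model, fwhms=(0.005, 0.01, 0.02))
        assert df["relative_free_energy"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_single_fwhm_relative_zero(self, sweep_setup, rng):
        model, lf = sweep_setup
        Y = rng.standard_normal((40, 100))
        df = patch_size_sweep(Y, lf, model, fwhms=(0.01,))
        assert df["relative_free_energy"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_generative_patch_size_recovered(self, sweep_setup):
        """Data simulated with 20 mm patches prefer the 20 mm model over a
        5 mm model in ≥15/20 repetitions."""
        model, lf = sweep_setup
        true_fwhm = 0.020
        lf_true = coherence_smooth(lf, model, true_fwhm)
        rms = lf.column_rms()
        good = np.where(rms > 0.3 * np.median(rms))[0]
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            src = r.choice(good, 2, replace=False)
            S = np.zeros((lf.n_sources,))
            S[src] = 1.0
            cols = lf_true.L[:, src]
            Y = cols @ r.standard_normal((2, 400))
            Y += 0.3 * np.sqrt((Y**2).mean()) * r.standard_normal(Y.shape)
            df = patch_size_sweep(Y, lf, model, fwhms=(0.005, true_fwhm))
            best = df.loc[df["free_energy"].idxmax(), "fwhm"]
            wins += best == true_fwhm
        assert wins >= 15
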