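"""Evoked/spontaneous decomposition, variance components, contribution
indices, tuning curves, shuffle nulls and cross-correlograms."""

import numpy as np
import pytest

from cilva.core import FluorescenceMatrix, StimulusDesign, reconstruct
from cilva.decomposition import (
    averaged_tuning_curve,
    decompose,
    decompose_traces,
    drive_ratio,
    factor_contribution_index,
    factor_cross_correlogram,
    model_tuning_curve,
    corrected_variance_and_private,
    onsets_from_design,
    shuffle_null,
    variance_components,
    _rowwise_corr,
)
from cilva.simulate import sample_zero_inflated_exp, simulate, zebrafish_like


class TestDecomposeTraces:
    def test_components_sum_to_reconstruction(self, small_instance):
        F, model, S = small_instance
        fe, fsp, _ = decompose_traces(model, S)
        np.testing.assert_allclose(
            fe + fsp - model.beta[:, None], reconstruct(model, S), rtol=1e-10, atol=1e-12
        )

    def test_zero_couplings_make_spont_pure_baseline(self, small_instance):
        F, model, S = small_instance
        m = model.copy()
        m.B = np.zeros_like(m.B)
        _, fsp, _ = decompose_traces(m, S)
        np.testing.assert_allclose(fsp, np.tile(m.beta[:, None], (1, S.n_frames)), atol=1e-14)

    def test_generative_round_trip_noiseless(self):
        tr = simulate(zebrafish_like(N=6, T=300, pi=0.0, sigma2=0.0, seed=21))
        fe, fsp, _ = decompose_traces(tr.model, tr.S)
        np.testing.assert_allclose(fe, tr.f_evoked_true, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(fsp, tr.f_spont_true, rtol=1e-10, atol=1e-12)


class TestVarianceComponents:
    def test_matches_sample_moment_oracle(self, rng):
        fe, fsp = rng.random((2, 4, 100))
        ve, vs, ces = variance_components(fe, fsp)
        for n in range(4):
            assert ve[n] == pytest.approx(np.var(fe[n]), rel=1e-12)
            assert vs[n] == pytest.approx(np.var(fsp[n]), rel=1e-12)
            assert ces[n] == pytest.approx(
                np.mean((fe[n] - fe[n].mean()) * (fsp[n] - fsp[n].mean())), rel=1e-10
            )

    def test_variance_identity(self, rng):
        fe, fsp = rng.random((2, 5, 200))
        ve, vs, ces = variance_components(fe, fsp)
        total = np.var(fe + fsp, axis=1)
        np.testing.assert_allclose(total, ve + vs + 2 * ces, rtol=1e-10)

    def test_constant_components_are_zero(self):
        fe = np.full((2, 50), 1.3)
        ve, vs, ces = variance_components(fe, fe * 2)
        np.testing.assert_allclose([ve, vs, ces], 0.0, atol=1e-20)

    def test_identical_components_quadruple_variance(self, rng):
        fe = rng.random((3, 120))
        ve, vs, ces = variance_components(fe, fe + 0.7)
        np.testing.assert_allclose(np.var(2 * fe, axis=1), 4 * ve, rtol=1e-10)
        np.testing.assert_allclose(ve + vs + 2 * ces, 4 * ve, rtol=1e-10)


class TestDriveRatio:
    @pytest.mark.parametrize(
        "ve,vs,expect", [(1.0, 0.0, 1.0), (0.0, 1.0, -1.0), (2.0, 2.0, 0.0), (3.0, 1.0, 0.5)]
    )
    def test_formula(self, ve, vs, expect):
        assert drive_ratio(np.array([ve]), np.array([vs]))[0] == pytest.approx(expect)

    def test_undefined_when_both_zero(self):
        d = drive_ratio(np.zeros(1), np.zeros(1))
        assert np.isnan(d[0])

    def test_bounded(self, rng):
        ve, vs = rng.random((2, 50))
        d = drive_ratio(ve, vs)
        assert np.all(d >= -1) and np.all(d <= 1)


class TestPrivateVariance:
    def test_perfect_fit_zero_private(self, rng):
        x = rng.random((3, 100))
        F = FluorescenceMatrix(x, fs=2.0)
        vc, priv = corrected_variance_and_private(F, x, np.zeros(3))
        np.testing.assert_allclose(priv, 0.0, atol=1e-14)

    def test_pure_noise_neuron_near_zero_in_expectation(self):
        rng = np.random.default_rng(22)
        v, reps, T = 0.2, 200, 500
        noise = rng.normal(0, np.sqrt(v), size=(reps, T))
        F = FluorescenceMatrix(noise, fs=2.0)
        _, priv = corrected_variance_and_private(F, np.zeros((reps, T)), np.full(reps, v))
        assert abs(priv.mean()) < 3 * priv.std() / np.sqrt(reps)

    def test_unmodeled_transient_raises_private_variance(self, rng):
        x = rng.normal(0, 0.1, size=(1, 400))
        bump = np.zeros((1, 400))
        bump[0, 100:120] = 2.0
        F0 = FluorescenceMatrix(x, fs=2.0)
        F1 = FluorescenceMatrix(x + bump, fs=2.0)
        fhat = np.zeros((1, 400))
        _, p0 = corrected_variance_and_private(F0, fhat, np.zeros(1))
        _, p1 = corrected_variance_and_private(F1, fhat, np.zeros(1))
        assert p1[0] > p0[0]


class TestContributionIndex:
    def test_zero_coupling_factor_contributes_nothing(self, small_instance):
        F, model, S = small_instance
        m = model.copy()
        m.B[:, 0] = 0.0
        idx = factor_contribution_index(F, m, S)
        assert idx[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_formula_oracle(self, small_instance):
        F, model, S = small_instance
        idx = factor_contribution_index(F, model, S)
        f_hat = reconstruct(model, S)
        base = _rowwise_corr(F.values, f_hat)
        for l in range(model.n_factors):
            m = model.copy()
            m.B = np.delete(m.B, l, axis=1)
            m.X = np.delete(m.X, l, axis=0)
            cl = _rowwise_corr(F.values, reconstruct(m, S))
            expect = 1.0 - np.mean(cl / base)
            assert idx[l] == pytest.approx(expect, rel=1e-10)

    def test_duplicate_factor_halves_contribution(self, small_instance, rng):
        _, model, S = small_instance
        # data generated by the model itself, so fit correlations are meaningful
        F = FluorescenceMatrix(
            reconstruct(model, S) + rng.normal(0, 0.05, (model.n_neurons, S.n_frames)),
            fs=2.0,
        )
        merged = model.copy()
        merged.B = merged.B[:, :1]
        merged.X = merged.X[:1]
        split = model.copy()
        split.B = np.hstack([merged.B / 2, merged.B / 2])
        split.X = np.vstack([merged.X, merged.X])
        idx_merged = factor_contribution_index(F, merged, S)
        idx_split = factor_contribution_index(F, split, S)
        assert idx_split[0] < idx_merged[0]
        assert idx_split[1] < idx_merged[0]

    def test_empty_for_evoked_only_model(self, small_instance, kernel):
        F, model, S = small_instance
        m = model.copy()
        m.B = np.zeros((m.n_neurons, 0))
        m.X = np.zeros((0, S.n_frames))
        assert factor_contribution_index(F, m, S).size == 0


class TestTuningCurves:
    def test_indicator_window_gives_unit_tuning(self):
        T = 60
        f = np.zeros((1, T))
        onset = 10
        f[0, onset + 4 : onset + 8] = 1.0  # exactly post-onset frames 4..7
        F = FluorescenceMatrix(f, fs=2.0)
        curve = averaged_tuning_curve(F, [(onset, 0)], n_stimuli=1)
        assert curve[0, 0] == pytest.approx(1.0)

    def test_mean_over_presentations(self):
        T = 100
        f = np.zeros((1, T))
        f[0, 14:18] = 0.2
        f[0, 54:58] = 0.4
        F = FluorescenceMatrix(f, fs=2.0)
        curve = averaged_tuning_curve(F, [(10, 0), (50, 0)], n_stimuli=1)
        assert curve[0, 0] == pytest.approx(0.3)

    def test_late_onset_dropped_with_warning(self):
        F = FluorescenceMatrix(np.ones((1, 30)), fs=2.0)
        with pytest.warns(UserWarning, match="dropped"):
            curve = averaged_tuning_curve(F, [(28, 0)], n_stimuli=1)
        assert np.isnan(curve[0, 0])

    def test_model_curve_scaling(self, small_instance):
        F, model, S = small_instance
        curve = model_tuning_curve(model)
        np.testing.assert_allclose(
            curve, model.kernel.peak * model.alpha[:, None] * model.W, rtol=1e-12
        )
        m2 = model.copy()
        m2.alpha = 2 * m2.alpha
        np.testing.assert_allclose(model_tuning_curve(m2), 2 * curve, rtol=1e-12)

    def test_model_curve_zero_filters_flat(self, small_instance):
        F, model, S = small_instance
        m = model.copy()
        m.W = np.zeros_like(m.W)
        assert np.all(model_tuning_curve(m) == 0)

    def test_simulated_evoked_only_matches_scaled_filters(self):
        tr = simulate(zebrafish_like(N=15, T=1500, xi=0.0, pi=0.0, sigma2=0.01, L=1, seed=23))
        onsets = onsets_from_design(tr.S)
        avg = averaged_tuning_curve(tr.F, onsets, tr.S.n_stimuli)
        mdl = model_tuning_curve(tr.model)
        corr = _rowwise_corr(avg, mdl)
        assert np.nanmean(corr) > 0.9


class TestShuffleNull:
    def test_moments_preserved_and_deterministic(self, rng):
        traces = rng.random((3, 120))
        seen = []

        def capture(shuffled):
            seen.append(shuffled.copy())
            return 0.0

        null, p95 = shuffle_null(traces, 5, capture, seed=3)
        for s in seen:
            np.testing.assert_allclose(np.sort(s, axis=1), np.sort(traces, axis=1))
        null2, _ = shuffle_null(traces, 5, lambda s: float(s[0, 0]), seed=3)
        null3, _ = shuffle_null(traces, 5, lambda s: float(s[0, 0]), seed=3)
        np.testing.assert_array_equal(null2, null3)

    def test_percentile_shrinks_with_length(self):
        rng = np.random.default_rng(1)

        def stat(s):
            return abs(np.mean((s[0] - s[0].mean()) * (s[1] - s[1].mean())))

        p95s = {}
        for T in (500, 2000):
            pair = rng.normal(size=(2, T))
            _, p95s[T] = shuffle_null(pair, 1000, stat, seed=2)
        ratio = p95s[500] / p95s[2000]
        assert ratio == pytest.approx(2.0, rel=0.3)  # 1/sqrt(T) scaling


class TestCrossCorrelogram:
    def test_diagonal_unit_at_zero_lag(self, rng):
        X = rng.random((3, 500))
        cc = factor_cross_correlogram(X, max_lag=4)
        for i in range(3):
            assert cc[i, i, 4] == pytest.approx(1.0, rel=1e-10)

    def test_shifted_copy_peaks_at_shift(self, rng):
        x = sample_zero_inflated_exp(0.05, 1.0, (600,), rng)
        s = 3
        X = np.vstack([x, np.roll(x, s)])
        cc = factor_cross_correlogram(X, max_lag=6)
        lags = np.arange(-6, 7)
        assert lags[np.argmax(cc[0, 1])] == s

    def test_independent_factors_within_white_noise_band(self):
        rng = np.random.default_rng(7)
        X = sample_zero_inflated_exp(0.05, 1.0, (3, 3000), rng)
        cc = factor_cross_correlogram(X, max_lag=3)
        off = [np.abs(cc[i, j]).max() for i in range(3) for j in range(3) if i != j]
        assert max(off) < 2.0 / np.sqrt(3000)

    def test_zero_variance_factor_flagged(self):
        X = np.vstack([np.zeros(100), np.random.default_rng(0).random(100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            cc = factor_cross_correlogram(X, max_lag=2)
        assert np.isnan(cc[0, 1]).all()


def test_cumulative_factor_contribution_non_decreasing():
    """Retaining factors one by one never lowers the mean fit correlation,
    and retaining none reproduces the evoked-only reconstruction."""
    from cilva.inference import FitConfig, fit

    tr = simulate(zebrafish_like(N=12, T=600, L=3, seed=15))
    m = fit(tr.F, tr.S, tr.model.kernel,
            FitConfig(L=3, gamma=1.0, max_alternations=15, seed=0))
    corrs = []
    for keep in range(4):
        sub = m.copy()
        sub.B = m.B[:, :keep]
        sub.X = m.X[:keep]
        corrs.append(np.nanmean(_rowwise_corr(tr.F.values, reconstruct(sub, tr.S))))
        if keep == 0:
            evoked_only = m.copy()
            evoked_only.B = np.zeros_like(m.B)
            np.testing.assert_allclose(
                reconstruct(sub, tr.S), reconstruct(evoked_only, tr.S), atol=1e-12
            )
    assert all(np.diff(corrs) >= -1e-9)


def test_full_decompose_on_fitted_simulation(tiny_truth):
    from cilva.inference import FitConfig, fit

    m = fit(tiny_truth.F, tiny_truth.S, tiny_truth.model.kernel,
            FitConfig(L=2, gamma=1.0, max_alternations=8, seed=0))
    dec = decompose(tiny_truth.F, m, tiny_truth.S)
    total = np.var(dec.f_evoked + dec.f_spont, axis=1)
    np.testing.assert_allclose(
        total, dec.var_evoked + dec.var_spont + 2 * dec.cov_es, rtol=1e-10
    )
    d = dec.drive_ratio[~np.isnan(dec.drive_ratio)]
    assert np.all((d >= -1) & (d <= 1))
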