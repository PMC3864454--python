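import math

import numpy as np
import pytest

from trapcycle.detect_harmonic import (
    ArSpectrum,
    ar_spectrum,
    bh_fdr,
    candidate_periods,
    detrend_linear,
    harmonic_fit,
    harmonic_test,
    harmonic_test_experiment,
)
from trapcycle.errors import ContractError


class TestDetrend:
    def test_perfect_line_leaves_zero_residuals(self):
        t = np.arange(10, dtype=float)
        np.testing.assert_allclose(detrend_linear(3 * t + 2, t), 0, atol=1e-10)

    def test_constant_leaves_zero_residuals(self):
        t = np.arange(5, dtype=float)
        np.testing.assert_allclose(detrend_linear(np.full(5, 9.0), t), 0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        t = np.arange(12) * 4.0
        r = detrend_linear(rng.random(12), t)
        assert abs(r.sum()) < 1e-8
        assert abs((r * t).sum()) < 1e-8


class TestArSpectrum:
    def test_ar2_peak_matches_closed_form(self):
        # AR(2) y_t = a1 y_{t-1} + a2 y_{t-2} + e has spectral peak at
        # cos(2*pi*f) = -a1(1-a2)/(4 a2)
        a1, a2 = 0.9, -0.8
        rng = np.random.default_rng(9)
        n = 4000
        y = np.zeros(n)
        e = rng.normal(size=n)
        for i in range(2, n):
            y[i] = a1 * y[i - 1] + a2 * y[i - 2] + e[i]
        y = y[500:]
        spec = ar_spectrum(y, order=2, method="yule_walker")
        f_peak = spec.freqs[np.argmax(spec.density)]
        f_true = math.acos(-a1 * (1 - a2) / (4 * a2)) / (2 * math.pi)
        assert abs(f_peak - f_true) <= 1.5 / 512  # within a grid bin

    def test_pure_cosine_dominant_period_in_range(self):
        t = np.arange(12) * 4.0
        y = detrend_linear(np.cos(2 * np.pi * t / 24.0), t)
        for method in ("yule_walker", "burg"):
            spec = ar_spectrum(y, order=6, method=method)
            period = 4.0 / spec.freqs[np.argmax(spec.density)]
            assert 20.0 <= period <= 28.0

    def test_white_noise_rarely_yields_in_range_candidates(self):
        rng = np.random.default_rng(12)
        t = np.arange(12) * 4.0
        fallback = 0
        n_rep = 200
        for _ in range(n_rep):
            y = detrend_linear(rng.normal(size=12), t)
            spec = ar_spectrum(y, order=6, method="yule_walker")
            if candidate_periods(spec) == [24.0]:
                fallback += 1
        assert fallback >= n_rep // 2

    def test_order_must_be_below_length(self):
        with pytest.raises(ContractError):
            ar_spectrum(np.random.default_rng(0).normal(size=6), order=6)


class TestCandidatePeriods:
    def _spec(self, density):
        freqs = np.arange(1, len(density) + 1) / (2.0 * len(density))
        return ArSpectrum(freqs=freqs, density=np.asarray(density, float), order=6,
                          method="yule_walker")

    def test_single_peak_at_24(self):
        freqs = np.arange(1, 513) / 1024.0
        density = np.exp(-((freqs - 4.0 / 24.0) ** 2) / 1e-4)
        spec = ArSpectrum(freqs=freqs, density=density, order=6, method="yule_walker")
        cands = candidate_periods(spec)
        assert len(cands) == 1
        assert cands[0] == pytest.approx(24.0, abs=0.2)

    def test_no_in_range_peak_falls_back_to_24(self):
        spec = self._spec(np.linspace(1.0, 0.1, 512))  # monotone, only edge max
        assert candidate_periods(spec) == [24.0]

    def test_two_peaks_sorted_by_power(self):
        freqs = np.arange(1, 513) / 1024.0
        density = np.exp(-((freqs - 4.0 / 21.0) ** 2) / 3e-5) + 2 * np.exp(
            -((freqs - 4.0 / 26.0) ** 2) / 3e-5
        )
        spec = ArSpectrum(freqs=freqs, density=density, order=6, method="yule_walker")
        cands = candidate_periods(spec)
        assert len(cands) == 2
        assert cands[0] == pytest.approx(26.0, abs=0.3)  # stronger peak first
        assert cands[1] == pytest.approx(21.0, abs=0.3)

    def test_flagged_spectrum_falls_back(self):
        spec = ArSpectrum(
            freqs=np.linspace(0.01, 0.5, 512), density=np.ones(512), order=6,
            method="yule_walker", flagged=True,
        )
        assert candidate_periods(spec) == [24.0]


class TestHarmonicFit:
    def test_noiseless_cosine_recovery(self, design_times):
        y = 5.0 + 2.0 * np.cos(2 * np.pi * (design_times - 8.0) / 24.0)
        res = harmonic_fit(y, design_times, [24.0])
        assert res.amplitude == pytest.approx(2.0, abs=1e-6)
        assert res.phase == pytest.approx(8.0, abs=1e-6)
        assert res.p < 1e-6

    def test_constant_series_is_null(self, design_times):
        res = harmonic_fit(np.full(12, 4.0), design_times, [24.0])
        assert res.p == 1.0 and res.amplitude == 0.0 and res.f_statistic == 0.0

    def test_coefficients_match_normal_equations(self, design_times):
        rng = np.random.default_rng(7)
        y = rng.random(12) * 10
        res = harmonic_fit(y, design_times, [24.0])
        w = 2 * np.pi / 24.0
        X = np.column_stack(
            [np.ones(12), np.cos(w * design_times), np.sin(w * design_times)]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.amplitude == pytest.approx(math.hypot(beta[1], beta[2]), abs=1e-9)

    def test_duplicate_periods_rejected(self, design_times):
        with pytest.raises(ContractError, match="duplicate"):
            harmonic_fit(np.arange(12.0), design_times, [24.0, 24.0])


class TestBhFdr:
    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            bh_fdr([0.5, 1.2])


class TestHarmonicTest:
    def test_noiseless_cosine_end_to_end(self, design_times):
        y = 5.0 + 2.0 * np.cos(2 * np.pi * (design_times - 8.0) / 24.0)
        res = harmonic_test(y, design_times)
        assert res.p < 0.021
        assert 22.0 <= res.period <= 26.0
        assert res.phase == pytest.approx(8.0, abs=0.5)
        assert res.amplitude == pytest.approx(2.0, abs=1e-6)

    def test_constant_gene_is_null(self, design_times):
        assert harmonic_test(np.full(12, 6.0), design_times).p == 1.0

    def test_experiment_level_q_fills_bh(self, design_times):
        rng = np.random.default_rng(5)
        vals = rng.random((20, 12))
        vals[0] = 100 + 60 * np.cos(2 * np.pi * (design_times - 4.0) / 24.0)
        res = harmonic_test_experiment(vals, design_times, [f"g{i}" for i in range(20)])
        q = bh_fdr([r.p for r in res])
        np.testing.assert_allclose([r.q for r in res], q)
        assert res[0].q == min(r.q for r in res)
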