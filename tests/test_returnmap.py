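"""Smoothing, peak detection, windowed fitting, selection, classification."""

import numpy as np
import pytest
from scipy import integrate, stats

from retmap import returnmap as rm
from retmap import synthetic as syn


def sg_oracle(x, order=2, window=9):
    """Per-sample polynomial least squares on the (truncated) neighborhood."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        t = np.arange(lo, hi) - i
        deg = min(order, hi - lo - 1)
        coef = np.polynomial.polynomial.polyfit(t, x[lo:hi], deg)
        out[i] = coef[0]
    return out


class TestSavitzkyGolay:
    def test_reproduces_quadratics_exactly(self):
        t = np.linspace(0, 1, 60)
        x = 1.3 * t**2 - 0.4 * t + 0.2
        np.testing.assert_allclose(rm.smooth_sg(x), x, atol=1e-12)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(rm.smooth_sg(np.full(30, 0.7)), 0.7, atol=1e-14)

    def test_matches_least_squares_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(9, 60))
            np.testing.assert_allclose(rm.smooth_sg(x), sg_oracle(x), atol=1e-10)

    @pytest.mark.parametrize("window", [8, 2])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            rm.smooth_sg(np.ones(30), window=window)


class TestDetectPeaks:
    def test_strict_maxima(self):
        s = np.array([0, 1, 0, 2, 0.0])
        pk = rm.detect_peaks(s, np.arange(5) / 100.0)
        assert pk.indices.tolist() == [1, 3]

    def test_monotone_empty(self):
        pk = rm.detect_peaks(np.linspace(0, 1, 20), np.arange(20) / 100.0)
        assert len(pk) == 0

    def test_min_separation_keeps_larger(self):
        s = np.array([0, 1.0, 0.9, 1.2, 0, 0, 0.5, 0])
        t = np.arange(s.size) * 0.01
        pk = rm.detect_peaks(s, t, min_separation_s=0.03)
        assert pk.indices.tolist() == [3, 6]


class TestBuildReturnMap:
    def test_pairs_consecutive_peaks(self):
        pts = rm.build_return_map(np.array([1.0, 0.8, 0.7]))
        np.testing.assert_allclose(pts, [[1.0, 0.8], [0.8, 0.7]])

    def test_constant_peaks_on_identity(self):
        pts = rm.build_return_map(np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(pts[:, 0], pts[:, 1])

    def test_point_count(self, rng):
        for m in (2, 5, 9):
            assert rm.build_return_map(rng.uniform(0.2, 0.8, m)).shape == (m - 1, 2)

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            rm.build_return_map(np.array([1.0]))


class TestFitWindow:
    def test_exact_linear_fit(self):
        x = np.array([0.9, 0.75, 0.675])
        pts = np.column_stack([x, 0.5 * x + 0.3])
        fit = rm.fit_window(pts, "linear")
        np.testing.assert_allclose(fit.params, (0.5, 0.3), atol=1e-12)
        assert fit.chi2 < 1e-16 and fit.q > 1 - 1e-9

    def test_q_matches_chi2_tail_integration(self):
        # independent oracle: numerical integration of the chi^2 density
        for chi2, dof in [(0.1, 1), (2.3, 3), (7.7, 4)]:
            density = stats.chi2(df=dof).pdf
            expected, _ = integrate.quad(density, chi2, np.inf)
            np.testing.assert_allclose(rm.gof_q(chi2, dof), expected, atol=1e-9)
        np.testing.assert_allclose(rm.gof_q(0.1, 1), 0.7518, atol=2e-4)

    def test_exponential_parameter_recovery(self, rng):
        x = np.linspace(0.2, 0.9, 6)
        y = 0.5 * np.exp(0.8 * x) + rng.normal(0, 1e-4, x.size)
        fit = rm.fit_window(np.column_stack([x, y]), "exponential", sigma=1e-4)
        np.testing.assert_allclose(fit.params, (0.5, 0.8), atol=3e-3)

    def test_logarithmic_closed_form(self):
        x = np.array([0.3, 0.5, 0.7, 0.9])
        y = 0.8 + 0.4 * np.log(x)
        fit = rm.fit_window(np.column_stack([x, y]), "logarithmic")
        np.testing.assert_allclose(fit.params, (0.8, 0.4), atol=1e-10)

    def test_singular_design_rejected(self):
        pts = np.column_stack([np.full(4, 0.5), np.linspace(0.4, 0.6, 4)])
        with pytest.raises(rm.FitError, match="singular"):
            rm.fit_window(pts, "linear")

    def test_q_monotone_in_chi2(self):
        qs = [rm.gof_q(c, 3) for c in (0.0, 0.5, 2.0, 8.0, 20.0)]
        assert qs[0] == 1.0
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestScanWindows:
    def test_window_count_for_five_points(self):
        x = np.array([0.9, 0.75, 0.675, 0.6375, 0.61875, 0.609375])
        pts = np.column_stack([x[:-1], x[1:]])
        cands = rm.scan_windows(pts)
        linear = {(c.start, c.length) for c in cands if c.family == "linear"}
        assert linear == {(0, 3), (1, 3), (2, 3), (0, 4), (1, 4), (0, 5)}

    def test_planted_regime_full_window_survives(self):
        reg = syn.RegimeSpec("linear", (0.5, 0.3), 7, initial_peak=0.95)
        peaks, _ = syn.generate_peak_sequence(syn.SyntheticSpec(regimes=(reg,)))
        cands = rm.scan_windows(rm.build_return_map(peaks))
        full = [c for c in cands if c.length == 6 and c.family == "linear"]
        assert len(full) == 1 and full[0].q > 1 - 1e-9

    def test_identity_crossing_exponential_excluded(self):
        # a e^{bx} with a fixed point inside the observed range
        a, b = 0.3, 1.2  # tangency gap dips negative near x ~ 0.85
        x = np.linspace(0.55, 1.05, 5)
        y = a * np.exp(b * x)
        assert np.any(np.sign(y - x)[:-1] != np.sign(y - x)[1:])  # crosses
        pts = np.column_stack([x, y])
        cands = rm.scan_windows(pts)
        # any window whose observed range brackets the crossing is excluded
        for c in cands:
            if c.family != "linear":
                win = pts[c.start : c.stop, 0]
                gap = c.predict(np.linspace(win.min(), win.max(), 100))
                gap = gap - np.linspace(win.min(), win.max(), 100)
                assert not np.any(gap[:-1] * gap[1:] <= 0)
        full = [c for c in cands if c.family == "exponential" and c.length == 5]
        assert full == []


class TestSelectFits:
    def _mk(self, start, length, chi2=0.0, family="linear"):
        return rm.FitResult(family=family, params=(0.5, 0.3), start=start,
                            length=length, chi2=chi2, dof=length - 2,
                            q=rm.gof_q(chi2, length - 2))

    def test_longer_window_displaces_overlapping_shorter(self):
        seg = rm.select_fits([self._mk(0, 5), self._mk(1, 3, chi2=0.0)])
        assert [(f.start, f.length) for f in seg.fits] == [(0, 5)]

    def test_disjoint_windows_coexist(self):
        seg = rm.select_fits([self._mk(0, 3), self._mk(3, 3)])
        assert len(seg.fits) == 2

    def test_equal_length_better_fit_wins(self):
        good = self._mk(0, 4, chi2=0.1)
        bad = self._mk(1, 4, chi2=3.0)
        seg = rm.select_fits([bad, good], tie_break="higher_q")
        assert seg.fits == [good]

    def test_parsimony_requires_margin_for_curved(self):
        lin = self._mk(0, 4, chi2=2.0)
        exp_slightly_better = self._mk(0, 4, chi2=1.0, family="exponential")
        exp_clearly_better = self._mk(0, 4, chi2=-0.0, family="exponential")
        assert rm.select_fits([lin, exp_slightly_better]).fits == [lin]
        seg = rm.select_fits([lin, exp_clearly_better])
        # margin 2.0 < 2.5 handicap: linear still wins
        assert seg.fits == [lin]
        exp_dominant = self._mk(0, 4, chi2=0.0, family="exponential")
        lin_poor = self._mk(0, 4, chi2=3.0)
        assert rm.select_fits([lin_poor, exp_dominant]).fits == [exp_dominant]

    def test_two_regime_roundtrip(self):
        # well-separated attractor -> rotational repeller switch
        regs = (
            syn.RegimeSpec("linear", (0.5, 0.35), 5, initial_peak=0.95),
            syn.RegimeSpec("linear", (-1.35, 1.41), 4),
        )
        peaks, truth = syn.generate_peak_sequence(syn.SyntheticSpec(regimes=regs))
        seg = rm.analyze_points(rm.build_return_map(peaks))
        assert seg.n_functions == 2
        assert [f.cls for f in seg.fits] == ["Aa", "Rr"]
        np.testing.assert_allclose(
            [f.params[0] for f in seg.fits], [0.5, -1.35], atol=1e-9
        )
        assert [(f.start, f.stop) for f in seg.fits] == [(0, 4), (4, 8)]

    def test_accepted_windows_never_overlap(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 5))
            regs = syn.random_switching_regimes(rng, n)
            peaks, _ = syn.generate_peak_sequence(
                syn.SyntheticSpec(regimes=tuple(regs), noise_sigma=0.01,
                                  seed=int(rng.integers(2**31)))
            )
            seg = rm.analyze_points(rm.build_return_map(peaks))
            spans = sorted((f.start, f.stop) for f in seg.fits)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 <= s1
            assert all(f.length in rm.WINDOW_LENGTHS for f in seg.fits)


class TestClassification:
    @pytest.mark.parametrize(
        "c, d, cls, fp",
        [
            (0.5, 0.3, "Aa", 0.6),
            (-0.5, 0.9, "Ar", 0.6),
            (1.3, -0.18, "Ra", 0.6),
            (-1.5, 1.5, "Rr", 0.6),
        ],
    )
    def test_linear_classes(self, c, d, cls, fp):
        fit = rm.FitResult(family="linear", params=(c, d), start=0, length=3,
                           chi2=0.0, dof=1, q=1.0)
        out = rm.classify_fit(fit)
        assert out.cls == cls
        np.testing.assert_allclose(out.fixed_point, fp)

    def test_intermittency_labels(self):
        for fam, cls in (("exponential", "Exp"), ("logarithmic", "Log")):
            fit = rm.FitResult(family=fam, params=(0.5, 0.8), start=0, length=3,
                               chi2=0.0, dof=1, q=1.0)
            assert rm.classify_fit(fit).cls == cls

    def test_unit_slope_flagged_degenerate(self):
        fit = rm.FitResult(family="linear", params=(1.0 + 1e-12, 0.1), start=0,
                           length=3, chi2=0.0, dof=1, q=1.0)
        out = rm.classify_fit(fit)
        assert out.degenerate and out.cls is None

    def test_agreement_with_iteration_oracle(self, rng):
        # iterate from fixed_point +/- 0.01; distance shrinks iff attractor
        for _ in range(200):
            c = float(rng.uniform(-2, 2))
            if abs(abs(c) - 1.0) < 1e-3 or abs(c) < 1e-3:
                continue
            d = float(rng.uniform(-0.5, 0.5))
            fit = rm.classify_fit(
                rm.FitResult(family="linear", params=(c, d), start=0, length=3,
                             chi2=0.0, dof=1, q=1.0)
            )
            fp = fit.fixed_point
            y = fp + 0.01
            for _ in range(50):
                y = c * y + d
            converges = abs(y - fp) < 0.01
            assert converges == (fit.cls in ("Aa", "Ar"))
            assert (fit.cls in ("Aa", "Ra")) == (c > 0)


class TestSigmaEstimation:
    def test_recovers_planted_noise_scale(self, rng):
        scenes = []
        for _ in range(40):
            reg = syn.random_single_regime(rng, "linear", n_peaks=7)
            peaks, _ = syn.generate_peak_sequence(
                syn.SyntheticSpec(regimes=(reg,), noise_sigma=0.02,
                                  seed=int(rng.integers(2**31)))
            )
            scenes.append(rm.build_return_map(peaks))
        est = rm.estimate_sigma(scenes)
        assert 0.01 < est < 0.06
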