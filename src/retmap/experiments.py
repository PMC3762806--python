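"""Self-contained verification experiments over the analysis pipeline.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and measures recovery of the planted truth.  They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np

from . import pipeline as pl
from . import preprocessing as prep
from . import returnmap as rm
from . import synthetic as syn
from . import transitions as tr

__all__ = [
    "sg_oracle_deviation",
    "fisher_oracle_deviation",
    "classification_dynamics_agreement",
    "parameter_recovery",
    "segmentation_recovery",
    "transition_recovery",
    "quick_detach_fidelity",
    "determinism_check",
]


def sg_oracle_deviation(n_series: int = 100, seed: int = 0) -> float:
    """Max |smooth_sg − per-window polynomial LSQ oracle| over random series."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_series):
        x = rng.normal(size=int(rng.integers(9, 80)))
        smoothed = rm.smooth_sg(x)
        half = 4
        for i in range(x.size):
            lo, hi = max(0, i - half), min(x.size, i + half + 1)
            t = np.arange(lo, hi) - i
            deg = min(2, hi - lo - 1)
            coef = np.polynomial.polynomial.polyfit(t, x[lo:hi], deg)
            worst = max(worst, abs(smoothed[i] - coef[0]))
    return worst


def _fisher_fraction_oracle(table) -> float:
    """Independent enumeration via the column-margin hypergeometric identity."""
    (a, b), (c, d) = table
    r1, r2, s, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or s == 0 or s == n:
        return 1.0
    denom = math.comb(n, r1)
    p_obs = Fraction(math.comb(s, a) * math.comb(n - s, b), denom)
    total = Fraction(0)
    for k in range(max(0, s - r2), min(r1, s) + 1):
        p = Fraction(math.comb(s, k) * math.comb(n - s, r1 - k), denom)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def fisher_oracle_deviation(max_margin: int = 15) -> float:
    """Max |fisher_exact_2x2 − exact enumeration| over all small tables."""
    worst = 0.0
    m = max_margin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate margins are part of the sweep
        return _fisher_sweep(m)


def _fisher_sweep(m: int) -> float:
    worst = 0.0
    for a in range(m + 1):
        for b in range(m + 1 - a):
            for c in range(m + 1 - a):
                for d in range(m + 1 - b):
                    if c + d > m:
                        continue
                    p = tr.fisher_exact_2x2([[a, b], [c, d]])
                    worst = max(worst, abs(p - _fisher_fraction_oracle([[a, b], [c, d]])))
    return worst


def classification_dynamics_agreement(n_maps: int = 1000, seed: int = 0) -> float:
    """Fraction of random linear maps where the class label matches iteration.

    Iterating from fixed_point ± 0.01 for 50 steps converges (distance
    shrinks below the start) iff the classified label is an attractor;
    asymptotic vs rotational must match the slope sign.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    done = 0
    while done < n_maps:
        c = float(rng.uniform(-2.0, 2.0))
        if abs(c) < 1e-6 or abs(abs(c) - 1.0) < 1e-6:
            continue
        d = float(rng.uniform(-0.5, 0.5))
        fit = rm.classify_fit(
            rm.FitResult(family="linear", params=(c, d), start=0, length=3,
                         chi2=0.0, dof=1, q=1.0)
        )
        ok = True
        for sign in (+1, -1):
            y = fit.fixed_point + sign * 0.01
            for _ in range(50):
                y = c * y + d
            converges = abs(y - fit.fixed_point) < 0.01
            ok &= converges == (fit.cls in ("Aa", "Ar"))
        ok &= (fit.cls in ("Aa", "Ra")) == (c > 0)
        agree += ok
        done += 1
    return agree / n_maps


def parameter_recovery(
    n_per_family: int = 200, noise_sigma: float = 0.01, seed: int = 42
) -> dict:
    """Fit single-regime scenes and measure family/parameter recovery."""
    rng = np.random.default_rng(seed)
    slope_errs: list[float] = []
    fp_errs: list[float] = []
    total = 0
    misclassified = 0
    for family in syn.FAMILIES:
        for _ in range(n_per_family):
            regime = syn.random_single_regime(rng, family, n_peaks=7)
            peaks, _ = syn.generate_peak_sequence(
                syn.SyntheticSpec(regimes=(regime,), noise_sigma=noise_sigma,
                                  seed=int(rng.integers(2**31)))
            )
            seg = rm.analyze_points(rm.build_return_map(peaks))
            total += 1
            if not seg.fits:
                misclassified += 1
                continue
            best = max(seg.fits, key=lambda f: f.length)
            if best.family != family:
                misclassified += 1
                continue
            if family == "linear":
                slope_errs.append(abs(best.params[0] - regime.params[0]))
                fp_errs.append(abs(best.fixed_point - regime.fixed_point))
    return {
        "median_abs_slope_error": float(np.median(slope_errs)),
        "median_fixed_point_error": float(np.median(fp_errs)),
        "family_misclassification_pct": 100.0 * misclassified / total,
        "n": total,
    }


def segmentation_recovery(
    n_scenes: int = 100, noise_sigma: float = 0.01, seed: int = 42
) -> dict:
    """Plant 2–4 switching regimes per scene; recover count and classes."""
    rng = np.random.default_rng(seed)
    count_ok = 0
    class_ok = 0
    matched = 0
    for _ in range(n_scenes):
        n_regimes = int(rng.integers(2, 5))
        regimes = syn.random_switching_regimes(rng, n_regimes)
        peaks, truth = syn.generate_peak_sequence(
            syn.SyntheticSpec(regimes=tuple(regimes), noise_sigma=noise_sigma,
                              seed=int(rng.integers(2**31)))
        )
        seg = rm.analyze_points(rm.build_return_map(peaks))
        if seg.n_functions == n_regimes:
            count_ok += 1
        for r, (p0, p1) in enumerate(truth.point_boundaries()):
            best, overlap = None, 0
            for fit in seg.fits:
                ov = max(0, min(p1, fit.stop) - max(p0, fit.start))
                if ov > overlap:
                    best, overlap = fit, ov
            if best is None:
                continue
            matched += 1
            c = regimes[r].params[0]
            want = "Aa" if 0 < c < 1 else "Ar" if -1 < c < 0 else "Ra" if c > 1 else "Rr"
            if best.cls == want:
                class_ok += 1
    return {
        "count_accuracy_pct": 100.0 * count_ok / n_scenes,
        "class_accuracy_pct": 100.0 * class_ok / max(matched, 1),
        "n": n_scenes,
    }


def transition_recovery(n_per_condition: int = 1000, seed: int = 7) -> dict:
    """Re-estimate a known second-order chain from generated label scenes."""
    truth = {"FF": 0.8, "FN": 0.35, "NF": 0.6, "NN": 0.25}
    scenes = syn.generate_label_sequences(truth, n_per_condition, seed=seed)
    m3 = tr.third_order(scenes)
    errors = {
        sub: abs(m3.probs[sub]["F"] - p) for sub, p in truth.items()
    }
    m2_from_3 = m3.marginalized()
    m2_direct = tr.second_order(scenes, skip_first_pair=True)
    return {
        "max_abs_probability_error": max(errors.values()),
        "marginalization_exact": m2_from_3.counts == m2_direct.counts,
        "n": sum(sum(r.values()) for r in m3.counts.values()),
    }


def quick_detach_fidelity() -> dict:
    """Constructed worked set for the 1 m / 1 500 ms rule and the 4-peak rule."""
    fs = 100.0
    cases = [  # (spread_m, gap_s, should_remove)
        (1.2, 1.0, True),
        (1.05, 1.4, True),
        (1.2, 2.0, False),
        (0.8, 0.5, False),
        (0.95, 1.0, False),
    ]
    correct = 0
    for spread, gap, should_remove in cases:
        n_gap = int(gap * fs)
        d = np.concatenate(
            [[1.2, 1.0], np.linspace(1.0, 1.0 + spread, n_gap)[1:],
             [1.0 + spread - 0.2, 0.5, 0.8]]
        )
        ipd = prep.IpdSeries(time=np.arange(d.size) / fs, d=d)
        pos, neg = prep.find_ipd_peaks(ipd)
        pos2, neg2 = prep.remove_quick_detachments(pos, neg, ipd)
        removed = (1 not in neg2) and (n_gap not in pos2)
        correct += removed == should_remove
    # scenes with fewer than four positive peaks never appear
    spec = syn.SyntheticSpec(
        regimes=(syn.RegimeSpec("linear", (0.5, 0.3), 3, initial_peak=0.9),)
    )
    traj, _ = syn.generate_match(spec)
    scenes = prep.split_scenes(prep.compute_ipd(traj), close_threshold_m=0.73)
    return {
        "rule_accuracy_pct": 100.0 * correct / len(cases),
        "short_scene_leak_count": len(scenes),
        "n": len(cases),
    }


def determinism_check(seed: int = 0) -> bool:
    """Two identical runs must serialize byte-identically."""
    cfg = pl.PipelineConfig(seed=seed, sim_mode="fn_mixture", n_matches=2,
                            scenes_per_match=5, noise_sigma=0.01)
    r1 = pl.report_to_json(pl.run_pipeline(cfg))
    r2 = pl.report_to_json(pl.run_pipeline(cfg))
    return r1 == r2
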