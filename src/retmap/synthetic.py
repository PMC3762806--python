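"""Synthetic two-agent matches with planted return-map dynamics.

The analysis pipeline assumes that successive peak amplitudes of the
(normalized) interpersonal distance follow piecewise simple maps
``y_{n+1} = f(y_n)`` — linear (attractors/repellers), exponential or
logarithmic (intermittency) — with a discrete "higher module" switching
between maps at peak events.  This module realizes exactly that structure
with known ground truth, so every downstream stage (peak detection,
windowed fitting, segmentation, F/N labeling, transition statistics) can
be verified without the original motion-capture recordings.

Amplitudes are dimensionless (normalized) and must stay inside the open
interval (0, 1.5); a regime whose iteration escapes that band raises
:class:`GenerationError` rather than silently producing unusable scenes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FAMILIES",
    "GenerationError",
    "RegimeSpec",
    "SyntheticSpec",
    "GroundTruth",
    "MatchGroundTruth",
    "generate_peak_sequence",
    "render_continuous_scene",
    "generate_match",
    "generate_label_sequences",
    "random_single_regime",
    "random_switching_regimes",
    "markov_regime_chain",
]

FAMILIES = ("linear", "exponential", "logarithmic")

#: generated amplitudes must stay inside this open band
AMPLITUDE_BAND = (0.0, 1.5)


class GenerationError(RuntimeError):
    """Planted dynamics left the admissible amplitude band."""


@dataclass(frozen=True)
class RegimeSpec:
    """One return-map regime.

    Parameters
    ----------
    family:
        ``"linear"`` (``f(x) = c·x + d``), ``"exponential"``
        (``f(x) = a·exp(b·x)``) or ``"logarithmic"`` (``f(x) = a + b·ln x``).
    params:
        ``(c, d)`` for linear, ``(a, b)`` otherwise.
    n_peaks:
        Number of peaks this regime contributes (≥ 3).  When
        ``initial_peak`` is given it counts as the first of these.
    initial_peak:
        Starting amplitude in (0, 1).  ``None`` chains the regime onto the
        last peak of the preceding regime.
    label:
        Optional planted F/N state label carried into the ground truth.
    """

    family: str
    params: tuple[float, float]
    n_peaks: int
    initial_peak: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.params) != 2:
            raise ValueError("params must be a (2,) coefficient pair")
        if self.n_peaks < 3:
            raise ValueError("a regime needs at least 3 peaks")
        if self.family == "linear" and abs(self.params[0] - 1.0) < 1e-12:
            raise ValueError("linear slope c = 1 has no identity crossing")
        if self.initial_peak is not None and not (
            AMPLITUDE_BAND[0] < self.initial_peak < AMPLITUDE_BAND[1]
        ):
            raise ValueError("initial_peak must lie inside the amplitude band")

    def evaluate(self, x: np.ndarray | float) -> np.ndarray | float:
        a, b = self.params
        if self.family == "linear":
            return a * np.asarray(x, dtype=float) + b
        if self.family == "exponential":
            return a * np.exp(b * np.asarray(x, dtype=float))
        return a + b * np.log(np.asarray(x, dtype=float))

    @property
    def fixed_point(self) -> float | None:
        """Identity-line crossing ``d/(1-c)`` (linear maps only)."""
        if self.family != "linear":
            return None
        c, d = self.params
        return d / (1.0 - c)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic scene (or scene template).

    ``oscillation_period`` is the peak-to-peak interval in seconds (the
    study's scenes oscillate at roughly 2 s per approach cycle, giving the
    observed ≈11 s mean scene length at 5–6 peaks).  ``noise_sigma`` is the
    std of additive observation noise applied to peak amplitudes, in
    normalized units.
    """

    regimes: tuple[RegimeSpec, ...]
    oscillation_period: float = 2.0
    sampling_rate: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0
    trough_fraction: float = 0.45
    process_noise: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimes", tuple(self.regimes))
        if not self.regimes:
            raise ValueError("at least one regime is required")
        if self.regimes[0].initial_peak is None:
            raise ValueError("the first regime must declare initial_peak")
        if self.sampling_rate <= 2.0 / self.oscillation_period:
            raise ValueError("sampling_rate must exceed 2/oscillation_period")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 < self.trough_fraction < 1.0):
            raise ValueError("trough_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth for one scene's peak sequence.

    ``regime_of_peak[i]`` is the index of the regime whose map produced
    peak ``i`` (the first, externally seeded peak belongs to regime 0).
    Return-map point ``i`` pairs peaks ``(i, i+1)`` and therefore lies on
    the map of ``regime_of_peak[i+1]``.
    """

    clean_peaks: np.ndarray
    regime_of_peak: np.ndarray
    families: list[str]
    fixed_points: list[float | None]
    peak_boundaries: list[tuple[int, int]]  # half-open, per regime
    fn_labels: list[str] | None = None
    peak_times: np.ndarray | None = None

    @property
    def regime_of_point(self) -> np.ndarray:
        """Regime index of each return-map point (length ``n_peaks - 1``)."""
        return self.regime_of_peak[1:]

    def point_boundaries(self) -> list[tuple[int, int]]:
        """Half-open return-map point ranges per regime."""
        out = []
        rop = self.regime_of_point
        for r in range(len(self.families)):
            idx = np.flatnonzero(rop == r)
            if idx.size:
                out.append((int(idx[0]), int(idx[-1]) + 1))
            else:
                out.append((0, 0))
        return out


@dataclass
class MatchGroundTruth:
    """Ground truth for a whole simulated match."""

    scenes: list[GroundTruth]
    scene_sample_ranges: list[tuple[int, int]]
    strike_sample_indices: list[int]
    ipd_normalized: np.ndarray
    ipd_meters: np.ndarray


def _check_band(value: float, regime_index: int, regime: RegimeSpec) -> None:
    lo, hi = AMPLITUDE_BAND
    if not (lo < value < hi) or not np.isfinite(value):
        raise GenerationError(
            f"regime {regime_index} ({regime.family}, params={regime.params}) "
            f"produced amplitude {value!r} outside ({lo}, {hi})"
        )


def generate_peak_sequence(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Iterate the planted maps into a concatenated peak sequence.

    Returns the observed (possibly noisy) amplitudes and the ground truth
    holding the noiseless ones.  Observation noise is drawn after the
    iteration; with ``spec.process_noise`` the draw instead perturbs the
    state fed to the next iteration.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    clean: list[float] = []
    regime_of_peak: list[int] = []
    boundaries: list[tuple[int, int]] = []
    labels: list[str] = []
    any_label = False

    for r, regime in enumerate(spec.regimes):
        start = len(clean)
        if regime.initial_peak is not None:
            y = float(regime.initial_peak)
            _check_band(y, r, regime)
            clean.append(y)
            regime_of_peak.append(r)
            n_new = regime.n_peaks - 1
        else:
            if not clean:
                raise ValueError("first regime must declare initial_peak")
            y = clean[-1]
            n_new = regime.n_peaks
        for _ in range(n_new):
            y = float(regime.evaluate(y))
            _check_band(y, r, regime)
            if spec.process_noise and spec.noise_sigma > 0:
                y += float(rng.normal(0.0, spec.noise_sigma))
                _check_band(y, r, regime)
            clean.append(y)
            regime_of_peak.append(r)
        boundaries.append((start, len(clean)))
        if regime.label is not None:
            any_label = True
        labels.extend([regime.label or ""] * (len(clean) - start))

    clean_arr = np.asarray(clean, dtype=float)
    if spec.noise_sigma > 0 and not spec.process_noise:
        observed = clean_arr + rng.normal(0.0, spec.noise_sigma, size=clean_arr.shape)
    else:
        observed = clean_arr.copy()

    truth = GroundTruth(
        clean_peaks=clean_arr,
        regime_of_peak=np.asarray(regime_of_peak, dtype=int),
        families=[reg.family for reg in spec.regimes],
        fixed_points=[reg.fixed_point for reg in spec.regimes],
        peak_boundaries=boundaries,
        fn_labels=labels if any_label else None,
    )
    return observed, truth


def _half_cosine(n: int, lo: float, hi: float, rising: bool) -> np.ndarray:
    """Half-cosine arc over ``n`` samples, excluding the starting sample.

    The previous segment owns the shared endpoint, so concatenated arcs
    tile the grid exactly; the returned arc ends exactly at its target
    value (``lo`` when falling, ``hi`` when rising) with zero slope.
    """
    phase = np.linspace(0.0, np.pi, n + 1)
    full = lo + (hi - lo) * (1.0 + np.cos(phase)) / 2.0  # hi -> lo inclusive
    return full[::-1][1:] if rising else full[1:]


def render_continuous_scene(
    peaks: np.ndarray, spec: SyntheticSpec, pad: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a peak sequence as a smooth sampled oscillation.

    Between consecutive peaks a trough is placed midway at
    ``trough_fraction`` of the smaller adjacent peak amplitude (so the
    trough always lies below both peaks), with half-cosine arcs on both
    sides (zero slope at every peak and trough, so the peaks are exact
    strict local maxima of the sampled signal).  On non-increasing peak
    runs the rising arc into each peak is exactly proportional to that
    peak's amplitude, which keeps the downstream composite state's peak
    amplitudes an exact affine image of the planted peaks.

    With ``pad`` (the default) a rising lead-in arc and a falling lead-out
    arc are added at negative / trailing times so that the first and last
    peaks are interior local maxima; the first peak sits at t = 0 either
    way.  :func:`generate_match` supplies its own context and renders
    unpadded.

    Returns ``(time, signal, peak_sample_indices)``.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.ndim != 1 or peaks.size < 3:
        raise ValueError("need at least 3 peaks to render a scene")
    fs = spec.sampling_rate
    half = int(round(spec.oscillation_period * fs / 2.0))
    if half < 9:
        raise ValueError(
            "oscillation half-period shorter than the 9-sample smoothing window"
        )
    segments = [np.array([peaks[0]])]
    peak_idx = [0]
    pos = 0
    for i in range(peaks.size - 1):
        trough = spec.trough_fraction * min(peaks[i], peaks[i + 1])
        segments.append(_half_cosine(half, trough, peaks[i], rising=False))
        segments.append(_half_cosine(half, trough, peaks[i + 1], rising=True))
        pos += 2 * half
        peak_idx.append(pos)
    lead = 0
    if pad:
        lead_arc = _half_cosine(half, spec.trough_fraction * peaks[0], peaks[0],
                                rising=True)
        tail_arc = _half_cosine(half, spec.trough_fraction * peaks[-1], peaks[-1],
                                rising=False)
        segments = [lead_arc[:-1]] + segments + [tail_arc]
        lead = half - 1
    signal = np.concatenate(segments)
    time = (np.arange(signal.size) - lead) / fs
    peak_idx = [p + lead for p in peak_idx]
    return time, signal, np.asarray(peak_idx, dtype=int)


@dataclass(frozen=True)
class MatchLayout:
    """Geometry constants mapping normalized amplitude to meters.

    Defaults place engagement peaks near 1.5–1.7 m, within-scene troughs
    above 0.8 m and strike close approaches at 0.65 m, so ordinary
    approach/detach half-cycles spread under 1 m per half-period and
    strikes sit cleanly below every ordinary trough.  Post-strike
    re-engagement takes a full oscillation period, slower than the 1.5 s
    quick-detachment cutoff.
    """

    baseline_m: float = 0.65
    meters_per_unit: float = 1.1
    strike_value: float = 0.0  # normalized depth of the strike close approach
    recovery_periods: float = 1.0  # slow re-engagement after a strike


def generate_match(
    specs: SyntheticSpec | Sequence[SyntheticSpec],
    match_id: str = "synthetic",
    group: str = "synthetic",
    layout: MatchLayout | None = None,
):
    """Realize one or more scene specs as a full two-agent match.

    Scenes are concatenated with a strike-like close approach between them:
    a half-cosine descent from the scene's last peak to a deep minimum (the
    "strike"), then a slow recovery ascent into the next scene's first
    peak.  The recovery takes ``recovery_periods`` full oscillation periods
    so it is not caught by the quick-detachment rule.

    The normalized trace is mapped to meters and realized as two agents
    symmetric about a slowly drifting midpoint, so that the Euclidean
    distance between them reproduces the target IPD to float precision.

    Returns ``(trajectory, truth)`` where ``trajectory`` is a
    :class:`retmap.preprocessing.TrajectoryPair` and ``truth`` a
    :class:`MatchGroundTruth`.
    """
    from .preprocessing import TrajectoryPair  # local import, avoids a cycle

    if isinstance(specs, SyntheticSpec):
        specs = [specs]
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one scene spec")
    if layout is None:
        layout = MatchLayout()

    fs = specs[0].sampling_rate
    period = specs[0].oscillation_period
    half = int(round(period * fs / 2.0))
    recovery = int(round(layout.recovery_periods * period * fs))
    rng = np.random.default_rng(specs[0].seed)

    # draw every scene's peaks first so re-engagement arcs can target the
    # observed (possibly noisy) first peak of the following scene
    scene_peaks: list[np.ndarray] = []
    scene_truths: list[GroundTruth] = []
    for spec in specs:
        if spec.sampling_rate != fs or spec.oscillation_period != period:
            raise ValueError("all scenes in a match must share the time grid")
        peaks, truth = generate_peak_sequence(spec, rng=rng)
        if np.any(peaks <= layout.strike_value + 0.1):
            raise GenerationError("a peak fell too close to the strike depth")
        scene_peaks.append(peaks)
        scene_truths.append(truth)

    pieces: list[np.ndarray] = [np.array([layout.strike_value])]
    pos = 1
    scene_ranges: list[tuple[int, int]] = []
    strike_idx: list[int] = []
    for k, (spec, peaks) in enumerate(zip(specs, scene_peaks)):
        # two-stage re-engagement: rise from strike depth to the standard
        # trough level, then a standard rising arc into the first peak, so
        # the first peak's local shape matches every other peak's
        trough0 = spec.trough_fraction * peaks[0]
        if recovery <= half:
            raise ValueError("recovery must exceed half an oscillation period")
        pieces.append(
            _half_cosine(recovery - half, layout.strike_value, trough0, rising=True)
        )
        pieces.append(_half_cosine(half, trough0, peaks[0], rising=True))
        pos += recovery
        scene_start = pos - 1  # sample index of the first peak
        t, s, _pk = render_continuous_scene(peaks, spec, pad=False)
        scene_truths[k].peak_times = t + scene_start / fs
        pieces.append(s[1:])  # s[0] is the first-peak sample already emitted
        pos += s.size - 1
        # strike descent to the close approach ending the scene
        pieces.append(_half_cosine(half, layout.strike_value, peaks[-1], rising=False))
        pos += half
        strike_idx.append(pos - 1)
        scene_ranges.append((scene_start, pos))

    s_norm = np.concatenate(pieces)
    d_m = layout.baseline_m + layout.meters_per_unit * s_norm
    if np.any(d_m <= 0):
        raise GenerationError("rendered IPD reached a non-positive value")
    n = d_m.size
    time = np.arange(n) / fs

    # slowly drifting midpoint and slowly rotating engagement axis
    mid = np.stack(
        [0.5 * np.sin(2 * np.pi * time / 60.0), 0.3 * np.sin(2 * np.pi * time / 45.0)],
        axis=1,
    )
    theta = 0.25 + 0.05 * np.sin(2 * np.pi * time / 30.0)
    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    offset = (d_m / 2.0)[:, None] * u
    traj = TrajectoryPair(
        time=time,
        pos_a=mid + offset,
        pos_b=mid - offset,
        match_id=match_id,
        group=group,
    )
    truth = MatchGroundTruth(
        scenes=scene_truths,
        scene_sample_ranges=scene_ranges,
        strike_sample_indices=strike_idx,
        ipd_normalized=s_norm,
        ipd_meters=d_m,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# random regime samplers (the study conditions for recovery experiments)
# ---------------------------------------------------------------------------

_LINEAR_CLASS_SLOPES = {
    "Aa": (0.3, 0.7),
    "Ar": (-0.7, -0.3),
    "Ra": (1.2, 1.7),
    "Rr": (-1.7, -1.2),
}


def _linear_regime(
    rng: np.random.Generator,
    cls: str,
    start: float,
    n_peaks: int,
    seed_initial: bool,
) -> RegimeSpec:
    lo, hi = _LINEAR_CLASS_SLOPES[cls]
    c = float(rng.uniform(lo, hi))
    if cls == "Aa":
        # wide approach span so zero curvature is resolvable against the
        # intermittency families at realistic noise
        gap = float(rng.uniform(0.4, 0.6))
        p = float(np.clip(start - np.sign(start - 0.5) * gap, 0.12, 1.0))
    elif cls == "Ar":
        # alternation overshoots to p − |c|·gap; band violations are
        # handled by the caller's rejection loop
        gap = float(rng.uniform(0.25, 0.45))
        p = float(np.clip(start - np.sign(start - 0.5) * gap, 0.15, 1.0))
    else:
        # repellers start close to the fixed point and diverge toward
        # mid-range so the iterates stay inside the band
        p = float(start + np.sign(0.55 - start) * rng.uniform(-0.08, -0.04))
    d = p * (1.0 - c)
    return RegimeSpec(
        "linear", (c, d), n_peaks, initial_peak=start if seed_initial else None
    )


def _exp_regime(
    rng: np.random.Generator, n_peaks: int, seed_initial: bool
) -> RegimeSpec:
    # lifted-tangency intermittency: a·e^{bx} tangent to the identity at
    # x = 1/b when a = e^{-1}/b; lifting a by 5–20 % keeps f(x) > x
    # everywhere (no crossing at any amplitude), so iterates drift through
    # the narrow channel and then accelerate away — the classic escape.
    b = float(rng.uniform(2.2, 3.0))
    lift = float(rng.uniform(1.25, 1.45))
    a = lift * np.exp(-1.0) / b
    start = 1.0 / b - float(rng.uniform(0.15, 0.22))
    return RegimeSpec(
        "exponential", (a, b), n_peaks, initial_peak=start if seed_initial else None
    )


def _log_regime(
    rng: np.random.Generator, n_peaks: int, seed_initial: bool
) -> RegimeSpec:
    # divergence from the lower (repelling) crossing x*: slope b/x* well
    # above 1 there, so iterates climb away through a strongly bent
    # stretch and decelerate before the upper (attracting) crossing
    x_cross = float(rng.uniform(0.18, 0.25))
    b = x_cross * float(rng.uniform(2.2, 2.8))
    a = x_cross - b * np.log(x_cross)
    start = x_cross + float(rng.uniform(0.06, 0.10))
    return RegimeSpec(
        "logarithmic", (a, b), n_peaks, initial_peak=start if seed_initial else None
    )


def _iterates_ok(regime: RegimeSpec, start: float, n: int) -> bool:
    y = start
    ys = [y]
    for _ in range(n):
        y = float(regime.evaluate(y))
        if not (0.05 < y < 1.45) or not np.isfinite(y):
            return False
        ys.append(y)
    if regime.family != "linear":
        # no identity crossing inside the observed range (noise margin)
        xs = np.linspace(min(ys) - 0.04, max(ys) + 0.04, 200)
        xs = xs[xs > 1e-6]
        if np.any(np.diff(np.sign(regime.evaluate(xs) - xs)) != 0):
            return False
        if np.ptp(ys) < 0.18:  # identifiability: enough curvature leverage
            return False
    return True


def random_single_regime(
    rng: np.random.Generator,
    family: str,
    n_peaks: int = 7,
    cls: str | None = None,
) -> RegimeSpec:
    """Rejection-sample one in-band regime of the requested family."""
    for _ in range(500):
        if family == "linear":
            c = cls or rng.choice(list(_LINEAR_CLASS_SLOPES))
            if c in ("Aa", "Ar"):
                start = float(rng.uniform(0.6, 0.95))
            else:
                start = float(rng.uniform(0.35, 0.75))
            reg = _linear_regime(rng, c, start, n_peaks, seed_initial=True)
        elif family == "exponential":
            reg = _exp_regime(rng, n_peaks, seed_initial=True)
        elif family == "logarithmic":
            reg = _log_regime(rng, n_peaks, seed_initial=True)
        else:
            raise ValueError(family)
        if _iterates_ok(reg, reg.initial_peak, n_peaks - 1):
            return reg
    raise GenerationError(f"could not sample an admissible {family} regime")


def _map_separation(a: RegimeSpec, b: RegimeSpec, xs: np.ndarray) -> float:
    return float(np.min(np.abs(np.asarray(a.evaluate(xs)) - np.asarray(b.evaluate(xs)))))


def random_switching_regimes(
    rng: np.random.Generator,
    n_regimes: int,
    n_peaks_range: tuple[int, int] = (4, 7),
    min_separation: float = 0.15,
) -> list[RegimeSpec]:
    """Sample a chained multi-regime scene with well-separated maps.

    Consecutive regimes are required to differ by at least
    ``min_separation`` over the handoff amplitude range, so that windows
    straddling a planted boundary fail the goodness-of-fit screen instead
    of blurring two regimes into one.
    """
    for _ in range(1000):
        regimes: list[RegimeSpec] = []
        y = float(rng.uniform(0.65, 0.9))
        start = y
        ok = True
        for r in range(n_regimes):
            n_pk = int(rng.integers(n_peaks_range[0], n_peaks_range[1] + 1))
            n_new = n_pk - 1 if r == 0 else n_pk
            for _ in range(50):
                cls = rng.choice(["Aa", "Ar", "Ra", "Rr"])
                cand = _linear_regime(rng, cls, y, n_pk, seed_initial=(r == 0))
                if not _iterates_ok(cand, y, n_new):
                    continue
                if regimes:
                    xs = np.linspace(max(0.05, y - 0.15), min(1.4, y + 0.15), 30)
                    if _map_separation(regimes[-1], cand, xs) < min_separation:
                        continue
                break
            else:
                ok = False
                break
            regimes.append(cand)
            for _ in range(n_new):
                y = float(cand.evaluate(y))
        if ok:
            return regimes
    raise GenerationError("could not sample a switching-regime scene")


def markov_regime_chain(
    rng: np.random.Generator,
    n_regimes: int,
    p_stay_high: float = 0.6,
    p_stay_low: float = 0.6,
    high_fp: float = 0.85,
    low_fp: float = 0.35,
    slope: float = 0.45,
    n_peaks_range: tuple[int, int] = (4, 6),
    start_high: bool = True,
) -> list[RegimeSpec]:
    """Two-mode attractor chain for planting F/N state structure.

    Alternates between attractors with a high fixed point (peaks labeled
    ``F``) and a low fixed point (labeled ``N``) according to a first-order
    chain over modes, giving bimodal peak histograms with a valley near the
    midpoint of the two fixed points.
    """
    regimes: list[RegimeSpec] = []
    high = start_high
    for r in range(n_regimes):
        fp = high_fp if high else low_fp
        c = float(slope * rng.uniform(0.85, 1.15))
        d = fp * (1.0 - c)
        n_pk = int(rng.integers(n_peaks_range[0], n_peaks_range[1] + 1))
        init = float(rng.uniform(0.85, 0.95)) if r == 0 else None
        regimes.append(
            RegimeSpec("linear", (c, d), n_pk, initial_peak=init,
                       label="F" if high else "N")
        )
        stay = p_stay_high if high else p_stay_low
        if rng.random() > stay:
            high = not high
    return regimes


def generate_label_sequences(
    p_next_f: dict[str, float],
    n_per_condition: int,
    seed: int,
    scene_length: int = 12,
) -> list[list[str]]:
    """Sample F/N label scenes from a known second-order chain.

    ``p_next_f`` maps each sub-state (previous two labels, e.g. ``"FF"``)
    to the probability that the next label is ``F``.  Scenes are generated
    until every sub-state has accumulated at least ``n_per_condition``
    observed transitions.
    """
    for key in ("FF", "FN", "NF", "NN"):
        if key not in p_next_f:
            raise ValueError(f"missing sub-state {key}")
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in ("FF", "FN", "NF", "NN")}
    scenes: list[list[str]] = []
    while min(counts.values()) < n_per_condition:
        labels = [
            "F" if rng.random() < 0.5 else "N",
            "F" if rng.random() < 0.5 else "N",
        ]
        for _ in range(scene_length - 2):
            sub = labels[-2] + labels[-1]
            counts[sub] += 1
            labels.append("F" if rng.random() < p_next_f[sub] else "N")
        scenes.append(labels)
    return scenes
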