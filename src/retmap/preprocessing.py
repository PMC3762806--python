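"""Trajectory preprocessing: filtering, interpersonal distance, scenes.

A *scene* is the unit of analysis: a contiguous stretch of competition
that starts at the farthest interpersonal distance (its first positive
peak is the largest), contains at least four positive peaks, and ends at a
strike-like close approach (a deep negative peak) or with a slow
detachment at the end of the recorded sequence.  Quick detachments —
adjacent negative/positive peak pairs spreading more than 1 m in under
1 500 ms — are transition movements, not competition, and their peaks are
removed before scenes are cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "TrajectoryPair",
    "IpdSeries",
    "Scene",
    "lowpass_positions",
    "compute_ipd",
    "find_ipd_peaks",
    "remove_quick_detachments",
    "split_scenes",
]


@dataclass
class TrajectoryPair:
    """Synchronized 2-D positions of two agents on a common time grid."""

    time: np.ndarray
    pos_a: np.ndarray
    pos_b: np.ndarray
    match_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pos_a = np.asarray(self.pos_a, dtype=float)
        self.pos_b = np.asarray(self.pos_b, dtype=float)
        n = self.time.size
        if self.pos_a.shape != (n, 2) or self.pos_b.shape != (n, 2):
            raise ValueError("positions must be (n, 2) arrays matching time")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.pos_a))
            and np.all(np.isfinite(self.pos_b))
        ):
            raise ValueError("non-finite values in trajectory")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "xA_m": self.pos_a[:, 0],
                "yA_m": self.pos_a[:, 1],
                "xB_m": self.pos_b[:, 0],
                "yB_m": self.pos_b[:, 1],
            }
        ).to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_csv(
        cls, path: str | Path, match_id: str = "", group: str = ""
    ) -> "TrajectoryPair":
        df = pd.read_csv(path)
        required = ["time_s", "xA_m", "yA_m", "xB_m", "yB_m"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV {path} missing columns {missing}")
        return cls(
            time=df["time_s"].to_numpy(),
            pos_a=df[["xA_m", "yA_m"]].to_numpy(),
            pos_b=df[["xB_m", "yB_m"]].to_numpy(),
            match_id=match_id or Path(path).stem,
            group=group,
        )


@dataclass
class IpdSeries:
    """Interpersonal distance D(t) in meters on the trajectory's grid."""

    time: np.ndarray
    d: np.ndarray
    filtered: bool = False
    match_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.time.shape != self.d.shape:
            raise ValueError("time and d must have equal length")
        if np.any(self.d < 0):
            raise ValueError("distance cannot be negative")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class Scene:
    """One contiguous competition segment (0-based half-open sample range)."""

    match_id: str
    scene_id: int
    start: int
    stop: int
    pos_peaks: np.ndarray  # global sample indices of positive (max) peaks
    neg_peaks: np.ndarray  # global sample indices of negative (min) peaks

    def __post_init__(self) -> None:
        self.pos_peaks = np.asarray(self.pos_peaks, dtype=int)
        self.neg_peaks = np.asarray(self.neg_peaks, dtype=int)
        if self.stop <= self.start:
            raise ValueError("empty scene range")
        if self.pos_peaks.size < 4:
            raise ValueError("a scene requires at least 4 positive peaks")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


def lowpass_positions(
    traj: TrajectoryPair,
    order: int = 4,
    cutoff_hz: float = 6.0,
    zero_phase: bool = True,
) -> TrajectoryPair:
    """Low-pass Butterworth filter on every coordinate channel.

    Zero-phase (forward–backward) by default so that downstream peak
    timing is not lag-shifted; ``zero_phase=False`` applies a single
    causal pass.
    """
    nyquist = traj.sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if len(traj) < 3 * order:
        raise ValueError("trajectory too short for the requested filter order")
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=traj.sampling_rate,
                           output="sos")
    apply = sp_signal.sosfiltfilt if zero_phase else sp_signal.sosfilt
    return replace(
        traj,
        pos_a=np.column_stack([apply(sos, traj.pos_a[:, j]) for j in range(2)]),
        pos_b=np.column_stack([apply(sos, traj.pos_b[:, j]) for j in range(2)]),
    )


def compute_ipd(traj: TrajectoryPair, filtered: bool = False) -> IpdSeries:
    """Euclidean distance between the two agents at every sample."""
    d = np.linalg.norm(traj.pos_a - traj.pos_b, axis=1)
    return IpdSeries(time=traj.time, d=d, filtered=filtered,
                     match_id=traj.match_id, group=traj.group)


def _strict_extrema(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    interior = np.arange(1, d.size - 1)
    maxima = interior[(d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])]
    minima = interior[(d[1:-1] < d[:-2]) & (d[1:-1] < d[2:])]
    return maxima, minima


def _enforce_alternation(
    events: list[tuple[int, str]], d: np.ndarray
) -> list[tuple[int, str]]:
    """Collapse runs of same-type events, keeping the most extreme one."""
    out: list[tuple[int, str]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            if kind == "max":
                keep = idx if d[idx] > d[prev_idx] else prev_idx
            else:
                keep = idx if d[idx] < d[prev_idx] else prev_idx
            out[-1] = (keep, kind)
        else:
            out.append((idx, kind))
    return out


def find_ipd_peaks(ipd: IpdSeries) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima of D with alternation enforced."""
    if len(ipd) < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = _strict_extrema(ipd.d)
    events = sorted(
        [(int(i), "max") for i in maxima] + [(int(i), "min") for i in minima]
    )
    events = _enforce_alternation(events, ipd.d)
    pos = np.array([i for i, k in events if k == "max"], dtype=int)
    neg = np.array([i for i, k in events if k == "min"], dtype=int)
    return pos, neg


def remove_quick_detachments(
    pos_peaks: np.ndarray,
    neg_peaks: np.ndarray,
    ipd: IpdSeries,
    max_spread_m: float = 1.0,
    max_time_s: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop peak pairs of quick detaching movements.

    A detaching movement is a negative peak followed by a positive peak;
    when the distance spreads by more than ``max_spread_m`` within less
    than ``max_time_s``, both peaks of the movement are removed and
    alternation is re-enforced.
    """
    events = sorted(
        [(int(i), "max") for i in pos_peaks] + [(int(i), "min") for i in neg_peaks]
    )
    removed = set()
    for (i0, k0), (i1, k1) in zip(events, events[1:]):
        if k0 == "min" and k1 == "max":
            spread = ipd.d[i1] - ipd.d[i0]
            gap = ipd.time[i1] - ipd.time[i0]
            if spread > max_spread_m and gap < max_time_s:
                removed.add(i0)
                removed.add(i1)
    events = [(i, k) for i, k in events if i not in removed]
    events = _enforce_alternation(events, ipd.d)
    pos = np.array([i for i, k in events if k == "max"], dtype=int)
    neg = np.array([i for i, k in events if k == "min"], dtype=int)
    return pos, neg


def _sequences_outside(
    n: int, time: np.ndarray, exclusion_intervals: Sequence[tuple[float, float]]
) -> list[tuple[int, int]]:
    """Maximal half-open index runs outside the excluded time intervals."""
    mask = np.zeros(n, dtype=bool)
    for start_s, end_s in exclusion_intervals:
        if end_s <= start_s:
            raise ValueError("exclusion interval must have end > start")
        mask |= (time >= start_s) & (time <= end_s)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def split_scenes(
    ipd: IpdSeries,
    exclusion_intervals: Sequence[tuple[float, float]] = (),
    min_positive_peaks: int = 4,
    close_quantile: float = 0.25,
    close_threshold_m: float | None = None,
    max_spread_m: float = 1.0,
    max_time_s: float = 1.5,
) -> list[Scene]:
    """Cut a match into scenes satisfying the inclusion rules.

    Sequences are maximal runs outside the exclusion intervals.  Within
    each sequence, quick detachments are removed, then the sequence is cut
    at close-approach events: negative peaks whose distance falls below
    ``close_threshold_m`` (or below the ``close_quantile`` quantile of the
    match's negative-peak distances when no absolute threshold is given —
    a proxy for the video-identified striking actions).  Each resulting
    piece is trimmed to start at its farthest positive peak and kept only
    if it retains ``min_positive_peaks`` positive peaks.
    """
    sequences = _sequences_outside(len(ipd), ipd.time, exclusion_intervals)

    per_seq: list[tuple[int, np.ndarray, np.ndarray]] = []
    all_neg_values: list[np.ndarray] = []
    for s0, s1 in sequences:
        if s1 - s0 < 3:
            continue
        seg = IpdSeries(time=ipd.time[s0:s1], d=ipd.d[s0:s1], filtered=ipd.filtered)
        pos, neg = find_ipd_peaks(seg)
        pos, neg = remove_quick_detachments(
            pos, neg, seg, max_spread_m=max_spread_m, max_time_s=max_time_s
        )
        per_seq.append((s0, pos + s0, neg + s0))
        if neg.size:
            all_neg_values.append(ipd.d[neg + s0])

    if close_threshold_m is None:
        if not all_neg_values:
            return []
        close_threshold_m = float(
            np.quantile(np.concatenate(all_neg_values), close_quantile)
        )

    scenes: list[Scene] = []
    scene_id = 0
    for s0, pos, neg in per_seq:
        strikes = neg[ipd.d[neg] <= close_threshold_m]
        cut_points = list(strikes)
        pieces: list[tuple[int, int]] = []
        lo = s0
        for c in cut_points:
            pieces.append((lo, int(c) + 1))
            lo = int(c) + 1
        seq_end = pos[-1] + 1 if pos.size else lo  # tail beyond peaks is idle
        if lo < seq_end:
            pieces.append((lo, seq_end))
        for p0, p1 in pieces:
            p_pos = pos[(pos >= p0) & (pos < p1)]
            p_neg = neg[(neg >= p0) & (neg < p1)]
            if p_pos.size == 0:
                continue
            # scene starts at its farthest positive peak
            far = p_pos[np.argmax(ipd.d[p_pos])]
            p_pos = p_pos[p_pos >= far]
            p_neg = p_neg[p_neg >= far]
            if p_pos.size < min_positive_peaks:
                continue
            scenes.append(
                Scene(
                    match_id=ipd.match_id,
                    scene_id=scene_id,
                    start=int(far),
                    stop=int(p1),
                    pos_peaks=p_pos,
                    neg_peaks=p_neg,
                )
            )
            scene_id += 1
    return scenes
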