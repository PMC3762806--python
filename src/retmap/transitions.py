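"""Discrete F/N states and hierarchical transition statistics.

Peak amplitudes belonging to accepted *linear* return-map fits form a
bimodal per-match histogram: a high-amplitude "farthest apart" cluster
(state F) and a low-amplitude "nearest together" cluster (state N).  The
split threshold is the minimum-frequency bin between the two largest
modes.  Second-order transitions condition on the current state;
third-order transitions condition on the previous two states (sub-states
FF, NF, NN, FN).  Transitions never cross scene boundaries.  Group
contrasts use a two-sided Fisher exact test computed by exhaustive
hypergeometric enumeration with integer arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StateLabeling",
    "TransitionModel",
    "GroupComparison",
    "ThresholdError",
    "SUB_STATES",
    "peak_histogram",
    "find_threshold",
    "label_states",
    "second_order",
    "third_order",
    "fisher_exact_2x2",
    "fisher_compare",
]

STATES = ("F", "N")
SUB_STATES = ("FF", "FN", "NF", "NN")


class ThresholdError(RuntimeError):
    """Histogram unusable for a per-match threshold; pool across matches."""


@dataclass
class StateLabeling:
    """Per-match F/N labels for well-fitted peaks, grouped by scene."""

    match_id: str
    threshold: float
    scene_labels: list[list[str]]
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None


@dataclass
class TransitionModel:
    """Conditional transition counts and probabilities for one group.

    ``order`` 2 conditions on the current state; ``order`` 3 on the
    previous two (sub-states).  ``probs[cond]`` maps each next state to
    P(next | cond) and is ``None`` when the condition was never observed.
    """

    order: int
    group: str
    counts: dict[str, dict[str, int]]
    probs: dict[str, dict[str, float] | None]

    def marginalized(self) -> "TransitionModel":
        """Second-order model obtained by summing third-order counts over
        the older label of each sub-state."""
        if self.order != 3:
            raise ValueError("marginalization applies to third-order models")
        counts = {s: {t: 0 for t in STATES} for s in STATES}
        for sub, row in self.counts.items():
            cur = sub[1]
            for nxt, c in row.items():
                counts[cur][nxt] += c
        return TransitionModel(order=2, group=self.group, counts=counts,
                               probs=_normalize_rows(counts))


@dataclass
class GroupComparison:
    """Per-condition 2×2 tables (group × next state) and Fisher p-values."""

    group_a: str
    group_b: str
    tables: dict[str, np.ndarray]
    pvalues: dict[str, float]


def peak_histogram(
    values: Sequence[float], bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram of well-fitted peak amplitudes over [0, 1]."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ThresholdError(
            f"only {values.size} well-fitted peaks in this match; "
            "use the pooled (global) threshold fallback"
        )
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide the unit interval")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
    return counts, edges


def _local_modes(counts: np.ndarray) -> list[int]:
    """Bins strictly higher than both neighbors (edge bins need one side)."""
    modes = []
    n = counts.size
    for i in range(n):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n - 1 else -1
        if counts[i] > left and counts[i] > right:
            modes.append(i)
    return modes


def find_threshold(counts: np.ndarray, edges: np.ndarray) -> float:
    """Center of the minimum-count bin strictly between the two largest modes."""
    counts = np.asarray(counts)
    modes = _local_modes(counts)
    if len(modes) < 2:
        raise ThresholdError(
            "histogram is unimodal; use the pooled (global) threshold fallback"
        )
    top_two = sorted(sorted(modes, key=lambda i: counts[i], reverse=True)[:2])
    lo_mode, hi_mode = top_two
    between = np.arange(lo_mode + 1, hi_mode)
    if between.size == 0:
        raise ThresholdError("no bin strictly between the two largest modes")
    min_count = counts[between].min()
    ties = between[counts[between] == min_count]
    midpoint = (lo_mode + hi_mode) / 2.0
    best = ties[np.argmin(np.abs(ties - midpoint))]
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[best])


def label_states(values: Sequence[float], threshold: float) -> list[str]:
    """F above the threshold, N at or below it (declared tie rule)."""
    return ["F" if v > threshold else "N" for v in np.asarray(values, dtype=float)]


def _normalize_rows(
    counts: dict[str, dict[str, int]]
) -> dict[str, dict[str, float] | None]:
    probs: dict[str, dict[str, float] | None] = {}
    for cond, row in counts.items():
        total = sum(row.values())
        probs[cond] = (
            {k: v / total for k, v in row.items()} if total > 0 else None
        )
    return probs


def _iter_scenes(labelings: Iterable[StateLabeling | list[str]]):
    for item in labelings:
        if isinstance(item, StateLabeling):
            yield from item.scene_labels
        else:
            yield list(item)


def second_order(
    labelings: Iterable[StateLabeling | list[str]],
    group: str = "",
    skip_first_pair: bool = False,
) -> TransitionModel:
    """P(next | current) over within-scene consecutive label pairs.

    ``skip_first_pair`` drops each scene's first pair, aligning the pair
    population with the one visible to third-order counting (every triple
    contains all pairs except the scene-initial one); with it the
    third-order marginalization identity holds exactly.
    """
    counts = {s: {t: 0 for t in STATES} for s in STATES}
    n_pairs = 0
    for labels in _iter_scenes(labelings):
        start = 1 if skip_first_pair else 0
        for i in range(start, len(labels) - 1):
            counts[labels[i]][labels[i + 1]] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no within-scene consecutive label pairs")
    return TransitionModel(order=2, group=group, counts=counts,
                           probs=_normalize_rows(counts))


def third_order(
    labelings: Iterable[StateLabeling | list[str]], group: str = ""
) -> TransitionModel:
    """P(next | previous two) over within-scene label triples."""
    counts = {s: {t: 0 for t in STATES} for s in SUB_STATES}
    for labels in _iter_scenes(labelings):
        for i in range(1, len(labels) - 1):
            sub = labels[i - 1] + labels[i]
            counts[sub][labels[i + 1]] += 1
    return TransitionModel(order=3, group=group, counts=counts,
                           probs=_normalize_rows(counts))


def fisher_exact_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed table's.  Point
    probabilities share the denominator C(n, s), so the comparison is done
    on exact integer numerators — no floating-point tie ambiguity.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 count matrix")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    s = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or s == 0 or s == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    obs_num = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    k_lo, k_hi = max(0, s - r2), min(r1, s)
    for k in range(k_lo, k_hi + 1):
        num = math.comb(r1, k) * math.comb(r2, s - k)
        if num <= obs_num:
            total += num
    return min(1.0, total / math.comb(n, s))


def fisher_compare(
    model_a: TransitionModel, model_b: TransitionModel
) -> GroupComparison:
    """Per-condition group contrast of next-state counts.

    For every conditioning state (or sub-state) present in both models,
    builds the 2×2 table [[a_F, a_N], [b_F, b_N]] of next-state counts and
    computes the two-sided Fisher exact p.
    """
    if model_a.order != model_b.order:
        raise ValueError("models must have the same order")
    tables: dict[str, np.ndarray] = {}
    pvalues: dict[str, float] = {}
    for cond in model_a.counts:
        row_a = model_a.counts[cond]
        row_b = model_b.counts.get(cond)
        if row_b is None:
            continue
        tab = np.array(
            [[row_a["F"], row_a["N"]], [row_b["F"], row_b["N"]]], dtype=int
        )
        tables[cond] = tab
        pvalues[cond] = fisher_exact_2x2(tab)
    return GroupComparison(
        group_a=model_a.group, group_b=model_b.group, tables=tables, pvalues=pvalues
    )
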