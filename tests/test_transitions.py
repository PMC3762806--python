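"""F/N thresholding, transition models, exact Fisher test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from retmap import synthetic as syn
from retmap import transitions as tr


class TestHistogram:
    def test_counts_and_bins(self):
        counts, edges = tr.peak_histogram(
            [0.41, 0.43, 0.77] + [0.1] * 7, bin_width=0.05
        )
        centers = (edges[:-1] + edges[1:]) / 2
        assert counts[(centers > 0.40) & (centers < 0.45)][0] == 2
        assert counts[(centers > 0.75) & (centers < 0.80)][0] == 1
        assert counts.sum() == 10

    def test_too_few_peaks_directs_to_fallback(self):
        with pytest.raises(tr.ThresholdError, match="pooled"):
            tr.peak_histogram([0.5] * 9)

    def test_bimodal_mixture_modes_recovered(self, rng):
        vals = np.concatenate(
            [rng.normal(0.4, 0.04, 300), rng.normal(0.75, 0.04, 300)]
        )
        counts, edges = tr.peak_histogram(np.clip(vals, 0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        modes = sorted(
            tr._local_modes(counts), key=lambda i: counts[i], reverse=True
        )[:2]
        assert {round(centers[m], 3) for m in modes} <= {0.375, 0.425, 0.725, 0.775}


class TestThreshold:
    def test_minimum_between_modes(self):
        counts = np.array([5, 1, 6])
        edges = np.array([0.25, 0.45, 0.65, 0.85])  # centers 0.35, 0.55, 0.75
        assert tr.find_threshold(counts, edges) == pytest.approx(0.55)

    def test_tie_broken_toward_mode_midpoint(self):
        counts = np.array([9, 1, 5, 1, 2, 8])  # minima ties at bins 1 and 3
        edges = np.linspace(0, 0.6, 7)
        thr = tr.find_threshold(counts, edges)
        # midpoint of modes (bins 0 and 5) is bin 2.5; bin 3 is nearer than 1
        assert thr == pytest.approx(0.35)

    def test_unimodal_rejected(self):
        with pytest.raises(tr.ThresholdError, match="unimodal"):
            tr.find_threshold(np.array([1, 5, 9, 5, 1]), np.linspace(0, 0.5, 6))

    def test_planted_boundary_recovered_within_one_bin(self, rng):
        boundary = 0.56
        lo = rng.uniform(0.30, boundary - 0.08, 400)
        hi = rng.uniform(boundary + 0.08, 0.92, 400)
        counts, edges = tr.peak_histogram(np.concatenate([lo, hi]))
        thr = tr.find_threshold(counts, edges)
        assert abs(thr - boundary) <= 0.05 + 1e-9


class TestLabeling:
    def test_threshold_split(self):
        assert tr.label_states([0.7, 0.4], 0.5) == ["F", "N"]

    def test_all_above(self):
        assert tr.label_states([0.9, 0.8], 0.5) == ["F", "F"]

    def test_exact_threshold_is_near_state(self):
        assert tr.label_states([0.5], 0.5) == ["N"]


class TestTransitionModels:
    def test_second_order_hand_count(self):
        model = tr.second_order([["F", "F", "N", "N", "F"]])
        assert model.counts == {"F": {"F": 1, "N": 1}, "N": {"F": 1, "N": 1}}
        for cond in "FN":
            assert model.probs[cond]["F"] == pytest.approx(0.5)

    def test_all_f_scene(self):
        model = tr.second_order([["F", "F", "F"]])
        assert model.probs["F"]["F"] == 1.0
        assert model.probs["N"] is None

    def test_rows_sum_to_one(self, rng):
        scenes = [
            ["F" if rng.random() < 0.6 else "N" for _ in range(10)] for _ in range(20)
        ]
        model = tr.second_order(scenes)
        for cond, row in model.probs.items():
            if row is not None:
                assert sum(row.values()) == pytest.approx(1.0)

    def test_no_cross_scene_pairs(self):
        # two scenes: the F->N junction between scenes must not be counted
        model = tr.second_order([["F", "F"], ["N", "N"]])
        assert model.counts["F"]["N"] == 0

    def test_third_order_single_triple(self):
        model = tr.third_order([["F", "F", "N"]])
        assert model.probs["FF"] == {"F": 0.0, "N": 1.0}
        assert model.probs["NN"] is None

    def test_overlap_constraint_marginalization(self):
        scenes = [["F", "N", "F", "F", "N", "N", "F"], ["N", "F", "N", "N"]]
        m3 = tr.third_order(scenes)
        m2 = tr.second_order(scenes, skip_first_pair=True)
        assert m3.marginalized().counts == m2.counts

    def test_label_permutation_symmetry(self):
        scenes = [["F", "N", "F", "F", "N"], ["N", "N", "F"]]
        flipped = [["N" if l == "F" else "F" for l in s] for s in scenes]
        m = tr.second_order(scenes)
        mf = tr.second_order(flipped)
        swap = {"F": "N", "N": "F"}
        for cond in "FN":
            for nxt in "FN":
                assert m.counts[cond][nxt] == mf.counts[swap[cond]][swap[nxt]]

    def test_chain_recovery_within_three_standard_errors(self):
        truth = {"FF": 0.7, "FN": 0.4, "NF": 0.55, "NN": 0.2}
        bad = 0
        for rep in range(100):
            scenes = syn.generate_label_sequences(truth, 250, seed=1000 + rep)
            m3 = tr.third_order(scenes)
            for sub, p in truth.items():
                n = sum(m3.counts[sub].values())
                se = math.sqrt(p * (1 - p) / n)
                if abs(m3.probs[sub]["F"] - p) > 3 * se:
                    bad += 1
        # 3 SE two-sided ~ 0.3% per estimate; allow a small count overall
        assert bad <= 8


def fisher_oracle(table):
    """Column-margin hypergeometric enumeration with exact fractions."""
    (a, b), (c, d) = table
    r1, r2, s, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or s == 0 or s == n:
        return 1.0
    p_obs = Fraction(math.comb(s, a) * math.comb(n - s, b), math.comb(n, r1))
    total = Fraction(0)
    for k in range(max(0, s - r2), min(r1, s) + 1):
        p = Fraction(math.comb(s, k) * math.comb(n - s, r1 - k), math.comb(n, r1))
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


class TestFisherExact:
    def test_matches_enumeration_oracle(self):
        assert tr.fisher_exact_2x2([[10, 5], [3, 12]]) == pytest.approx(
            fisher_oracle([[10, 5], [3, 12]]), abs=1e-12
        )

    def test_identical_rows_give_p_one(self):
        assert tr.fisher_exact_2x2([[7, 3], [7, 3]]) == 1.0

    def test_extreme_table_closed_form(self):
        # both extreme tables have probability 1/C(10,5)
        assert tr.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / math.comb(10, 5), abs=1e-15
        )

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert tr.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_agrees_with_scipy(self, rng):
        for _ in range(100):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert tr.fisher_exact_2x2(t) == pytest.approx(
                scipy_fisher(t)[1], abs=1e-7
            )


class TestGroupComparison:
    def test_tables_and_margins(self):
        a = tr.second_order([["F", "F", "N", "F"]] * 5, group="expert")
        b = tr.second_order([["N", "N", "F", "N"]] * 5, group="intermediate")
        comp = tr.fisher_compare(a, b)
        assert set(comp.pvalues) == {"F", "N"}
        for cond in "FN":
            tab = comp.tables[cond]
            assert tab[0].sum() == sum(a.counts[cond].values())
            assert tab[1].sum() == sum(b.counts[cond].values())

    def test_identical_groups_not_significant(self):
        scenes = [["F", "N", "F", "F", "N"]] * 10
        a = tr.second_order(scenes, group="x")
        b = tr.second_order(scenes, group="y")
        comp = tr.fisher_compare(a, b)
        assert all(p == 1.0 for p in comp.pvalues.values())
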