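"""Cutpoint search: candidates, tier assignment, oracle equality, permutation p."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senesurv.cutpoints import (
    assign_tiers,
    candidate_cutoffs,
    find_cutpoint_2tier,
    find_cutpoints_3tier,
    permutation_adjusted_p,
)
from senesurv.survival_stats import logrank_test_labels


def _brute_2tier(scores, dur, ev, frac):
    best = (-1.0, None)
    for c in candidate_cutoffs(scores, frac):
        chi2 = logrank_test_labels(dur, ev, scores <= c).chi2
        if chi2 > best[0]:
            best = (chi2, c)
    return best


def _brute_3tier(scores, dur, ev, frac):
    cands = candidate_cutoffs(scores, 0.0 + 1e-12)  # all midpoints; sizes checked below
    g = math.ceil(frac * len(scores))
    best = (-1.0, None, -1)
    for i, c1 in enumerate(cands):
        for c2 in cands[i + 1:]:
            tiers = assign_tiers(scores, (c1, c2))
            sizes = [np.sum(tiers == t) for t in ("low", "moderate", "excessive")]
            if min(sizes) < g:
                continue
            chi2 = logrank_test_labels(dur, ev, tiers).chi2
            if chi2 > best[0] + 1e-11:
                best = (chi2, (c1, c2), min(sizes))
    return best


class TestCandidates:
    def test_constraint_spans_inner_percentiles(self):
        scores = np.arange(1.0, 101.0)
        cands = candidate_cutoffs(scores, 0.1)
        assert cands[0] == 10.5 and cands[-1] == 90.5
        assert len(cands) == 81

    def test_two_distinct_values_single_midpoint(self):
        cands = candidate_cutoffs([3.0, 3.0, 8.0, 8.0], 0.25)
        np.testing.assert_allclose(cands, [5.5])

    def test_all_identical_raises(self):
        with pytest.raises(ValueError, match="identical"):
            candidate_cutoffs([4.0] * 10, 0.1)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_every_candidate_respects_balance(self, seed):
        r = np.random.default_rng(seed)
        scores = r.choice(np.arange(20.0), size=40, replace=True)
        if np.unique(scores).size < 2:
            return
        frac = 0.15
        g = math.ceil(frac * 40)
        for c in candidate_cutoffs(scores, frac):
            assert np.sum(scores <= c) >= g and np.sum(scores > c) >= g


class TestAssignTiers:
    def test_boundary_belongs_to_lower_tier(self):
        tiers = assign_tiers([30.0, 50.0, 70.0, 70.1], (30.0, 70.0))
        assert list(tiers) == ["low", "moderate", "moderate", "excessive"]

    def test_single_cutoff_two_tiers(self):
        assert list(assign_tiers([1.0, 2.0], (1.5,))) == ["low", "high"]

    def test_counting_oracle(self, rng):
        scores = rng.uniform(0, 100, 500)
        c1, c2 = 33.0, 66.0
        tiers = assign_tiers(scores, (c1, c2))
        assert np.sum(tiers == "low") == np.sum(scores <= c1)
        assert np.sum(tiers == "moderate") == np.sum((scores > c1) & (scores <= c2))
        assert np.sum(tiers == "excessive") == np.sum(scores > c2)

    def test_unordered_cutoffs_raise(self):
        with pytest.raises(ValueError, match="increasing"):
            assign_tiers([1.0], (5.0, 2.0))


class TestFinders:
    @pytest.mark.parametrize("seed", range(8))
    def test_2tier_equals_bruteforce(self, seed, survival_factory):
        r = np.random.default_rng(seed)
        n = 50
        scores = r.uniform(0, 100, n)
        dur, ev = survival_factory(r, n)
        res = find_cutpoint_2tier(scores, dur, ev, min_group_frac=0.15)
        chi2, cut = _brute_2tier(scores, dur, ev, 0.15)
        assert res.cutoffs[0] == pytest.approx(cut)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_3tier_equals_bruteforce(self, seed, survival_factory):
        r = np.random.default_rng(100 + seed)
        n = 30
        scores = r.uniform(0, 100, n)
        dur, ev = survival_factory(r, n)
        res = find_cutpoints_3tier(scores, dur, ev, min_group_frac=0.2)
        chi2, cuts, _ = _brute_3tier(scores, dur, ev, 0.2)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)
        assert res.cutoffs == pytest.approx(cuts)

    @pytest.mark.parametrize("k", [2, 3])
    def test_groups_respect_min_fraction(self, k, survival_factory):
        finder = find_cutpoint_2tier if k == 2 else find_cutpoints_3tier
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            n = 60
            scores = r.uniform(0, 100, n)
            dur, ev = survival_factory(r, n)
            res = finder(scores, dur, ev, min_group_frac=0.12)
            assert min(res.group_sizes) >= math.ceil(0.12 * n)
            assert sum(res.group_sizes) == n

    def test_step_effect_cutoff_recovered(self):
        """True threshold at 50 with HR = 3 is localized to the 40-60 window."""
        hits = 0
        for rep in range(30):
            r = np.random.default_rng(300 + rep)
            n = 400
            scores = r.uniform(0, 100, n)
            lam = np.where(scores > 50, 0.01, 0.03)
            t = r.exponential(1 / lam)
            c = r.uniform(0, 120, n)
            dur, ev = np.minimum(t, c), (t <= c).astype(int)
            cut = find_cutpoint_2tier(scores, dur, ev).cutoffs[0]
            hits += 40 <= cut <= 60
        assert hits >= 27  # >= 90% of replicates

    def test_monotone_effect_three_tier_usually_not_weaker(self):
        """With a strong monotone effect the 3-tier p rarely exceeds the 2-tier p.

        The 3-group statistic dominates in chi2 but spends an extra degree
        of freedom, so strict p-ordering cannot hold on every draw.
        """
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n = 300
            scores = r.uniform(0, 100, n)
            lam = np.where(scores > 50, 0.03, 0.01)
            t = r.exponential(1 / lam)
            c = r.uniform(0, 120, n)
            dur, ev = np.minimum(t, c), (t <= c).astype(int)
            p2 = find_cutpoint_2tier(scores, dur, ev).p_raw
            p3 = find_cutpoints_3tier(scores, dur, ev).p_raw
            wins += p3 <= p2
        assert wins >= 14

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            find_cutpoint_2tier([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 4], [0, 0, 0, 0])

    def test_identical_scores_raise(self, survival_factory, rng):
        dur, ev = survival_factory(rng, 20)
        with pytest.raises(ValueError, match="identical"):
            find_cutpoint_2tier(np.full(20, 5.0), dur, ev)


class TestPermutation:
    def test_deterministic_given_seed(self, rng, survival_factory):
        scores = rng.uniform(0, 100, 60)
        dur, ev = survival_factory(rng, 60)
        a = permutation_adjusted_p(scores, dur, ev, B=199, seed=9)
        b = permutation_adjusted_p(scores, dur, ev, B=199, seed=9)
        assert a == b

    def test_small_B_rejected(self, rng, survival_factory):
        scores = rng.uniform(0, 100, 40)
        dur, ev = survival_factory(rng, 40)
        with pytest.raises(ValueError, match="100"):
            permutation_adjusted_p(scores, dur, ev, B=50)

    def test_perfect_separation_attains_lower_bound(self):
        """All low scores die at t=1, all high scores censored late: p = 1/(B+1)."""
        n = 100
        scores = np.concatenate([np.arange(50.0), 60.0 + np.arange(50.0)])
        dur = np.concatenate([np.full(50, 1.0), np.full(50, 100.0)])
        ev = np.concatenate([np.ones(50, dtype=int), np.zeros(50, dtype=int)])
        p = permutation_adjusted_p(scores, dur, ev, B=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_adjusted_not_below_its_bound_and_le_one(self, rng, survival_factory):
        scores = rng.uniform(0, 100, 50)
        dur, ev = survival_factory(rng, 50)
        for k in (2, 3):
            p = permutation_adjusted_p(scores, dur, ev, k_tiers=k, B=199, seed=1)
            assert 1 / 200 <= p <= 1.0
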