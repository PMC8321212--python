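"""Scoring functions: frozen hand-derived values, degenerate cases, and
cross-checks against the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgemetrics import (EdgeMap, MeasureParams, ValidationError, auto_params,
                         confusion_counts, d4, dice, dp, emm, f_measure, fom,
                         m_measure, rde, score_all)
from conftest import random_pair
import naive_oracle


def maps(shape, gt_pts, dc_pts):
    return (EdgeMap.from_points(shape, gt_pts), EdgeMap.from_points(shape, dc_pts))


class TestConfusion:
    def test_identity(self):
        gt, dc = maps((6, 6), [(1, 1), (2, 2)], [(1, 1), (2, 2)])
        c = confusion_counts(gt, dc)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_disjoint(self):
        gt, dc = maps((6, 6), [(0, 0)], [(5, 5), (4, 4)])
        c = confusion_counts(gt, dc)
        assert (c.tp, c.fp, c.fn) == (0, 2, 1)

    def test_hand_enumerated(self):
        gt, dc = maps((4, 4), [(0, 0), (0, 1), (0, 2)], [(0, 1), (0, 2), (0, 3)])
        c = confusion_counts(gt, dc)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 12)

    def test_invariants(self, rng):
        for _ in range(30):
            gt, dc = random_pair(rng)
            c = confusion_counts(gt, dc)
            assert c.total == gt.size
            assert c.n_gt == gt.n_points
            assert c.n_dc == dc.n_points


class TestFrozenValues:
    """Hand-evaluated scores for tiny constructed pairs."""

    def test_dice(self):
        gt, dc = maps((4, 4), [(0, 0), (0, 1), (0, 2)], [(0, 1), (0, 2), (0, 3)])
        assert dice(gt, dc).value == pytest.approx(4 / 6, abs=1e-12)

    def test_fom_single_displaced_pixel(self):
        # one FP at distance 1: (1/1) * 1/(1 + (1/9)*1) = 0.9
        gt, dc = maps((8, 8), [(0, 0)], [(0, 1)])
        assert fom(gt, dc).value == pytest.approx(0.9, abs=1e-12)

    def test_fom_subset_special_case(self):
        gt, dc = maps((8, 8), [(0, c) for c in range(4)], [(0, 0), (0, 1)])
        assert fom(gt, dc).value == pytest.approx(0.5, abs=1e-12)

    def test_f_one_tp_one_far_fp(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 0), (5, 5)])
        assert f_measure(gt, dc).value == pytest.approx(0.5, abs=1e-12)

    def test_f_displaced_pixel(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 2)])
        expected = 0.5 * (1.0 / (1.0 + 4.0 / 9.0))
        assert f_measure(gt, dc).value == pytest.approx(expected, abs=1e-12)

    def test_d4_subset(self):
        gt, dc = maps((8, 8), [(0, c) for c in range(4)], [(0, 0), (0, 1)])
        expected = 1.0 - 0.5 * math.sqrt((4 + 4 + 0) / 16 + 0.25)
        assert d4(gt, dc).value == pytest.approx(expected, abs=1e-12)

    def test_d4_far_single_pixels(self):
        gt, dc = maps((64, 64), [(0, 0)], [(63, 63)])
        # TP=0, FN=FP=max=1, FoM ~ 0 -> d4 ~ 1 - 0.5*sqrt(3+1) = 0
        assert d4(gt, dc).value == pytest.approx(0.0, abs=1e-3)

    def test_dp_one_fn(self):
        gt, dc = maps((4, 4), [(0, 0), (0, 1)], [(0, 0)])
        assert dp(gt, dc).value == pytest.approx(0.975, abs=1e-12)

    def test_dp_superset_structure(self):
        gt, dc = maps((8, 8), [(3, 3), (3, 4)], [(3, 3), (3, 4), (0, 0)])
        c = confusion_counts(gt, dc)
        v = dp(gt, dc).value
        assert v < 1.0
        assert v >= 1.0 - c.fp / (2 * (gt.size - gt.n_points))

    def test_emm_one_fn(self):
        gt, dc = maps((8, 8), [(0, 0), (0, 1)], [(0, 0)])
        assert emm(gt, dc).value == pytest.approx(1 / (1 + 10 / 64), abs=1e-12)

    def test_rde_displaced_pixel(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 3)])
        assert rde(gt, dc).value == pytest.approx(6.0, abs=1e-12)

    def test_rde_superset(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 0), (0, 4)])
        assert rde(gt, dc).value == pytest.approx(math.sqrt(8.0), abs=1e-12)

    def test_rde_without_root(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 3)])
        p = MeasureParams(rde_root=False)
        assert rde(gt, dc, p).value == pytest.approx(18.0, abs=1e-12)

    def test_m_equal_mu(self):
        gt, dc = maps((8, 8), [(0, 0)], [(0, 3)])
        p = MeasureParams(mu_fp=0.1, mu_fn=0.1)
        assert m_measure(gt, dc, p).value == pytest.approx(1 / 1.9, abs=1e-12)

    def test_m_far_limit_tends_to_zero(self):
        gt, dc = maps((512, 512), [(0, 0)], [(511, 511)])
        assert m_measure(gt, dc, MeasureParams(mu_fp=0.1, mu_fn=0.2)).value < 0.01


class TestDegenerate:
    def test_empty_candidate(self):
        gt = EdgeMap.from_points((8, 8), [(2, 2), (2, 3)])
        empty = EdgeMap.empty((8, 8))
        assert fom(gt, empty).value == 0.0
        assert f_measure(gt, empty).value == 0.0
        assert dice(gt, empty).value == 0.0
        assert emm(gt, empty).value == 0.0
        assert m_measure(gt, empty).value == 0.0
        assert dp(gt, empty).value == pytest.approx(0.5, abs=1e-12)
        with pytest.raises(ValidationError):
            rde(gt, empty)

    def test_dp_full_ground_truth_rejected(self):
        gt = EdgeMap(np.ones((4, 4), dtype=bool))
        with pytest.raises(ValidationError):
            dp(gt, gt)

    def test_non_positive_mu_rejected(self):
        with pytest.raises(ValidationError):
            MeasureParams(mu_fp=-1.0, mu_fn=0.5)

    def test_unvalidated_pair_rejected(self):
        gt = EdgeMap.from_points((8, 8), [(0, 0)])
        dc = EdgeMap.empty((4, 4))
        with pytest.raises(ValidationError):
            m_measure(gt, dc)


class TestAutoParams:
    def test_delta_mode(self):
        gt = EdgeMap.from_points((3, 4), [(0, 0)])
        mu_fp, mu_fn = auto_params(gt, "delta")
        assert mu_fp == pytest.approx(1 / 13, abs=1e-12)
        assert mu_fn == pytest.approx(1 / math.sqrt(13), abs=1e-12)

    def test_diagonal_mode(self):
        gt = EdgeMap.from_points((3, 4), [(0, 0)])
        assert auto_params(gt, "diagonal") == pytest.approx((1 / 25, 1 / 5))

    def test_fixed_mode(self):
        gt = EdgeMap.from_points((3, 4), [(0, 0)])
        assert auto_params(gt, "fixed", fixed=(0.1, 0.2)) == (0.1, 0.2)
        with pytest.raises(ValidationError):
            auto_params(gt, "fixed")

    def test_fn_weight_exceeds_fp_weight(self, rng):
        # 1/Delta^2 < 1/Delta whenever Delta > 1
        for _ in range(20):
            gt, _ = random_pair(rng, max_side=24)
            mu_fp, mu_fn = auto_params(gt, "delta")
            assert mu_fp < mu_fn

    def test_unknown_mode(self):
        gt = EdgeMap.from_points((3, 4), [(0, 0)])
        with pytest.raises(ValidationError):
            auto_params(gt, "bogus")


class TestProperties:
    def test_identity_scores(self, rng):
        for _ in range(20):
            gt, _ = random_pair(rng)
            for s in score_all(gt, gt):
                assert s.value == pytest.approx(0.0 if s.name == "rde" else 1.0,
                                                abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_normalized_range(self, seed):
        rng = np.random.default_rng(seed)
        gt, dc = random_pair(rng, max_side=48)
        for s in score_all(gt, dc):
            if s.normalized:
                assert 0.0 <= s.value <= 1.0 + 1e-12, s
            else:
                assert s.value >= 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_m_symmetry_under_equal_mu(self, seed):
        # swapping the maps exchanges FP<->FN and the two distance sums
        rng = np.random.default_rng(seed)
        gt, dc = random_pair(rng, max_side=32)
        if dc.is_empty:
            return
        p = MeasureParams(mu_fp=0.07, mu_fn=0.07)
        assert m_measure(gt, dc, p).value == pytest.approx(
            m_measure(dc, gt, p).value, abs=1e-12)

    def test_fom_fp_zero_special_case(self, rng):
        for _ in range(50):
            gt, _ = random_pair(rng)
            coords = gt.coords()
            keep = coords[rng.random(len(coords)) < 0.6]
            dc = EdgeMap.from_points(gt.shape, map(tuple, keep))
            c = confusion_counts(gt, dc)
            assert c.fp == 0
            assert fom(gt, dc).value == c.tp / gt.n_points

    def test_emm_zero_without_tp(self, rng):
        for _ in range(30):
            gt, dc = random_pair(rng, overlap=0.0)
            dc = EdgeMap(dc.mask & ~gt.mask)
            assert emm(gt, dc).value == 0.0

    def test_fn_penalized_more_than_fp(self, rng):
        # same mistakes at the same distances score lower as misses than as
        # spurious detections when (muFP, muFN) = (1/Delta^2, 1/Delta)
        from edgemetrics import delta_max

        for _ in range(50):
            base, extra_src = random_pair(rng, max_side=32)
            extra = extra_src.point_set() - base.point_set()
            if not extra or delta_max(base) <= 1:
                # the automatic ordering muFP < muFN needs Delta > 1
                continue
            extra_map = EdgeMap.from_points(base.shape, extra)
            both = EdgeMap(base.mask | extra_map.mask)
            m_fp = m_measure(base, both)    # Gt=base, extras are FPs
            m_fn = m_measure(both, base)    # Gt=base+extras, extras are FNs
            assert m_fn.value < m_fp.value

    def test_score_all_matches_individual_calls(self, rng):
        gt, dc = random_pair(rng)
        if dc.is_empty:
            dc = EdgeMap.from_points(gt.shape, [(0, 0)])
        params = MeasureParams(mu_fp=0.05, mu_fn=0.1)
        combined = {s.name: s.value for s in score_all(gt, dc, params)}
        singles = {
            "dice": dice(gt, dc, params), "fom": fom(gt, dc, params),
            "f": f_measure(gt, dc, params), "d4": d4(gt, dc, params),
            "dp": dp(gt, dc, params), "emm": emm(gt, dc, params),
            "rde": rde(gt, dc, params), "m": m_measure(gt, dc, params),
        }
        for name, score in singles.items():
            assert combined[name] == pytest.approx(score.value, abs=1e-12)

    def test_score_all_request_order(self, rng):
        gt, dc = random_pair(rng)
        out = score_all(gt, dc, measures=["m", "dice"])
        assert [s.name for s in out] == ["m", "dice"]

    def test_score_all_unknown_measure(self, rng):
        gt, dc = random_pair(rng)
        with pytest.raises(ValidationError, match="unknown measure"):
            score_all(gt, dc, measures=["hausdorff"])


class TestOracleAgreement:
    """Spot cross-check against the brute-force oracle (the full 200-pair run
    lives in the acceptance suite)."""

    def test_all_measures_match_naive(self, rng):
        for _ in range(25):
            gt, dc = random_pair(rng, max_side=20, max_points=12)
            if dc.is_empty:
                continue
            g, d, shape = gt.point_set(), dc.point_set(), gt.shape
            params = MeasureParams(mu_fp=0.08, mu_fn=0.3)
            got = {s.name: s.value for s in score_all(gt, dc, params)}
            expected = {
                "dice": naive_oracle.dice(g, d, shape),
                "fom": naive_oracle.fom(g, d, shape),
                "f": naive_oracle.f_measure(g, d, shape),
                "d4": naive_oracle.d4(g, d, shape),
                "dp": naive_oracle.dp(g, d, shape),
                "emm": naive_oracle.emm(g, d, shape),
                "rde": naive_oracle.rde(g, d, shape),
                "m": naive_oracle.m_measure(g, d, shape, 0.08, 0.3),
            }
            for name, value in expected.items():
                assert got[name] == pytest.approx(value, abs=1e-9), name
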