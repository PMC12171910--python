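"""Method-comparison battery: each statistic against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bodycomp.agreement import (
    AgreementReport,
    bland_altman,
    cohens_d_paired,
    compare_arrays,
    compare_method,
    gower_index,
    lin_ccc,
    mape,
    passing_bablok,
    rank_equations,
    tost_min_equivalence,
)
from bodycomp.dilution import BodyComposition


class TestBlandAltman:
    def test_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        bias, sd, loa, (slope, p) = bland_altman(x + 0.5, x)
        assert bias == pytest.approx(0.5)
        assert sd == 0.0
        assert loa == (pytest.approx(0.5), pytest.approx(0.5))
        assert slope == 0.0

    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, sd, loa, _ = bland_altman(x, x)
        assert bias == 0.0 and sd == 0.0

    def test_loa_halfwidth_matches_196_sigma(self, rng):
        # sd 0.8 -> half-width 1.568 at large n
        x = rng.normal(20, 3, 5000)
        y = x - rng.normal(0, 0.8, 5000)
        bias, sd, loa, _ = bland_altman(x, y)
        half = (loa[1] - loa[0]) / 2
        assert half == pytest.approx(1.96 * 0.8, abs=0.05)

    def test_coverage_about_95_percent(self, rng):
        x = rng.normal(20, 3, 5000)
        y = x - rng.normal(0, 0.8, 5000)
        bias, sd, loa, _ = bland_altman(x, y)
        d = x - y
        cover = np.mean((d >= loa[0]) & (d <= loa[1]))
        assert abs(cover - 0.95) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestLinCcc:
    def test_identity_is_one(self, rng):
        x = rng.normal(size=50)
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_shift_closed_form(self):
        # population variance exactly 1: sqrt(3/2)*(-1,0,1)
        x = math.sqrt(1.5) * np.array([-1.0, 0.0, 1.0])
        y = x + 1.0
        assert lin_ccc(x, y) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_bounded_by_pearson(self, rng):
        for _ in range(100):
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(size=20)
            assert abs(lin_ccc(x, y)) <= abs(stats.pearsonr(x, y).statistic) \
                + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc(np.ones(5), np.arange(5.0))


class TestCohensD:
    def test_antisymmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert cohens_d_paired(x, y) == pytest.approx(-cohens_d_paired(y, x))

    def test_constant_difference_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            cohens_d_paired(x, x + 1.0)

    def test_symmetric_noise_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = x + rng.normal(0, 1, 5000)
        assert abs(cohens_d_paired(x, y)) < 0.05


class TestPassingBablok:
    def test_exact_line(self):
        x = np.arange(1.0, 16.0)
        slope, intercept, rsd = passing_bablok(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert rsd == pytest.approx(0.0, abs=1e-12)

    def test_swap_inverts_slope_on_exact_data(self):
        x = np.arange(1.0, 16.0)
        y = 2 * x + 1
        s_xy, _, _ = passing_bablok(x, y)
        s_yx, _, _ = passing_bablok(y, x)
        assert s_yx == pytest.approx(1.0 / s_xy, rel=1e-12)

    def test_matches_exhaustive_shifted_median_oracle(self, rng):
        n = 25
        x = rng.normal(10, 2, n)
        y = 1.2 * x + rng.normal(0, 1, n)
        slope, _, _ = passing_bablok(x, y)
        # independent brute force over all C(n,2) pairs
        slopes = []
        for i in range(n):
            for j in range(i + 1, n):
                dx = x[j] - x[i]
                dy = y[j] - y[i]
                if dx == 0 and dy == 0:
                    continue
                s = np.inf * np.sign(dy) if dx == 0 else dy / dx
                if s != -1.0:
                    slopes.append(s)
        slopes = np.sort(slopes)
        N = len(slopes)
        K = int(np.sum(slopes < -1))
        if N % 2:
            expected = slopes[(N + 1) // 2 + K - 1]
        else:
            expected = 0.5 * (slopes[N // 2 + K - 1] + slopes[N // 2 + K])
        assert slope == pytest.approx(expected, rel=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            passing_bablok(np.arange(5.0), np.arange(5.0))


class TestMape:
    def test_worked_example(self):
        assert mape([10.0, 20.0, 40.0], [9.0, 22.0, 40.0]) == \
            pytest.approx(10.0)

    def test_perfect_prediction(self):
        assert mape([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_single_outlier_bounded_by_order_statistics(self):
        # the median of 5 APEs with one value free always lies between the
        # 2nd and 3rd order statistics of the four fixed APEs - exhaustive
        # check over every corrupted position
        ref = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        pred = np.array([11.0, 19.0, 33.0, 42.0, 45.0])
        for i in range(5):
            rest = np.sort(np.delete(100 * np.abs(ref - pred) / ref, i))
            for corrupt in (1e6, -1e6, ref[i], pred[i] * 1.01):
                p2 = pred.copy()
                p2[i] = corrupt
                new = mape(ref, p2)
                assert rest[1] - 1e-12 <= new <= rest[2] + 1e-12

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([0.0, 1.0], [1.0, 1.0])


class TestTost:
    def test_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(10, 40)
            x = rng.normal(20, 2, n)
            y = x + rng.normal(0.1, 0.5, n)
            bound = tost_min_equivalence(x, y, resolution_pct=0.01)
            # dense grid at 0.001% steps around the returned bound
            d = x - y
            se = d.std(ddof=1) / math.sqrt(n)
            gm = np.mean(np.concatenate([x, y]))
            tcrit = stats.t.ppf(0.95, n - 1)

            def equivalent(delta_pct):
                delta = delta_pct / 100 * abs(gm)
                return ((d.mean() + delta) / se >= tcrit
                        and (delta - d.mean()) / se >= tcrit)

            grid = np.arange(max(bound - 0.05, 0), bound + 0.05, 0.001)
            passing = [g for g in grid if equivalent(g)]
            assert passing
            assert abs(bound - passing[0]) <= 0.011

    def test_monotone_nonincreasing_in_n(self, rng):
        # fixed mean/sd of differences, growing n shrinks the SE
        prev = None
        for n in (10, 20, 40, 80, 160):
            d = np.resize([0.5, -0.3, 0.4, -0.2], n)
            x = np.full(n, 20.0) + d
            y = np.full(n, 20.0)
            b = tost_min_equivalence(x, y)
            if prev is not None:
                assert b <= prev + 1e-9
            prev = b

    def test_tiny_jitter_bound_near_zero(self, rng):
        x = np.full(50, 20.0) + rng.normal(0, 1e-6, 50)
        y = np.full(50, 20.0) + rng.normal(0, 1e-6, 50)
        b = tost_min_equivalence(x, y)
        assert 0 < b < 0.02


class TestGower:
    def test_identity_is_one(self):
        x = np.array([1.0, 5.0, 9.0])
        assert gower_index(x, x) == 1.0

    def test_maximal_discrepancy_is_zero(self):
        assert gower_index([0.0, 0.0], [4.0, 4.0]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, a):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        y = np.array([1.5, 2.5, 4.0, 8.0])
        assert gower_index(a * x, a * y) == pytest.approx(gower_index(x, y),
                                                          rel=1e-9)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            gower_index([2.0, 2.0], [2.0, 2.0])


class TestCompareAndRank:
    @staticmethod
    def _bc(weight, pbf, tag=""):
        fm = weight * pbf / 100
        return BodyComposition(tbw_l=(weight - fm) * 0.765,
                               ffm_kg=weight - fm, fm_kg=fm, pbf=pbf,
                               method_tag=tag)

    def test_identical_inputs_perfect_report(self, rng):
        comps = [self._bc(w, p) for w, p in
                 zip(rng.uniform(20, 50, 20), rng.uniform(15, 55, 20))]
        rep = compare_method(comps, comps, quantity="ffm_kg")
        assert rep.bias == 0.0
        assert rep.lin_ccc == pytest.approx(1.0)
        assert rep.gower == 1.0
        assert rep.mape_pct == 0.0

    def test_report_serialization_round_trip(self, rng):
        x = rng.normal(20, 3, 30)
        y = x + rng.normal(0, 1, 30)
        rep = compare_arrays(x, y, label="demo")
        back = AgreementReport.from_dict(rep.to_dict())
        assert back == rep

    def test_report_invariants(self, rng):
        x = rng.normal(20, 3, 50)
        y = x + rng.normal(0.4, 1, 50)
        r = compare_arrays(x, y)
        assert r.loa_low <= r.bias <= r.loa_high
        assert -1 <= r.pearson_r <= 1
        assert abs(r.lin_ccc) <= abs(r.pearson_r) + 1e-12
        assert 0 <= r.gower <= 1
        assert r.mape_pct >= 0

    def test_unit_rescaling_behaviour(self, rng):
        x = rng.normal(20, 3, 40)
        y = x + rng.normal(0.2, 0.8, 40)
        a = compare_arrays(x, y)
        b = compare_arrays(10 * x, 10 * y)
        assert b.gower == pytest.approx(a.gower, rel=1e-9)
        assert b.pearson_r == pytest.approx(a.pearson_r, rel=1e-9)
        assert b.lin_ccc == pytest.approx(a.lin_ccc, rel=1e-9)
        assert b.cohen_d_paired == pytest.approx(a.cohen_d_paired, rel=1e-9)
        assert b.mape_pct == pytest.approx(a.mape_pct, rel=1e-9)
        assert b.bias == pytest.approx(10 * a.bias, rel=1e-9)
        assert b.loa_high == pytest.approx(10 * a.loa_high, rel=1e-9)

    def test_few_pairs_omits_passing_bablok_with_warning(self, rng):
        x = rng.normal(20, 2, 8)
        y = x + rng.normal(0, 1, 8)
        with pytest.warns(UserWarning, match="Passing-Bablok"):
            rep = compare_arrays(x, y)
        assert rep.pb_slope is None
        assert rep.bias == pytest.approx(np.mean(x - y))

    def test_rank_dominant_report_first(self, rng):
        x = rng.normal(20, 3, 40)
        good = compare_arrays(x, x + rng.normal(0, 0.2, 40), label="good")
        bad = compare_arrays(x, x + rng.normal(2.0, 1.0, 40), label="bad")
        table = rank_equations([bad, good])
        assert table.iloc[0]["eq_id"] == "good"
        assert table.iloc[0]["overall_rank"] == 1

    def test_rank_order_invariance(self, rng):
        x = rng.normal(20, 3, 40)
        reports = [compare_arrays(x, x + rng.normal(b, 0.5, 40),
                                  label=f"eq{b}") for b in (0.1, 0.5, 1.0)]
        t1 = rank_equations(reports)
        t2 = rank_equations(reports[::-1])
        assert list(t1["eq_id"]) == list(t2["eq_id"])

    def test_rank_mean_rank_matches_hand_computation(self):
        def rep(label, mape_pct, tost, gower):
            return AgreementReport(
                label=label, n=20, bias=0.0, sd_diff=1.0, loa_low=-2.0,
                loa_high=2.0, pearson_r=0.9, lin_ccc=0.9,
                cohen_d_paired=0.0, paired_t_p=0.9, pb_slope=1.0,
                pb_intercept=0.0, pb_rsd=1.0, mape_pct=mape_pct,
                tost_bound_pct=tost, gower=gower, prop_bias_slope=0.0,
                prop_bias_p=1.0)

        reports = [rep("a", 2.0, 1.0, 0.95), rep("b", 3.0, 0.5, 0.90),
                   rep("c", 1.0, 2.0, 0.99), rep("d", 4.0, 3.0, 0.80)]
        table = rank_equations(reports).set_index("eq_id")
        # hand ranks: mape a=2,b=3,c=1,d=4; tost a=2,b=1,c=3,d=4;
        # gower(desc) a=2,b=3,c=1,d=4 -> means a=2, b=7/3, c=5/3, d=4
        assert table.loc["a", "mean_rank"] == pytest.approx(2.0)
        assert table.loc["b", "mean_rank"] == pytest.approx(7 / 3)
        assert table.loc["c", "mean_rank"] == pytest.approx(5 / 3)
        assert table.loc["d", "mean_rank"] == pytest.approx(4.0)
        assert list(table.index) == ["c", "a", "b", "d"]
        assert list(table["overall_rank"]) == [1, 2, 3, 4]
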