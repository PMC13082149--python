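"""Statistics layer: filtering, CV combinatorics, SSMD, power, 4PL fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from wormdart.stats import (
    FourPLFit,
    UnidentifiableFitError,
    combo_cv_analysis,
    compare_fits,
    cv_percent,
    ec_f,
    fit_4pl,
    fourpl,
    l1_bottom_constraints,
    l1_cylinder_volume,
    normalize_and_rank,
    normalize_response,
    oneway_anova,
    p_stars,
    power_min_effect,
    power_one_sample,
    ssmd,
    tukey_filter,
    well_means,
)


def worm_table(volumes, totals=None, well="W01"):
    n = len(volumes)
    totals = totals if totals is not None else [40] * n
    return pd.DataFrame({
        "experiment": ["exp1"] * n, "well": [well] * n,
        "channel": range(n), "volume_um3": volumes, "total_count": totals,
    })


class TestTukeyFilter:
    def test_hand_computed_fences(self):
        # volumes {1,2,3,4,100}: Q1=2, Q3=4, fences [-1, 7] -> 100 out
        kept, excl = tukey_filter(worm_table([1, 2, 3, 4, 100]))
        assert list(excl["volume_um3"]) == [100]
        assert len(kept) == 4

    def test_identical_values_nothing_excluded(self):
        kept, excl = tukey_filter(worm_table([5.0] * 6))
        assert len(excl) == 0 and len(kept) == 6

    def test_or_rule_across_endpoints(self):
        # normal volume, outlying embryo count -> still excluded
        kept, excl = tukey_filter(worm_table([10, 11, 12, 13, 12],
                                             totals=[40, 41, 42, 43, 400]))
        assert len(excl) == 1
        assert excl.iloc[0]["outlier_endpoints"] == "total_count"

    def test_small_group_passes_with_warning(self):
        with pytest.warns(UserWarning):
            kept, excl = tukey_filter(worm_table([1, 2, 100]))
        assert len(kept) == 3 and len(excl) == 0

    @given(scale=st.floats(0.1, 100), shift=st.floats(-1e4, 1e4))
    def test_affine_invariance(self, scale, shift):
        vols = [10, 12, 11, 13, 95, 12, 14]
        base_kept, _ = tukey_filter(worm_table(vols))
        trans_kept, _ = tukey_filter(worm_table([scale * v + shift for v in vols]))
        assert list(base_kept["channel"]) == list(trans_kept["channel"])


class TestWellMeans:
    def test_means_match_hand_average(self):
        df = worm_table([10.0, 20.0, 30.0, 40.0])
        out = well_means(df, endpoints=("volume_um3", "total_count"))
        assert out.iloc[0]["volume_um3"] == pytest.approx(25.0)
        assert out.iloc[0]["n_after"] == 4

    def test_emptied_well_flagged(self):
        df = worm_table([10.0, 20.0])
        n_before = pd.Series([2, 3], index=pd.MultiIndex.from_tuples(
            [("exp1", "W01"), ("exp1", "W02")], names=["experiment", "well"]))
        out = well_means(df, endpoints=("volume_um3",), n_before=n_before)
        emptied = out[out["well"] == "W02"]
        assert emptied.iloc[0]["emptied"]
        assert emptied.iloc[0]["n_after"] == 0


class TestCV:
    def test_examples(self):
        assert cv_percent([5, 5, 5]) == 0.0
        assert cv_percent([8, 10, 12]) == pytest.approx(20.0)

    @given(st.lists(st.floats(1, 1e3), min_size=2, max_size=10),
           st.floats(0.5, 50))
    def test_scale_invariance(self, values, scale):
        if np.mean(values) == 0:
            return
        assert cv_percent(np.array(values) * scale) == pytest.approx(
            cv_percent(values), rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            cv_percent([1.0])
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


def wells_frame(n_reps=5, n_pos=4, cv=0.05, seed=0, base=100.0):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        f = rng.lognormal(-0.5 * math.log(1 + cv**2), math.sqrt(math.log(1 + cv**2))) \
            if cv > 0 else 1.0
        for p in range(1, n_pos + 1):
            rows.append({"experiment": f"exp{rep}", "well": f"W{p:02d}",
                         "condition": "control", "volume_um3": base * f})
    return pd.DataFrame(rows)


class TestComboCV:
    def test_combination_count_5_choose_3(self):
        res = combo_cv_analysis(wells_frame(), endpoints=("volume_um3",))
        r = res[0]
        assert r.combinations_per_position == 10
        assert len(r.cvs) == 10 * 4

    def test_single_combination_sem_undefined(self):
        res = combo_cv_analysis(wells_frame(n_reps=3, n_pos=1),
                                endpoints=("volume_um3",))
        assert len(res[0].cvs) == 1
        assert res[0].sem_cv is None

    def test_identical_means_zero_cv(self):
        res = combo_cv_analysis(wells_frame(cv=0.0), endpoints=("volume_um3",))
        assert res[0].mean_cv == 0.0

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            combo_cv_analysis(wells_frame(n_reps=2), endpoints=("volume_um3",))

    @pytest.mark.parametrize("n,k", [(n, k) for n in range(3, 9) for k in range(2, n + 1)])
    def test_counts_match_bruteforce_subsets(self, n, k):
        res = combo_cv_analysis(wells_frame(n_reps=n, n_pos=1),
                                endpoints=("volume_um3",), k=k)
        brute = len(list(itertools.combinations(range(n), k)))
        assert len(res[0].cvs) == brute == math.comb(n, k)


class TestSSMD:
    def test_identical_groups(self):
        r = ssmd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.value == 0.0 and r.quality == "weak"

    def test_closed_form_exact_moments(self):
        # control (mu=10, sd=1), treated (mu=5, sd=1) -> 5/sqrt(2) ~ 3.54
        r = ssmd([9.0, 10.0, 11.0], [4.0, 5.0, 6.0])
        assert r.value == pytest.approx(5.0 / math.sqrt(2.0))
        assert r.quality == "excellent"

    def test_good_quality_band(self):
        shift = 2.5 * math.sqrt(2.0)
        r = ssmd([9.0, 10.0, 11.0], [9.0 - shift, 10.0 - shift, 11.0 - shift])
        assert r.value == pytest.approx(2.5)
        assert r.quality == "good"

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(10, 1, 8), rng.normal(7, 2, 8)
        assert ssmd(a, b).value == pytest.approx(-ssmd(b, a).value)
        assert ssmd(3 * a, 3 * b).value == pytest.approx(ssmd(a, b).value)

    def test_zero_variance_flagged(self):
        r = ssmd([5.0, 5.0], [3.0, 3.0])
        assert r.infinite_separation


class TestPower:
    def test_zero_effect_equals_alpha(self):
        assert power_one_sample(0.0, 100, 5, n=3, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_effect_and_n(self):
        p10 = power_one_sample(0.10, 100, 5, n=3)
        p20 = power_one_sample(0.20, 100, 5, n=3)
        assert p20 > p10
        assert power_one_sample(0.10, 100, 5, n=6) > p10

    def test_matches_monte_carlo_oracle(self):
        # independent oracle: simulate the one-sample one-tailed t test
        rng = np.random.default_rng(77)
        mean, sd, n, alpha, eff = 100.0, 5.0, 3, 0.05, 0.5
        x = rng.normal(mean * (1 - eff), sd, (100_000, n))
        t = (mean - x.mean(axis=1)) / (x.std(axis=1, ddof=1) / math.sqrt(n))
        mc = float((t > sps.t.ppf(1 - alpha, n - 1)).mean())
        assert float(power_one_sample(eff, mean, sd, n, alpha)) == pytest.approx(mc, abs=0.005)

    def test_min_detectable_effect_interpolated(self):
        pc = power_min_effect(100.0, 2.0, n=3)
        assert pc.min_detectable_effect is not None
        # power at the reported effect is ~0.80
        assert float(power_one_sample(pc.min_detectable_effect, 100.0, 2.0, 3)) == \
            pytest.approx(0.80, abs=0.02)


class TestAnova:
    def test_hand_computed_f(self):
        F, p = oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert F == pytest.approx(3.0)

    def test_identical_groups(self):
        F, p = oneway_anova([[2, 2], [2, 2], [2, 2]])
        assert F == 0.0 and p == 1.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            oneway_anova([[1, 2, 3]])


class TestFit4PL:
    CONC = np.concatenate([[0.0], np.geomspace(0.05, 30.0, 10)])

    def test_noiseless_recovery_free_bottom(self):
        y = fourpl(self.CONC, 45.0, 0.0, 1.5, 2.0)
        fit = fit_4pl(self.CONC, y, bottom="free")
        assert fit.top == pytest.approx(45.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(1.5, rel=1e-6)
        assert fit.hill == pytest.approx(2.0, rel=1e-6)
        assert abs(fit.bottom) < 1e-6 * 45

    def test_fixed_vs_free_bottom_same_ec50(self):
        y = fourpl(self.CONC, 45.0, 0.0, 1.5, 2.0)
        free = fit_4pl(self.CONC, y, bottom="free")
        fixed = fit_4pl(self.CONC, y, bottom=0.0)
        assert fixed.ec50 == pytest.approx(free.ec50, rel=1e-6)

    def test_constant_response_unidentifiable(self):
        with pytest.raises(UnidentifiableFitError):
            fit_4pl(self.CONC, np.full_like(self.CONC, 42.0))

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_4pl([0, 1, 2, 3], [4, 3, 2, 1])

    def test_curve_decreasing_and_top_at_zero(self):
        y = fourpl(self.CONC, 45.0, 5.0, 2.0, 1.5)
        fit = fit_4pl(self.CONC, y)
        grid = np.geomspace(0.01, 100, 50)
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) <= 1e-9)
        assert fit.predict(0.0) == pytest.approx(fit.top)


class TestECF:
    def _fit(self, ec50, hill):
        return FourPLFit(top=45, bottom=0, log_ec50=math.log(ec50),
                         log_hill=math.log(hill), bottom_fixed=True, cov=None,
                         ssr=0, dof=1, n=11, converged=True,
                         param_names=("top", "log_ec50", "log_hill"))

    def test_ec50_is_fixed_point(self):
        assert ec_f(self._fit(4.0, 3.0), 50).value == pytest.approx(4.0)

    def test_closed_forms(self):
        assert ec_f(self._fit(4.0, 1.0), 10).value == pytest.approx(4 * 10 / 90)
        assert ec_f(self._fit(4.0, 2.0), 90).value == pytest.approx(12.0)

    def test_monotone_in_f(self):
        fit = self._fit(2.0, 2.0)
        vals = [ec_f(fit, F).value for F in (10, 25, 50, 75, 90)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_f(self):
        with pytest.raises(ValueError):
            ec_f(self._fit(1, 1), 0)
        with pytest.raises(ValueError):
            ec_f(self._fit(1, 1), 100)

    def test_ci_contains_point_estimate(self):
        conc = np.repeat(np.concatenate([[0.0], np.geomspace(0.05, 30, 9)]), 3)
        rng = np.random.default_rng(3)
        y = fourpl(conc, 45, 0, 1.5, 2) * (1 + rng.normal(0, 0.05, conc.size))
        fit = fit_4pl(conc, y, bottom=0.0)
        for F in (10, 25, 50):
            est = ec_f(fit, F)
            assert est.ci_low < est.value < est.ci_high


class TestCompareFits:
    CONC = np.concatenate([[0.0], np.geomspace(0.05, 30.0, 10)])

    def test_duplicate_datasets(self):
        y = fourpl(self.CONC, 45, 0, 1.5, 2)
        F, p = compare_fits((self.CONC, y), (self.CONC, y))
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0)

    def test_three_point_dataset_rejected(self):
        with pytest.raises(ValueError):
            compare_fits(([0, 1, 2], [3, 2, 1]), (self.CONC, fourpl(self.CONC, 3, 0, 1, 1)))

    def test_separated_ec50s_detected(self):
        """EC50 1 vs 4 at 5% noise: rejected in >= 95/100 seeded runs."""
        hits = 0
        conc = np.repeat(self.CONC, 3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ya = fourpl(conc, 45, 0, 1.0, 2) * (1 + rng.normal(0, 0.05, conc.size))
            yb = fourpl(conc, 45, 0, 4.0, 2) * (1 + rng.normal(0, 0.05, conc.size))
            _, p = compare_fits((conc, ya), (conc, yb), bottom=0.0)
            hits += p < 0.01
        assert hits >= 95


class TestNormalizeAndRank:
    def test_normalization_fixed_points(self):
        assert normalize_response(45.0, 45.0, 5.0) == pytest.approx(100.0)
        assert normalize_response(5.0, 45.0, 5.0) == pytest.approx(0.0)

    def test_configured_ordering_recovered(self):
        """EC50 ratios 1:2:5 -> EC10 ordering matches in >= 95/100 seeds."""
        conc = np.repeat(np.concatenate([[0.0], np.geomspace(0.05, 30, 9)]), 3)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            fits = {}
            for ep, e50 in (("late", 1.0), ("total", 2.0), ("length", 5.0)):
                y = fourpl(conc, 45, 0, e50, 2.5) * (1 + rng.normal(0, 0.05, conc.size))
                fits[ep] = fit_4pl(conc, y, bottom=0.0)
            order = list(normalize_and_rank(fits, F=10)["endpoint"])
            hits += order == ["late", "total", "length"]
        assert hits >= 95


class TestConstantsAndFormatting:
    def test_l1_cylinder_volume(self):
        assert l1_cylinder_volume() == pytest.approx(11775.0)
        constraints = l1_bottom_constraints()
        assert constraints["volume_um3"] == pytest.approx(11775.0)
        assert constraints["total_count"] == 0.0

    def test_p_star_thresholds(self):
        assert p_stars(0.2) == "ns"
        assert p_stars(0.03) == "*"
        assert p_stars(0.005) == "**"
        assert p_stars(0.0005) == "***"
        assert p_stars(1e-5) == "****"
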