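"""Tests of the descriptive battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoprec import behavioral_stats as bs
from endoprec import synthetic_data as sd
from endoprec.specs import SubjectPopulation


class TestBins:
    def test_printed_ranges(self):
        assert bs.default_bins("Narrow").ranges == (
            (50, 52), (53, 57), (58, 62), (63, 67), (68, 70))
        assert bs.default_bins("Medium").ranges[2] == (56, 64)
        assert bs.default_bins("Wide").ranges == (
            (30, 40), (41, 53), (54, 66), (67, 79), (80, 90))

    @pytest.mark.parametrize("cond", ["Narrow", "Medium", "Wide"])
    def test_partition_of_support(self, cond):
        scheme = bs.default_bins(cond)
        support = sd.ESTIMATION_PRIORS[cond].support()
        idx = scheme.assign(support)
        assert (idx >= 0).all()
        # every integer in exactly one bin and the bins are ordered
        assert np.all(np.diff(idx) >= 0)
        widths = [hi - lo + 1 for lo, hi in scheme.ranges]
        assert sum(widths) == len(support)

    def test_middle_bin_centered(self):
        for cond, prior in sd.ESTIMATION_PRIORS.items():
            lo, hi = bs.default_bins(cond).ranges[2]
            assert (lo + hi) / 2 == prior.midpoint

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            bs.default_bins("Huge")


class TestExcursionVariance:
    def test_constant_responses_zero(self):
        t = pd.DataFrame({"x": [55, 55, 60, 60], "response": [54, 54, 61, 61]})
        out = bs.excursion_variance(t, bs.default_bins("Narrow"))
        assert (out.dropna(subset=["variance"]).variance == 0).all()

    def test_hand_computed_pair(self):
        t = pd.DataFrame({"x": [60, 60], "response": [58, 62]})
        out = bs.excursion_variance(t, bs.default_bins("Narrow"), ddof=0)
        assert out.loc[out.bin == 2, "variance"].iloc[0] == pytest.approx(4.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(50, 71, 200)
        resp = np.clip(x + rng.integers(-4, 5, 200), 50, 70)
        t1 = pd.DataFrame({"x": x, "response": resp})
        t2 = t1.copy()
        t2.loc[t2.x == 60, "response"] += 7  # shift all responses to one number
        v1 = bs.excursion_variance(t1, bs.default_bins("Narrow"))
        v2 = bs.excursion_variance(t2, bs.default_bins("Narrow"))
        assert np.allclose(v1.variance.dropna(), v2.variance.dropna())

    def test_empty_bin_is_missing(self):
        t = pd.DataFrame({"x": [60, 60], "response": [59, 61]})
        out = bs.excursion_variance(t, bs.default_bins("Narrow"))
        assert np.isnan(out.loc[out.bin == 0, "variance"].iloc[0])


class TestCvAndRelativeError:
    def test_constant_responses(self):
        t = pd.DataFrame({"x": [60] * 5, "response": [58] * 5})
        assert (bs.cv_curve(t).cv == 0).all()

    def test_hand_computed_cv(self):
        t = pd.DataFrame({"x": [60, 60], "response": [50, 70]})
        out = bs.cv_curve(t, ddof=0)
        assert out.cv.iloc[0] == pytest.approx(10 / 60)

    def test_scalar_variability_gives_flat_cv(self):
        # sd proportional to x -> constant coefficient of variation
        rng = np.random.default_rng(1)
        xs = np.repeat(np.arange(30, 91), 400)
        resp = xs * (1 + 0.15 * rng.standard_normal(len(xs)))
        out = bs.cv_curve(pd.DataFrame({"x": xs, "response": resp}))
        assert out.cv.std() / out.cv.mean() < 0.1
        assert out.cv.mean() == pytest.approx(0.15, rel=0.1)

    def test_relative_error(self):
        t = pd.DataFrame({"x": [60], "response": [66]})
        out = bs.relative_error(t, w=20)
        assert out == {"mean_abs_error": 6.0, "ratio": pytest.approx(0.30)}


class TestAffineExtrapolate:
    def test_width_squared_worked_example(self):
        v = bs.affine_extrapolate([(20, 17.64), (40, 46.24)], "width_squared", 60)
        assert round(v, 2) == 93.91

    def test_width_worked_example(self):
        v = bs.affine_extrapolate([(20, 17.64), (40, 46.24)], "width", 60)
        assert v == pytest.approx(74.84, abs=1e-9)

    @given(st.floats(1, 100), st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_interpolation_identity(self, w1, v1, v2):
        w2 = w1 + 10.0
        for tf in ("width", "width_squared"):
            out = bs.affine_extrapolate([(w1, v1), (w2, v2)], tf, w2)
            assert out == pytest.approx(v2, abs=1e-6)

    def test_coincident_abscissae_raise(self):
        with pytest.raises(ValueError):
            bs.affine_extrapolate([(20, 1.0), (20, 2.0)], "width", 60)


class TestPsychometric:
    def test_noiseless_choices_perfect_in_nonzero_bins(self):
        pn = SubjectPopulation(n_subjects=1, nu_median=0.0, nu_log_sd=0.0, seed=1)
        pw = SubjectPopulation(n_subjects=1, nu_median=0.0, nu_log_sd=0.0, seed=2)
        t = sd.gen_discrimination(pn, pw, trials=400)
        out = bs.psychometric_bins(t, 0.75)["correct"]
        filled = out.dropna(subset=["p"])
        assert (filled[filled.x > 0].p == 1.0).all()

    def test_balanced_at_zero_difference(self, discrimination_table):
        out = bs.psychometric_bins(discrimination_table, 0.75, n_bins=21)["signed"]
        central = out.dropna(subset=["p"]).loc[lambda f: f.x.abs() < 0.4]
        assert len(central) > 0
        # allow a small offset because the bin center is not exactly zero
        assert ((central.ci_lo <= 0.53) & (central.ci_hi >= 0.47)).all()

    def test_collapse_best_at_true_exponent(self):
        pn = SubjectPopulation(n_subjects=31, nu_median=0.22, nu_log_sd=0.0,
                               shared_alpha=0.75, lapse_eta=0.05, seed=21)
        pw = SubjectPopulation(n_subjects=32, nu_median=0.22, nu_log_sd=0.0,
                               shared_alpha=0.75, lapse_eta=0.05, seed=22)
        t = sd.gen_discrimination(pn, pw, trials=1000)
        gaps = {a: bs.psychometric_collapse_gap(t, a) for a in (0.5, 0.75, 1.0)}
        assert gaps[0.75] < gaps[0.5]
        assert gaps[0.75] < gaps[1.0]


class TestClassicTests:
    def test_levene_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = bs.levene([g, g])
        assert res["W"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_levene_detects_unequal_variances(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 3, 500)
        assert bs.levene([a, b])["p"] < 1e-6

    def test_fisher_exact_against_enumeration(self):
        # [[10,0],[0,10]]: only the two extreme tables are as extreme;
        # p = 2 / C(20,10)
        from math import comb

        res = bs.fisher_exact_2x2([[10, 0], [0, 10]])
        assert res["p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_holm_stepdown(self):
        assert np.allclose(bs.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_holm_properties(self, pvals):
        adj = bs.holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone: ordering of adjusted values follows ordering of raw ones
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestHalfSplit:
    def test_missing_column_raises(self):
        with pytest.raises(ValueError):
            bs.half_split(pd.DataFrame({"x": [1]}), "estimation")

    def test_concatenating_halves_reproduces_full_summary(self, small_estimation_table):
        _, table = small_estimation_table
        narrow = table[table.condition == "Narrow"]
        bins = bs.default_bins("Narrow")
        full = bs.excursion_variance(narrow, bins)
        halves = pd.concat(
            [narrow[narrow.half == "first"], narrow[narrow.half == "second"]]
        )
        again = bs.excursion_variance(halves, bins)
        assert np.allclose(full.variance.dropna(), again.variance.dropna())

    def test_stationary_generator_rarely_flags_halves(self):
        flagged = 0
        n_rep = 15
        for i in range(n_rep):
            # per-number trial counts must be reasonably large: Levene on
            # mean-subtracted excursions is anticonservative in tiny cells
            pop = SubjectPopulation(n_subjects=8, nu_log_sd=0.0, sigma0_log_sd=0.0,
                                    seed=500 + i)
            t = sd.gen_estimation(
                pop, priors={"Narrow": sd.ESTIMATION_PRIORS["Narrow"]},
                trials_per_condition=120,
            )
            res = bs.half_split(t, "estimation")
            if (res["tests"].p_holm < 0.05).any():
                flagged += 1
        assert flagged <= max(1, int(0.1 * n_rep) + 1)
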