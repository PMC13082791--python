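"""Tests of the maximum-likelihood machinery and model-comparison tools."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from endoprec import model_fitting as mf
from endoprec import synthetic_data as sd
from endoprec.specs import SubjectPopulation

TWO_PRIORS = {k: sd.ESTIMATION_PRIORS[k] for k in ("Narrow", "Medium")}


class TestBic:
    def test_formula(self):
        assert mf.bic(-5.0, 2, 10) == pytest.approx(2 * np.log(10) + 10)
        assert mf.bic(0.0, 0, 7) == 0.0

    def test_monotone_in_k(self):
        vals = [mf.bic(-10.0, k, 50) for k in range(5)]
        assert np.all(np.diff(vals) > 0)

    def test_fit_result_identity(self):
        res = mf.FitResult(mf.FitStructure(), {"nu": 1.0}, logL=-12.5, k=2, N=30)
        assert res.bic == pytest.approx(2 * np.log(30) + 25.0, abs=1e-9)


class TestEstimationNll:
    def test_additivity_under_duplication(self, small_estimation_table):
        _, table = small_estimation_table
        st = mf.FitStructure()
        params = {"nu": 1.0, "sigma0": 2.0}
        one = mf.estimation_nll(table, params, st, priors=TWO_PRIORS)
        two = mf.estimation_nll(
            pd.concat([table, table], ignore_index=True), params, st, priors=TWO_PRIORS
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_row_order_invariance(self, small_estimation_table):
        _, table = small_estimation_table
        st = mf.FitStructure()
        params = {"nu": 1.0, "sigma0": 2.0}
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = mf.estimation_nll(table, params, st, priors=TWO_PRIORS)
        b = mf.estimation_nll(shuffled, params, st, priors=TWO_PRIORS)
        assert a == pytest.approx(b, rel=1e-12)

    def test_true_parameters_beat_perturbed(self, small_estimation_table):
        _, table = small_estimation_table
        st = mf.FitStructure()
        at_truth = mf.estimation_nll(table, {"nu": 1.0, "sigma0": 2.0}, st, priors=TWO_PRIORS)
        perturbed = mf.estimation_nll(table, {"nu": 2.0, "sigma0": 2.0}, st, priors=TWO_PRIORS)
        assert at_truth < perturbed

    def test_out_of_range_response_raises(self, small_estimation_table):
        _, table = small_estimation_table
        bad = table.copy()
        bad.loc[bad.index[0], "response"] = 5
        with pytest.raises(ValueError):
            mf.estimation_nll(bad, {"nu": 1.0, "sigma0": 2.0}, mf.FitStructure(), priors=TWO_PRIORS)


class TestFitEstimation:
    def test_nesting_free_alpha_dominates_fixed(self, small_estimation_table):
        _, table = small_estimation_table
        starts = [(1.0, 2.0, 0.5), (0.6, 1.0, 0.4)]
        fixed = mf.fit_estimation(
            table, mf.FitStructure(alpha_mode="fixed", alpha_value=0.5),
            starts=starts, priors=TWO_PRIORS,
        )
        free = mf.fit_estimation(
            table, mf.FitStructure(alpha_mode="shared_free", alpha_value=None),
            starts=starts, priors=TWO_PRIORS,
        )
        assert free.logL >= fixed.logL - 1e-6
        assert free.k == fixed.k + 1

    def test_motor_noise_only_structure(self, small_estimation_table):
        _, table = small_estimation_table
        res = mf.fit_estimation(
            table,
            mf.FitStructure(alpha_mode="fixed", alpha_value=0.0, nu_mode="zero",
                            sigma0_mode="shared_per_condition"),
            starts=[(0.0, 3.0, 0.0)], priors=TWO_PRIORS,
        )
        assert res.k == 2  # one sigma0 per condition, no nu, no alpha
        assert np.all(np.asarray(res.params["sigma0"]) > 0)

    def test_structure_validation(self):
        with pytest.raises(ValueError):
            mf.FitStructure(alpha_mode="shared_free", nu_mode="zero")


class TestFitDiscrimination:
    def test_balanced_coin_flip_data_gives_ln2_per_trial(self):
        n = 400
        rng = np.random.default_rng(0)
        d = rng.uniform(-1e-9, 1e-9, n)
        table = pd.DataFrame(
            {
                "subject": 0,
                "condition": "Narrow",
                "x_R": 50 + d,
                "x_B": 50.0,
                "choice": np.where(np.arange(n) % 2 == 0, "red", "blue"),
            }
        )
        st = mf.FitStructure(alpha_mode="fixed", alpha_value=0.75)
        nll = mf.discrimination_nll(table, {"nu": 0.3}, st)
        assert nll == pytest.approx(n * np.log(2), rel=1e-6)

    def test_identifiability_error_single_condition(self, discrimination_table):
        narrow = discrimination_table[discrimination_table.condition == "Narrow"]
        st = mf.FitStructure(alpha_mode="shared_free", alpha_value=None)
        with pytest.raises(ValueError):
            mf.fit_discrimination(narrow, st)

    def test_recovery_and_bic_grid(self, discrimination_table):
        st = mf.FitStructure(alpha_mode="shared_free", alpha_value=None, lapse="shared")
        free = mf.fit_discrimination(discrimination_table, st)
        assert free.params["alpha"] == pytest.approx(0.75, abs=0.12)
        bics = {}
        for av in (0.5, 0.75, 1.0):
            stf = mf.FitStructure(alpha_mode="fixed", alpha_value=av, lapse="shared")
            bics[av] = mf.fit_discrimination(discrimination_table, stf).bic
        assert bics[0.75] < bics[0.5]
        assert bics[0.75] < bics[1.0]

    def test_row_order_invariance(self, discrimination_table):
        st = mf.FitStructure(alpha_mode="fixed", alpha_value=0.75, lapse="shared")
        a = mf.fit_discrimination(discrimination_table, st)
        shuffled = discrimination_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = mf.fit_discrimination(shuffled, st)
        assert a.logL == pytest.approx(b.logL, rel=1e-9)
        assert a.params["nu"] == pytest.approx(b.params["nu"], rel=1e-6)


class TestSplitMagnitudeProbit:
    @staticmethod
    def _simulate(rng, n, scale_small, scale_large, threshold=50.0, half_width=40.0):
        xr = rng.uniform(threshold - half_width, threshold + half_width, n)
        xb = np.clip(xr + rng.uniform(-12, 12, n), threshold - half_width, threshold + half_width)
        small = (xr < threshold) & (xb < threshold)
        large = (xr > threshold) & (xb > threshold)
        keep = small | large
        xr, xb, small = xr[keep], xb[keep], small[keep]
        scale = np.where(small, scale_small, scale_large)
        p = ndtr((xr - xb) / scale)
        choice = np.where(rng.random(len(p)) < p, "red", "blue")
        return pd.DataFrame({"x_R": xr, "x_B": xb, "choice": choice})

    def test_duplicated_strata_no_improvement(self, rng):
        t = self._simulate(rng, 3000, 6.0, 6.0)
        res = mf.split_magnitude_probit(t)
        assert res["LR_chi2"] >= 0.0
        assert res["logL_full"] >= res["logL_restricted"] - 1e-6

    def test_scale_ratio_recovery(self, rng):
        t = self._simulate(rng, 30_000, 6.0, 7.8)
        res = mf.split_magnitude_probit(t)
        assert res["scale_large"] / res["scale_small"] == pytest.approx(1.3, abs=0.1)

    def test_type_one_error_rate(self):
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            t = self._simulate(rng, 2500, 6.0, 6.0)
            if mf.split_magnitude_probit(t)["p"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.11

    def test_empty_stratum_raises(self):
        t = pd.DataFrame({"x_R": [55.0, 60.0], "x_B": [56.0, 58.0], "choice": ["red", "blue"]})
        with pytest.raises(ValueError):
            mf.split_magnitude_probit(t)


class TestKsMatch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = mf.ks_match({"a": x, "b": x}, {"a": 1.0, "b": 1.0}, alpha=0.5)
        assert res["D"] == pytest.approx(0.0)

    def test_common_rescaling_leaves_d_unchanged(self, rng):
        a, b = rng.lognormal(0, 0.3, 31), rng.lognormal(0.2, 0.3, 32)
        w = {"n": 30.0, "w": 80.0}
        r1 = mf.ks_match({"n": a, "w": b}, w, alpha=0.75)
        r2 = mf.ks_match({"n": 10 * a, "w": 10 * b}, w, alpha=0.75)
        assert r1["D"] == pytest.approx(r2["D"])

    def test_correct_exponent_matches_distributions(self, rng):
        nu = rng.lognormal(np.log(0.22), 0.3, 400)
        nu2 = rng.lognormal(np.log(0.22), 0.3, 400)
        groups = {"Narrow": nu * 30**0.75, "Wide": nu2 * 80**0.75}
        widths = {"Narrow": 30.0, "Wide": 80.0}
        p_right = mf.ks_match(groups, widths, 0.75)["p"]
        p_half = mf.ks_match(groups, widths, 0.5)["p"]
        p_one = mf.ks_match(groups, widths, 1.0)["p"]
        assert p_right > p_half and p_right > p_one


class TestBms:
    def test_symmetric_evidences(self):
        res = mf.bms_proportions(np.zeros((12, 2)))
        assert np.allclose(res.expected_frequencies, 0.5)

    def test_strong_unanimous_evidence(self):
        ev = np.column_stack([np.full(10, 20.0), np.zeros(10)])
        res = mf.bms_proportions(ev)
        assert res.expected_frequencies[0] > 0.9
        assert np.all(res.dirichlet >= 1.0)
        assert res.expected_frequencies.sum() == pytest.approx(1.0)

    def test_column_permutation_equivariance(self, rng):
        ev = rng.normal(0, 3, size=(15, 3))
        res = mf.bms_proportions(ev)
        perm = [2, 0, 1]
        res_p = mf.bms_proportions(ev[:, perm])
        assert np.allclose(res_p.expected_frequencies, res.expected_frequencies[perm], atol=1e-8)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            mf.bms_proportions(np.array([[0.0, np.inf]]))
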