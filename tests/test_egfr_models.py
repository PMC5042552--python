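"""MDRD eGFR, cross-sectional regressions, mixed models, LRT and impacts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allogenomics.egfr_models import (
    DEFAULT_EFFECTIVE_RANGES,
    ClinicalRecord,
    compare_models,
    egfr_mdrd,
    fit_cross_sectional,
    fit_longitudinal,
    impact_report,
    load_clinical,
)
from allogenomics.synthetic_cohort import SimulationParams, simulate_truth


class TestMdrd:
    def test_closed_form_value(self):
        # 175 * 1.0^-1.154 * 50^-0.203 for a non-black male
        assert egfr_mdrd(1.0, 50, female=False, black=False) == pytest.approx(
            79.09465531827084, rel=1e-12
        )

    def test_power_law_scaling_in_creatinine(self):
        base = egfr_mdrd(1.0, 50, False, False)
        assert egfr_mdrd(2.0, 50, False, False) == pytest.approx(base * 2 ** -1.154)

    def test_sex_and_race_factors_exact(self):
        base = egfr_mdrd(1.3, 40, False, False)
        assert egfr_mdrd(1.3, 40, True, False) == pytest.approx(base * 0.742)
        assert egfr_mdrd(1.3, 40, False, True) == pytest.approx(base * 1.212)
        assert egfr_mdrd(1.3, 40, True, True) == pytest.approx(base * 0.742 * 1.212)

    def test_strictly_decreasing_in_scr_and_age(self):
        scrs = np.linspace(0.5, 5, 30)
        vals = [egfr_mdrd(s, 50, False, False) for s in scrs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        ages = np.linspace(18, 90, 30)
        vals = [egfr_mdrd(1.2, a, True, False) for a in ages]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("scr,age", [(0, 50), (-1, 50), (1, 0)])
    def test_domain_errors(self, scr, age):
        with pytest.raises(ValueError):
            egfr_mdrd(scr, age, False, False)


class TestClinicalRecords:
    def test_record_validation(self):
        with pytest.raises(ValueError, match="months"):
            ClinicalRecord("p", -1, 40, egfr=50)
        with pytest.raises(ValueError, match="HLA"):
            ClinicalRecord("p", 1, 40, hla_abdr_mismatches=7, egfr=50)
        with pytest.raises(ValueError, match="at least one"):
            ClinicalRecord("p", 1, 40)

    def test_load_computes_egfr_only_when_absent(self, tmp_path):
        path = tmp_path / "clin.csv"
        path.write_text(
            "pair_id,months,donor_age,serum_creatinine,recipient_age,recipient_sex,recipient_race,egfr\n"
            "p1,12,40,1.0,50,male,non-black,\n"
            "p2,12,45,2.0,50,male,non-black,99.0\n"
        )
        df = load_clinical(path)
        assert df.loc[df.pair_id == "p1", "egfr"].iloc[0] == pytest.approx(
            egfr_mdrd(1.0, 50, False, False)
        )
        # provided eGFR is never overwritten
        assert df.loc[df.pair_id == "p2", "egfr"].iloc[0] == 99.0


class TestCrossSectional:
    def _clin(self, pair_ids, month, y):
        return pd.DataFrame(
            {"pair_id": pair_ids, "months": month, "donor_age": 40.0, "egfr": y}
        )

    def test_noiseless_line(self):
        scores = {f"p{i}": float(i) for i in range(10)}
        y = [2.0 * scores[f"p{i}"] for i in range(10)]
        fit = fit_cross_sectional(scores, self._clin(list(scores), 36, y), 36)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.n == 10

    def test_constant_score_is_singular(self):
        scores = {f"p{i}": 5.0 for i in range(5)}
        with pytest.raises(np.linalg.LinAlgError):
            fit_cross_sectional(scores, self._clin(list(scores), 12, range(5)), 12)

    def test_too_few_pairs(self):
        scores = {"p0": 1.0, "p1": 2.0}
        with pytest.raises(ValueError, match=">=3"):
            fit_cross_sectional(scores, self._clin(list(scores), 12, [1, 2]), 12)

    def test_permutation_null_p_values_uniform(self):
        """With AMS permuted against the outcome the p-value is uniform on
        (0,1): a KS test over 1000 permutations must not reject at 0.01."""
        rng = np.random.default_rng(0)
        n = 100
        x = rng.normal(1000, 200, n)
        y = rng.normal(55, 12, n)
        pair_ids = [f"p{i}" for i in range(n)]
        clin = self._clin(pair_ids, 12, y)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(x)
            scores = dict(zip(pair_ids, perm))
            pvals.append(fit_cross_sectional(scores, clin, 12).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_negative_effect_detected_in_discovery_like_cohort(self):
        """A 10-pair cohort with a strong negative AMS->eGFR effect at a late
        timepoint yields a negative fitted slope."""
        params = SimulationParams(
            n_pairs=10, n_sites=2000, beta_ams=-0.05, sigma_pair=4, sigma_resid=4, seed=21
        )
        truth = simulate_truth(params)
        scores = dict(zip(truth.pair_ids, truth.ams_distinct.astype(float)))
        fit = fit_cross_sectional(scores, truth.clinical, 36)
        assert fit.slope < 0 and fit.n == 10


def _cohort_fit(seed=1, include_hla=False, reml=False, include_ams=True, **kw):
    params = SimulationParams(n_pairs=20, n_sites=2000, seed=seed, **kw)
    truth = simulate_truth(params)
    scores = dict(zip(truth.pair_ids, truth.ams_distinct.astype(float)))
    return truth, scores, fit_longitudinal(
        truth.clinical, scores, include_hla=include_hla, reml=reml, include_ams=include_ams
    )


class TestLongitudinal:
    def test_noiseless_identifiability(self):
        """With both noise terms at zero the full model reproduces the
        generating coefficients (to solver tolerance and the 1e-4 rounding
        of the clinical table)."""
        truth, scores, fit = _cohort_fit(seed=5, include_hla=True,
                                         sigma_pair=0.0, sigma_resid=0.0)
        p = truth.params
        assert fit.coefficients["intercept"].estimate == pytest.approx(p.intercept, abs=1e-3)
        assert fit.coefficients["donor_age"].estimate == pytest.approx(p.beta_age, abs=1e-3)
        assert fit.coefficients["ams"].estimate == pytest.approx(p.beta_ams, abs=1e-4)
        assert fit.coefficients["months"].estimate == pytest.approx(p.beta_t, abs=1e-3)
        assert fit.coefficients["hla"].estimate == pytest.approx(p.beta_hla, abs=1e-3)

    def test_single_observation_per_pair_warns(self):
        truth, scores, _ = _cohort_fit(seed=6)
        one_obs = truth.clinical.groupby("pair_id").head(1)
        with pytest.warns(UserWarning, match="confounded"):
            fit_longitudinal(one_obs, scores)

    def test_too_few_pairs_rejected(self):
        truth, scores, _ = _cohort_fit(seed=7)
        clin = truth.clinical[truth.clinical.pair_id == "pair000"]
        with pytest.raises(ValueError, match=">=2"):
            fit_longitudinal(clin, scores)

    def test_unmatched_pair_ids_listed(self):
        truth, scores, _ = _cohort_fit(seed=8)
        scores.pop("pair003")
        with pytest.raises(ValueError, match="pair003"):
            fit_longitudinal(truth.clinical, scores)

    def test_wald_ci_brackets_estimate_and_reml_flagged(self):
        _, _, fit = _cohort_fit(seed=9, reml=True)
        assert fit.method == "REML"
        for c in fit.coefficients.values():
            assert c.ci_low <= c.estimate <= c.ci_high
            assert c.ci_low == pytest.approx(c.estimate - 1.96 * c.se, rel=1e-3)

    def test_zero_ams_effect_ci_covers_zero_in_most_replicates(self):
        """Generating with no AMS effect, the 95% Wald CI for the AMS
        coefficient covers zero in >=90% of 100 replicate cohorts."""
        covered = 0
        for seed in range(100):
            params = SimulationParams(n_pairs=20, n_sites=2000, beta_ams=0.0, seed=seed)
            truth = simulate_truth(params)
            scores = dict(zip(truth.pair_ids, truth.ams_distinct.astype(float)))
            fit = fit_longitudinal(truth.clinical, scores)
            c = fit.coefficients["ams"]
            covered += c.ci_low <= 0.0 <= c.ci_high
        assert covered >= 90


class TestModelComparison:
    def test_identical_models_short_circuit(self):
        _, _, fit = _cohort_fit(seed=10)
        cmp = compare_models(fit, fit)
        assert cmp.chi2 == 0.0 and cmp.p_value == 1.0 and cmp.df == 0

    def test_reml_fits_rejected(self):
        _, _, ml = _cohort_fit(seed=11)
        _, _, reml = _cohort_fit(seed=11, reml=True)
        with pytest.raises(ValueError, match="ML"):
            compare_models(reml, ml)

    def test_non_nested_rejected(self):
        _, _, eq3 = _cohort_fit(seed=12)  # donor_age + ams + months
        _, _, other = _cohort_fit(seed=12, include_hla=True, include_ams=False)
        with pytest.raises(ValueError, match="not nested"):
            compare_models(eq3, other)

    def test_lrt_chi2_from_loglik_difference(self):
        truth, scores, full = _cohort_fit(seed=13, include_hla=True)
        reduced = fit_longitudinal(truth.clinical, scores, include_hla=False)
        cmp = compare_models(full, reduced)
        assert cmp.df == 1
        assert cmp.chi2 == pytest.approx(max(0.0, 2 * (full.loglik - reduced.loglik)))
        assert cmp.p_value == pytest.approx(stats.chi2.sf(cmp.chi2, 1))

    def test_lrt_invariant_to_affine_rescaling_of_ams(self):
        truth, scores, full = _cohort_fit(seed=14)
        reduced = fit_longitudinal(truth.clinical, scores, include_ams=False)
        chi2_raw = compare_models(full, reduced).chi2
        scaled = {k: v / 1000.0 for k, v in scores.items()}
        full_s = fit_longitudinal(truth.clinical, scaled)
        reduced_s = fit_longitudinal(truth.clinical, scaled, include_ams=False)
        chi2_scaled = compare_models(full_s, reduced_s).chi2
        assert chi2_scaled == pytest.approx(chi2_raw, abs=1e-3)

    def test_uninformative_covariate_null_distribution(self):
        """Adding a covariate with no true effect gives an LRT statistic
        with mean ~1 (chi-squared, 1 df) over null replicates."""
        chi2s = []
        for seed in range(40):
            params = SimulationParams(n_pairs=20, n_sites=2000, beta_hla=0.0, seed=seed)
            truth = simulate_truth(params)
            scores = dict(zip(truth.pair_ids, truth.ams_distinct.astype(float)))
            full = fit_longitudinal(truth.clinical, scores, include_hla=True)
            reduced = fit_longitudinal(truth.clinical, scores, include_hla=False)
            chi2s.append(compare_models(full, reduced).chi2)
        assert 0.4 < np.mean(chi2s) < 1.8


class TestImpactReport:
    def _fit(self):
        _, _, fit = _cohort_fit(seed=15, include_hla=True)
        return fit

    def test_impact_arithmetic(self):
        from allogenomics.egfr_models import Coefficient, ModelFit
        fit = ModelFit(
            coefficients={
                "intercept": Coefficient(100, 1, 98, 102),
                "donor_age": Coefficient(-0.47, 0.1, -0.78, -0.15),
                "ams": Coefficient(-0.011, 0.005, -0.022, -0.00063),
            },
            random_intercept_sd=10, residual_sd=8, loglik=-500, method="ML",
            n_obs=100, n_pairs=20,
        )
        rep = impact_report(fit, {"donor_age": 60, "ams": 1700})
        age = rep.rows.loc["donor_age"]
        assert age["Impact"] == pytest.approx(-0.47 * 60)  # -28.2
        ams = rep.rows.loc["ams"]
        assert ams["Impact 2.50%"] == pytest.approx(-0.022 * 1700)  # -37.4
        assert ams["Impact 97.50%"] == pytest.approx(-0.00063 * 1700)  # -1.071

    def test_zero_estimate_zero_impact(self):
        from allogenomics.egfr_models import Coefficient, ModelFit
        fit = ModelFit(
            coefficients={"ams": Coefficient(0.0, 1.0, -1.0, 1.0)},
            random_intercept_sd=1, residual_sd=1, loglik=0, method="ML",
            n_obs=10, n_pairs=5,
        )
        assert impact_report(fit, {"ams": 1700}).rows.loc["ams", "Impact"] == 0.0

    def test_missing_range_is_a_configuration_error(self):
        fit = self._fit()
        with pytest.raises(ValueError, match="effective range"):
            impact_report(fit, {"donor_age": 60})

    def test_default_ranges_cover_default_model(self):
        fit = self._fit()
        rep = impact_report(fit)
        assert set(rep.rows.index) == {"donor_age", "ams", "months", "hla"}
        assert (rep.rows["Effective Range"] > 0).all()
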