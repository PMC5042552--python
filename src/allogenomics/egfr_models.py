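"""Kidney-function models: MDRD eGFR, per-timepoint regressions, and
longitudinal linear mixed models relating eGFR to the AMS.

The longitudinal model regresses eGFR on donor age at transplant, the
pair's AMS and months post-transplantation, with a random intercept per
transplant pair capturing baseline graft-function differences and the
correlation of repeated measurements:

    eGFR ~ donor_age + AMS + T + (1 | pair)

An extended model adds the clinical HLA-A/B/DR mismatch count (0-6) as a
fixed effect. Nested models are compared by likelihood ratio after
maximum-likelihood (not REML) fits. Fixed-effect confidence intervals are
Wald intervals. Coefficients are converted to expected impacts on eGFR by
multiplying by each predictor's effective range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "Coefficient",
    "ModelFit",
    "ModelComparison",
    "CrossSectionalFit",
    "ImpactReport",
    "DEFAULT_EFFECTIVE_RANGES",
    "egfr_mdrd",
    "load_clinical",
    "fit_cross_sectional",
    "fit_longitudinal",
    "compare_models",
    "impact_report",
]

# Effective ranges used to convert coefficients into expected eGFR impacts:
# months post-transplant, years of donor age, AMS units, HLA mismatches.
DEFAULT_EFFECTIVE_RANGES: dict[str, float] = {
    "months": 480.0,
    "donor_age": 60.0,
    "ams": 1700.0,
    "hla": 6.0,
}


@dataclass(frozen=True)
class ClinicalRecord:
    """One longitudinal observation of a transplant pair."""

    pair_id: str
    months: float
    donor_age: float
    hla_abdr_mismatches: Optional[int] = None
    recipient_sex: Optional[str] = None  # "male" | "female"
    recipient_race: Optional[str] = None  # "black" | "non-black"
    recipient_age: Optional[float] = None
    serum_creatinine: Optional[float] = None  # mg/dL
    egfr: Optional[float] = None  # mL/min/1.73m^2

    def __post_init__(self) -> None:
        if self.months < 0:
            raise ValueError(f"months post-transplant must be >= 0, got {self.months}")
        if self.hla_abdr_mismatches is not None and not 0 <= self.hla_abdr_mismatches <= 6:
            raise ValueError(
                f"HLA-ABDR mismatch count must be in 0..6, got {self.hla_abdr_mismatches}"
            )
        if self.serum_creatinine is None and self.egfr is None:
            raise ValueError("at least one of serum_creatinine and egfr is required")


def egfr_mdrd(scr: float, age: float, female: bool, black: bool) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the 4-variable MDRD study
    equation (IDMS-traceable): 175 x Scr^-1.154 x age^-0.203,
    x 0.742 if female, x 1.212 if black. Scr in mg/dL, age in years.
    """
    if scr <= 0 or age <= 0:
        raise ValueError(f"serum creatinine and age must be positive, got scr={scr}, age={age}")
    egfr = 175.0 * scr ** -1.154 * age ** -0.203
    if female:
        egfr *= 0.742
    if black:
        egfr *= 1.212
    return egfr


def load_clinical(path: Union[str, Path]) -> pd.DataFrame:
    """Load a clinical CSV into a validated observation table.

    Required columns: pair_id, months, donor_age, and at least one of
    egfr / serum_creatinine. When egfr is absent for a row it is computed
    from serum creatinine by MDRD, which additionally requires
    recipient_age, recipient_sex and recipient_race; a provided eGFR is
    never overwritten.
    """
    df = pd.read_csv(path, comment="#")
    required = {"pair_id", "months", "donor_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks column(s): {sorted(missing)}")
    if "egfr" not in df.columns and "serum_creatinine" not in df.columns:
        raise ValueError(f"clinical table {path} needs an egfr or serum_creatinine column")
    if "egfr" not in df.columns:
        df["egfr"] = np.nan
    needs = df["egfr"].isna()
    if needs.any():
        for col in ("serum_creatinine", "recipient_age", "recipient_sex", "recipient_race"):
            if col not in df.columns or df.loc[needs, col].isna().any():
                raise ValueError(
                    f"rows without egfr need {col!r} to compute MDRD eGFR from creatinine"
                )
        df.loc[needs, "egfr"] = [
            egfr_mdrd(
                row.serum_creatinine,
                row.recipient_age,
                str(row.recipient_sex).lower() == "female",
                str(row.recipient_race).lower() == "black",
            )
            for row in df.loc[needs].itertuples()
        ]
    if (df["months"] < 0).any():
        raise ValueError("months post-transplant must be >= 0")
    if "hla_abdr_mismatches" in df.columns:
        hla = df["hla_abdr_mismatches"].dropna()
        if ((hla < 0) | (hla > 6)).any():
            raise ValueError("HLA-ABDR mismatch counts must be in 0..6")
    return df


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        # NaN bounds occur for degenerate (singular) fits and are let through
        if math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("confidence interval must bracket the estimate")


@dataclass
class ModelFit:
    """A fitted longitudinal mixed model."""

    coefficients: dict[str, Coefficient]
    random_intercept_sd: float
    residual_sd: float
    loglik: float
    method: str  # "ML" | "REML"
    n_obs: int
    n_pairs: int
    converged: bool = True
    formula: str = ""

    @property
    def fixed_effect_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of two nested ML fits.

    ``df == 0`` only for the degenerate self-comparison, which is
    short-circuited to chi2 = 0, p = 1.
    """

    chi2: float
    df: int
    p_value: float
    full_name: str
    reduced_name: str


@dataclass(frozen=True)
class CrossSectionalFit:
    """Simple OLS of an outcome on AMS at a fixed timepoint."""

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n: int


@dataclass
class ImpactReport:
    """Per-predictor expected impact on eGFR over its effective range."""

    rows: pd.DataFrame  # Estimate, 2.50%, 97.50%, Effective Range, Impact, Impact 2.50%, Impact 97.50%


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge."""


def fit_cross_sectional(
    scores: Mapping[str, float],
    clinical: pd.DataFrame,
    month: float,
    outcome: str = "egfr",
) -> CrossSectionalFit:
    """Ordinary least squares of an outcome (egfr or serum_creatinine) on
    AMS across pairs observed at one timepoint."""
    obs = clinical[clinical["months"] == month]
    obs = obs[obs["pair_id"].isin(scores)]
    if outcome not in obs.columns:
        raise ValueError(f"outcome column {outcome!r} not in clinical table")
    obs = obs.dropna(subset=[outcome])
    if len(obs) < 3:
        raise ValueError(
            f"need >=3 pairs with {outcome} at month {month}, found {len(obs)}"
        )
    x = np.array([scores[p] for p in obs["pair_id"]], dtype=float)
    y = obs[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("AMS is constant across pairs; regression is singular")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return CrossSectionalFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        p_value=float(res.pvalues[1]),
        n=len(obs),
    )


def _merged_table(
    records: pd.DataFrame, scores: Mapping[str, float], include_hla: bool
) -> pd.DataFrame:
    df = records.copy()
    missing = sorted(set(df["pair_id"].astype(str)) - {str(k) for k in scores})
    if missing:
        raise ValueError(f"no AMS score for pair id(s): {missing}")
    df["ams"] = df["pair_id"].map(lambda p: float(scores[p]))
    cols = ["pair_id", "egfr", "donor_age", "ams", "months"]
    if include_hla:
        if "hla_abdr_mismatches" not in df.columns or df["hla_abdr_mismatches"].isna().any():
            raise ValueError("HLA mismatch counts required but missing from clinical table")
        df["hla"] = df["hla_abdr_mismatches"].astype(float)
        cols.append("hla")
    return df[cols].dropna()


def fit_longitudinal(
    records: pd.DataFrame,
    scores: Mapping[str, float],
    include_hla: bool = False,
    reml: bool = False,
    include_ams: bool = True,
) -> ModelFit:
    """Fit the random-intercept mixed model of eGFR on donor age, AMS and
    months post-transplant (plus HLA mismatches when ``include_hla``).

    ``include_ams=False`` fits the nested model without the score, for
    likelihood-ratio testing of the AMS effect. ML (``reml=False``) is
    required for model comparison; REML is available for reporting
    single-model estimates.
    """
    df = _merged_table(records, scores, include_hla)
    n_pairs = df["pair_id"].nunique()
    if n_pairs < 2:
        raise ValueError(f"need >=2 transplant pairs, found {n_pairs}")
    terms = ["donor_age"] + (["ams"] if include_ams else []) + ["months"]
    if include_hla:
        terms.append("hla")
    formula = "egfr ~ " + " + ".join(terms)
    obs_per_pair = df.groupby("pair_id").size()
    if (obs_per_pair < 2).all():
        # With one observation per pair the likelihood is flat along the
        # sigma_pair^2 + sigma_resid^2 ridge; attribute all variance to the
        # residual (the OLS solution) and say so.
        warnings.warn(
            "every pair has a single observation: the random-intercept variance "
            "is confounded with the residual variance (set to 0)",
            UserWarning,
            stacklevel=2,
        )
        return _fit_degenerate_ols(df, formula, terms, reml, n_pairs)
    model = MixedLM.from_formula(formula, groups="pair_id", data=df)
    res = None
    last_err: Optional[Exception] = None
    # lbfgs is fastest but its profiled Hessian can be singular on small
    # cohorts; fall back to slower optimizers before giving up.
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # scale/boundary chatter
                candidate = model.fit(reml=reml, method=method)
            if candidate.converged:
                res = candidate
                break
        except np.linalg.LinAlgError as exc:
            last_err = exc
    if res is None:
        raise ConvergenceError(
            f"mixed model did not converge: {formula}"
            + (f" ({last_err})" if last_err else "")
        )
    re_var = float(res.cov_re.iloc[0, 0])
    if re_var <= 1e-10:
        warnings.warn(
            f"singular fit: random-intercept variance is ~0 in {formula}",
            UserWarning,
            stacklevel=2,
        )
    coefs: dict[str, Coefficient] = {}
    ci = res.conf_int(alpha=0.05)
    for name in res.fe_params.index:
        est = float(res.fe_params[name])
        se = float(res.bse_fe[name])
        coefs[_canonical_name(name)] = Coefficient(
            estimate=est, se=se, ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1])
        )
    loglik = float(res.llf)
    if not math.isfinite(loglik):
        raise ConvergenceError(f"non-finite log-likelihood for {formula}")
    return ModelFit(
        coefficients=coefs,
        random_intercept_sd=math.sqrt(max(re_var, 0.0)),
        residual_sd=math.sqrt(float(res.scale)),
        loglik=loglik,
        method="REML" if reml else "ML",
        n_obs=len(df),
        n_pairs=n_pairs,
        converged=bool(res.converged),
        formula=formula,
    )


def _canonical_name(name: str) -> str:
    return "intercept" if name == "Intercept" else name


def _fit_degenerate_ols(df: pd.DataFrame, formula: str, terms: list, reml: bool,
                        n_pairs: int) -> ModelFit:
    import statsmodels.formula.api as smf

    res = smf.ols(formula, data=df).fit()
    ci = res.conf_int(alpha=0.05)
    coefs = {
        _canonical_name(name): Coefficient(
            estimate=float(res.params[name]), se=float(res.bse[name]),
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1]),
        )
        for name in res.params.index
    }
    return ModelFit(
        coefficients=coefs,
        random_intercept_sd=0.0,
        residual_sd=math.sqrt(float(res.scale)),
        loglik=float(res.llf),
        method="REML" if reml else "ML",
        n_obs=len(df),
        n_pairs=n_pairs,
        converged=True,
        formula=formula,
    )


def compare_models(full: ModelFit, reduced: ModelFit) -> ModelComparison:
    """Likelihood-ratio test of nested mixed models fitted by ML.

    chi2 = 2 (logLik_full - logLik_reduced), df = difference in fixed-effect
    count, p from the chi-squared upper tail. Comparing a model with itself
    (identical fixed effects) short-circuits to chi2 = 0, p = 1.
    """
    for fit, role in ((full, "full"), (reduced, "reduced")):
        if fit.method != "ML":
            raise ValueError(f"{role} model must be fitted by ML (REML fits are not comparable)")
    full_fx = set(full.fixed_effect_names)
    red_fx = set(reduced.fixed_effect_names)
    if full_fx == red_fx:
        return ModelComparison(
            chi2=0.0, df=0, p_value=1.0, full_name=full.formula, reduced_name=reduced.formula
        )
    if not red_fx < full_fx:
        raise ValueError(
            f"models are not nested: reduced has terms {sorted(red_fx - full_fx)} "
            "absent from the full model"
        )
    df = len(full_fx) - len(red_fx)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df))
    return ModelComparison(
        chi2=chi2, df=df, p_value=p, full_name=full.formula, reduced_name=reduced.formula
    )


def impact_report(
    fit: ModelFit,
    ranges: Optional[Mapping[str, float]] = None,
) -> ImpactReport:
    """Expected impact of each predictor on eGFR when varied over its
    effective range: impact = estimate x range, with the Wald CI endpoints
    scaled the same way."""
    if ranges is None:
        ranges = DEFAULT_EFFECTIVE_RANGES
    rows = []
    for name, coef in fit.coefficients.items():
        if name == "intercept":
            continue
        r = ranges.get(name)
        if r is None:
            raise ValueError(f"no effective range configured for predictor {name!r}")
        if r <= 0:
            raise ValueError(f"effective range for {name!r} must be positive, got {r}")
        rows.append(
            {
                "predictor": name,
                "Estimate": coef.estimate,
                "2.50%": coef.ci_low,
                "97.50%": coef.ci_high,
                "Effective Range": r,
                "Impact": coef.estimate * r,
                "Impact 2.50%": coef.ci_low * r,
                "Impact 97.50%": coef.ci_high * r,
            }
        )
    return ImpactReport(rows=pd.DataFrame(rows).set_index("predictor"))
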