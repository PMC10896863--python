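"""Association models for adherence, discontinuation, and time to discontinuation.

Three regression models relate beneficiary covariates to the outcome
measures:

* multinomial (baseline-category) logit on the three-level adherence
  category, with optimal adherence (PDC >= 0.95) as the reference outcome;
* binary logit on discontinuation (continuous gap >= 90 days);
* Cox proportional hazards on time to discontinuation, with
  administrative censoring at the end of follow-up (day 365) for
  non-discontinuers and Efron handling of ties.

Model fitting itself is routine maximum likelihood delegated to
statsmodels and lifelines; what this module pins down is the analysis
table assembly, the categorical encodings and reference levels, the
censoring convention, and Wald confidence intervals / p-values — reported
as odds or hazard ratios, never for reference levels.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import AnalysisConfig, ClaimsBundle
from .outcomes import CATEGORIES, CATEGORY_OPTIMAL

AGE_BANDS = ["<=34", "35-44", "45-54", "55-64", "65-74", "75-84", ">=85"]


class ModelFitError(Exception):
    """Structured fitting failure (degenerate outcome, separation, no events)."""

    def __init__(self, model: str, reason: str, term: str | None = None):
        self.model = model
        self.reason = reason
        self.term = term
        msg = f"{model}: {reason}" + (f" (term: {term})" if term else "")
        super().__init__(msg)


@dataclasses.dataclass
class ModelSpec:
    """Which outcome to model and how to encode the covariates.

    ``categorical`` maps covariate name to its reference level;
    ``numeric`` covariates enter as-is.  Categorical levels (or numeric 0/1
    flags) observed fewer than ``min_level_count`` times are merged into
    the reference (dropped), a standard guard against quasi-separation in
    sparse claims strata; 0 disables the guard.
    """

    outcome: str  # adherence_category | discontinuation | time_to_discontinuation
    categorical: dict[str, str]
    numeric: list[str]
    min_level_count: int = 0


def default_model_spec(outcome: str, comorbidities: Iterable[str] = (),
                       min_level_count: int = 0) -> ModelSpec:
    """The study's covariate list with its published reference levels."""
    return ModelSpec(
        outcome=outcome,
        categorical={
            "age_group": "65-74", "sex": "male", "race_ethnicity": "White",
            "lis_status": "none", "eligibility_reason": "age",
            "census_region": "Northeast", "metro": "urban", "plan_type": "other",
            "index_year": "2014", "anchor_str": "PI",
        },
        numeric=["hcc_score", *(f"cm_{c}" for c in comorbidities), "rx_per_month_pre"],
        min_level_count=min_level_count,
    )


def age_group(age_years: float) -> str:
    """Age band at the index date (64.9 years falls in 55-64)."""
    age = int(age_years)
    if age <= 34:
        return "<=34"
    if age >= 85:
        return ">=85"
    for band in AGE_BANDS[1:-1]:
        lo, hi = band.split("-")
        if int(lo) <= age <= int(hi):
            return band
    raise ValueError(f"age {age_years} outside supported range")


def assemble_analysis_table(cohort: pd.DataFrame, outcomes: pd.DataFrame,
                            bundle: ClaimsBundle,
                            config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join covariates onto per-person outcomes (one row per cohort member).

    Returns the analysis table and a covariate-completeness report
    (non-missing counts per column).  Raises :class:`ModelFitError` if a
    cohort member has no outcome row.
    """
    missing = set(cohort["beneficiary_id"]) - set(outcomes["beneficiary_id"])
    if missing:
        raise ModelFitError("assemble", "cohort members missing outcome rows: "
                            + ", ".join(sorted(missing)[:10]))
    df = cohort.merge(outcomes, on="beneficiary_id", validate="one_to_one")
    bene = bundle.beneficiaries.set_index("beneficiary_id")
    cm_cols = bundle.comorbidity_columns()
    cols = ["birth_date", "sex", "race_ethnicity", "lis_status",
            "eligibility_reason", "census_region", "metro", "plan_type",
            "hcc_score", "rx_per_month_pre"] + cm_cols
    df = df.join(bene[cols], on="beneficiary_id")

    idx = pd.to_datetime(df["index_date"])
    age_years = (idx - pd.to_datetime(df["birth_date"])).dt.days / 365.25
    df["age_group"] = [age_group(a) for a in age_years]
    df["index_year"] = idx.dt.year.astype(str)
    # anchor class x tablet-regimen status; PIs form a single level
    df["anchor_str"] = np.where(df["anchor_class"] == "PI", "PI",
                                df["anchor_class"] + "_" + df["str_flag"])
    df["event_time"] = df["time_to_discontinuation"].where(
        df["discontinued"], config.followup_days).astype(float)

    report = pd.DataFrame({
        "column": df.columns,
        "n_nonmissing": [int(df[c].notna().sum()) for c in df.columns],
        "n_total": len(df),
    })
    return df, report


def build_design_matrix(table: pd.DataFrame, spec: ModelSpec
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-encoded design matrix; reference levels are never emitted.

    Returns the matrix and the list of terms dropped or merged by the
    sparse-level guard.
    """
    X = pd.DataFrame(index=table.index)
    dropped: list[str] = []
    for cov, ref in spec.categorical.items():
        values = table[cov].astype(str)
        levels = sorted(values.unique())
        if ref not in levels:
            raise ModelFitError(spec.outcome, f"reference level {ref!r} of {cov!r} "
                                "not observed", term=cov)
        for level in levels:
            if level == ref:
                continue
            col = values == level
            if spec.min_level_count and col.sum() < spec.min_level_count:
                dropped.append(f"{cov}={level}")
                continue
            X[f"{cov}={level}"] = col.astype(float)
    for cov in spec.numeric:
        x = pd.to_numeric(table[cov])
        uniq = x.dropna().unique()
        if (spec.min_level_count and set(uniq) <= {0, 1}
                and min((x == 1).sum(), (x == 0).sum()) < spec.min_level_count):
            dropped.append(cov)
            continue
        if len(uniq) <= 1:
            dropped.append(cov)
            continue
        X[cov] = x.astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ModelFitError(spec.outcome, f"missing covariate values in {bad}")
    return X, dropped


@dataclasses.dataclass(frozen=True)
class EffectEstimate:
    """One model term's odds or hazard ratio (a results-table row)."""

    model: str           # adherence_multinomial | discontinuation_logit | time_to_discontinuation_cox
    contrast: str        # e.g. "low_vs_optimal"; "" for single-equation models
    term: str
    measure: str         # "OR" or "HR"
    point: float
    ci_low: float
    ci_high: float
    chi_square: float
    p_value: float


def estimates_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates])


def _wald_rows(model: str, contrast: str, measure: str, terms: Sequence[str],
               params: np.ndarray, bse: np.ndarray) -> list[EffectEstimate]:
    z = params / bse
    rows = []
    from scipy import stats
    for term, b, se, zz in zip(terms, params, bse, z):
        rows.append(EffectEstimate(
            model=model, contrast=contrast, term=term, measure=measure,
            point=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.959963984540054 * se)),
            ci_high=float(np.exp(b + 1.959963984540054 * se)),
            chi_square=float(zz ** 2),
            p_value=float(2 * stats.norm.sf(abs(zz)))))
    return rows


def _check_converged(model: str, result) -> None:
    converged = getattr(result, "mle_retvals", {}).get("converged", True)
    if not converged:
        raise ModelFitError(model, "maximum-likelihood fit did not converge")
    params = np.asarray(result.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 15):
        terms = list(result.model.exog_names)
        worst = terms[int(np.nanargmax(np.abs(params).reshape(len(terms), -1).max(axis=1)))]
        raise ModelFitError(model, "quasi-separation (diverging coefficient)", term=worst)


def fit_adherence_multinomial(table: pd.DataFrame, spec: ModelSpec
                              ) -> list[EffectEstimate]:
    """Baseline-category logit on the 3-level adherence category.

    Optimal adherence is the reference outcome; one OR per non-reference
    covariate level per non-reference category (intermediate, low).
    """
    observed = [c for c in CATEGORIES if (table["category"] == c).any()]
    if len(observed) < 2:
        raise ModelFitError("adherence_multinomial",
                            f"only one outcome category observed ({observed})")
    if CATEGORY_OPTIMAL not in observed:
        raise ModelFitError("adherence_multinomial",
                            "reference category (optimal adherence) not observed")
    X, _ = build_design_matrix(table, spec)
    Xc = sm.add_constant(X, has_constant="add")
    codes = table["category"].map({c: i for i, c in enumerate(CATEGORIES)})
    try:
        result = sm.MNLogit(codes.to_numpy(), Xc).fit(disp=False, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise ModelFitError("adherence_multinomial", f"fit failed: {exc}") from exc
    _check_converged("adherence_multinomial", result)
    params = np.asarray(result.params, dtype=float)  # (k_exog, n_cat-1)
    bse = np.asarray(result.bse, dtype=float)
    non_ref = [c for c in CATEGORIES if c != CATEGORY_OPTIMAL and c in observed]
    rows: list[EffectEstimate] = []
    terms = list(Xc.columns)
    for j, cat in enumerate(non_ref):
        keep = [i for i, t in enumerate(terms) if t != "const"]
        rows += _wald_rows("adherence_multinomial", f"{cat}_vs_{CATEGORY_OPTIMAL}",
                           "OR", [terms[i] for i in keep],
                           params[keep, j], bse[keep, j])
    return rows


def fit_discontinuation_logit(table: pd.DataFrame, spec: ModelSpec
                              ) -> list[EffectEstimate]:
    """Binary logit on discontinuation (>= 90-day continuous gap)."""
    y = table["discontinued"].astype(int)
    if y.nunique() < 2:
        raise ModelFitError("discontinuation_logit",
                            "outcome is constant (all "
                            + ("discontinued" if y.iloc[0] else "persistent") + ")")
    X, _ = build_design_matrix(table, spec)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        result = sm.Logit(y.to_numpy(), Xc).fit(disp=False, maxiter=200)
    except Exception as exc:
        raise ModelFitError("discontinuation_logit", f"fit failed: {exc}") from exc
    _check_converged("discontinuation_logit", result)
    terms = list(Xc.columns)
    keep = [i for i, t in enumerate(terms) if t != "const"]
    params = np.asarray(result.params, dtype=float)
    bse = np.asarray(result.bse, dtype=float)
    return _wald_rows("discontinuation_logit", "", "OR",
                      [terms[i] for i in keep], params[keep], bse[keep])


def fit_time_to_discontinuation_cox(table: pd.DataFrame, spec: ModelSpec
                                    ) -> list[EffectEstimate]:
    """Cox proportional hazards on time to discontinuation.

    Events are discontinuations at their gap-start time; everyone else is
    administratively censored at the end of follow-up.  Ties are handled
    with Efron's method (lifelines' default).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    events = table["discontinued"].astype(bool)
    if not events.any():
        raise ModelFitError("time_to_discontinuation_cox", "no events (all censored)")
    X, _ = build_design_matrix(table, spec)
    df = X.copy()
    df["event_time"] = table["event_time"].astype(float)
    df["event"] = events.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="event_time", event_col="event")
    except ConvergenceError as exc:
        raise ModelFitError("time_to_discontinuation_cox",
                            f"fit failed to converge: {exc}") from exc
    summary = cph.summary
    return _wald_rows("time_to_discontinuation_cox", "", "HR",
                      list(summary.index),
                      summary["coef"].to_numpy(), summary["se(coef)"].to_numpy())


def fit_all(table: pd.DataFrame, comorbidities: Iterable[str],
            min_level_count: int = 0) -> dict[str, list[EffectEstimate]]:
    """Fit the three study models with the default covariate list."""
    cms = list(comorbidities)
    return {
        "adherence_multinomial": fit_adherence_multinomial(
            table, default_model_spec("adherence_category", cms, min_level_count)),
        "discontinuation_logit": fit_discontinuation_logit(
            table, default_model_spec("discontinuation", cms, min_level_count)),
        "time_to_discontinuation_cox": fit_time_to_discontinuation_cox(
            table, default_model_spec("time_to_discontinuation", cms, min_level_count)),
    }
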