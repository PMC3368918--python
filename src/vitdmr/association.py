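"""Observational association layer: contingency-table and logistic models.

Implements the conventional epidemiological analyses of the study design:
crude and covariate-adjusted odds ratios for 25-OHD (continuous, binary
deficiency, quintiles), genotype-phenotype and genotype-outcome tables,
stratified analyses, trend tests across quintiles and the genotype x
phenotype interaction likelihood-ratio test.  Model fitting is delegated to
statsmodels GLM; this module owns design construction and reporting shape.

Adjustment sets follow the study's convention:

* crude    — exposure only
* model I  — age and sex
* model II — model I plus deprivation index, energy intake, smoking, BMI,
             regular NSAID use, family history of cancer and physical
             activity (complete-case)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._glm import SeparationError
from .datatypes import ORResult

Z975 = stats.norm.ppf(0.975)

#: Covariates per adjustment model; categorical ones expand to indicator sets.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "crude": (),
    "modelI": ("age", "sex"),
    "modelII": (
        "age", "sex", "deprivation", "energy", "smoking", "bmi",
        "nsaid", "family_history", "activity",
    ),
}
#: Multi-level covariates entered as indicator (dummy) sets.
CATEGORICAL_COVARIATES = ("smoking", "activity")


def build_design(cohort: pd.DataFrame, terms: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Design matrix with intercept; categorical terms expand to indicators.

    Rows with any missing term are dropped (complete-case analysis); the
    caller aligns the outcome on the returned index.
    """
    cols = {"const": pd.Series(1.0, index=cohort.index)}
    for t in terms:
        v = cohort[t]
        if t in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(v, prefix=t, drop_first=True, dtype=float)
            # get_dummies drops rows with NaN silently into all-zero rows; mask them
            d[v.isna()] = np.nan
            for c in d.columns:
                cols[c] = d[c]
        else:
            cols[t] = v.astype(float)
    X = pd.DataFrame(cols)
    return X.dropna()


def contingency_or(table, model_label: str = "crude") -> ORResult:
    """Cross-product odds ratio for a 2x2 case-control table.

    ``table`` is ((cases_exposed, controls_exposed),
    (cases_reference, controls_reference)); the estimate is
    (cases_exp * controls_ref) / (controls_exp * cases_ref) with a Woolf
    log-scale standard error for the 95% CI and two-sided p.  A zero cell
    triggers the Haldane-Anscombe 0.5 correction, recorded in the result.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    cells = np.array([a, b, c, d])
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("table has a zero margin; odds ratio undefined")
    note = ""
    if np.any(cells == 0):
        cells = cells + 0.5
        note = "haldane-anscombe 0.5 correction (zero cell)"
        a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * Z975 * se)
    p = 2 * stats.norm.sf(abs(np.log(or_)) / se)
    return ORResult(float(or_), float(lo), float(hi), float(p),
                    n_cases=int(round(a + c)), n_controls=int(round(b + d)),
                    model_label=model_label, note=note)


def fit_logistic(outcome, design, freq_weights=None):
    """Maximum-likelihood logistic regression with Wald inference.

    ``outcome`` is a 0/1 vector, or an (events, non-events) two-column array
    for grouped data; ``design`` must include its own intercept column.
    Returns the statsmodels GLM results object, augmented with a
    ``coef_table`` DataFrame (coef, se, OR, CI, p).  Quasi-complete
    separation (diverging coefficients or non-convergence) raises
    :class:`~vitdmr._glm.SeparationError`: the effect is non-estimable.
    """
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(np.asarray(outcome, dtype=float), X,
                   family=sm.families.Binomial(), freq_weights=freq_weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns en route to divergence
        res = model.fit(maxiter=100)
    if (not res.converged) or np.max(np.abs(res.params)) > 15.0:
        raise SeparationError("logistic fit diverged; effect non-estimable")
    names = list(design.columns) if hasattr(design, "columns") else [
        f"x{i}" for i in range(X.shape[1])]
    ci = res.conf_int()
    res.coef_table = pd.DataFrame({
        "coef": res.params, "se": res.bse,
        "or": np.exp(res.params),
        "ci_low": np.exp(ci[:, 0]), "ci_high": np.exp(ci[:, 1]),
        "p": res.pvalues,
    }, index=names)
    return res


def logistic_or(cohort: pd.DataFrame, exposure: str, outcome: str = "y",
                model_label: str = "crude") -> ORResult:
    """Odds ratio for one exposure column under a named adjustment model."""
    if model_label not in MODEL_COVARIATES:
        raise KeyError(f"unknown model {model_label!r}")
    X = build_design(cohort, (exposure, *MODEL_COVARIATES[model_label]))
    y = cohort.loc[X.index, outcome].astype(float)
    res = fit_logistic(y, X)
    row = res.coef_table.loc[exposure]
    n_cases = int((y == 1).sum())
    return ORResult(float(row["or"]), float(row["ci_low"]), float(row["ci_high"]),
                    float(row["p"]), n_cases=n_cases, n_controls=int(len(y) - n_cases),
                    model_label=model_label)


def per_allele_or(deficient_counts, sufficient_counts) -> ORResult:
    """Per-allele OR of deficiency from grouped genotype counts (doses 0/1/2).

    Fits a maximum-likelihood logistic regression of deficiency status on
    allele dose using the grouped (events, non-events) representation and
    exponentiates the slope — the 'per allele' rows of the genotype-phenotype
    tables.
    """
    events = np.asarray(deficient_counts, float)
    nonevents = np.asarray(sufficient_counts, float)
    if events.shape != (3,) or nonevents.shape != (3,):
        raise ValueError("expected counts for doses 0,1,2")
    dose = np.arange(3.0)
    design = pd.DataFrame({"const": 1.0, "dose": dose})
    res = fit_logistic(np.column_stack([events, nonevents]), design)
    row = res.coef_table.loc["dose"]
    return ORResult(float(row["or"]), float(row["ci_low"]), float(row["ci_high"]),
                    float(row["p"]), n_cases=int(events.sum()),
                    n_controls=int(nonevents.sum()), model_label="crude")


def trend_test(quintile, outcome, covariates: pd.DataFrame | None = None) -> float:
    """Wald p-value for a linear-in-category score across ordered groups.

    The quintile label enters the logistic model as a single numeric score;
    the reported p is the two-sided Wald p of its coefficient.
    """
    q = pd.Series(quintile).astype(float)
    y = pd.Series(outcome).astype(float)
    if q.dropna().nunique() < 2:
        raise ValueError("trend test needs at least two populated categories")
    X = pd.DataFrame({"const": 1.0, "score": q})
    if covariates is not None:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    X = X.dropna()
    res = fit_logistic(y.loc[X.index], X)
    return float(res.coef_table.loc["score", "p"])


def stratified_analysis(cohort: pd.DataFrame, stratifier: str,
                        exposure: str = "x_std", model_label: str = "crude",
                        min_n: int = 50) -> dict[str, ORResult]:
    """Continuous-exposure logistic model fitted independently per stratum.

    For case-only stratifiers (AJCC stage, symptom group, recruitment time)
    each stratum's cases are compared against the full control series, as the
    study's stratified tables do.  Strata below ``min_n`` subjects are skipped
    with a warning.
    """
    if stratifier not in cohort.columns:
        raise KeyError(f"no stratifier column {stratifier!r}")
    out: dict[str, ORResult] = {}
    controls = cohort[cohort["y"] == 0]
    case_only = cohort.loc[cohort["y"] == 1, stratifier].notna().any() and \
        cohort.loc[cohort["y"] == 0, stratifier].isna().all()
    levels = cohort[stratifier].dropna().unique()
    for level in sorted(map(str, levels)):
        mask = cohort[stratifier].astype("string") == level
        sub = pd.concat([cohort[mask & (cohort["y"] == 1)], controls]) if case_only \
            else cohort[mask]
        if len(sub) < min_n:
            warnings.warn(f"stratum {stratifier}={level}: n={len(sub)} < {min_n}; skipped",
                          stacklevel=2)
            continue
        out[level] = logistic_or(sub, exposure, model_label=model_label)
    return out


def interaction_lrt(cohort: pd.DataFrame, snp: str, exposure: str = "x_std",
                    covariates: tuple[str, ...] = ()) -> tuple[float, int, float]:
    """Likelihood-ratio test for genotype x phenotype interaction on disease.

    Compares nested logistic models of the outcome with and without the
    (allele dose) x (25-OHD) product term.  Returns (statistic, df, p) with
    the statistic 2*(ll_full - ll_reduced) referred to chi-square(df).
    """
    base_terms = (snp, exposure, *covariates)
    X0 = build_design(cohort, base_terms)
    y = cohort.loc[X0.index, "y"].astype(float)
    X1 = X0.copy()
    X1[f"{snp}:{exposure}"] = X0[snp] * X0[exposure]
    r0 = fit_logistic(y, X0)
    r1 = fit_logistic(y, X1)
    stat = max(0.0, 2.0 * (r1.llf - r0.llf))
    df = X1.shape[1] - X0.shape[1]
    return float(stat), int(df), float(stats.chi2.sf(stat, df))
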