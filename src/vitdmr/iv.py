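"""Instrumental-variable estimators of the causal odds ratio.

Five estimators of the causal effect of plasma 25-OHD (X, ng/ml) on disease
(Y), using genotype dosages or allele scores as instruments (Z):

* ``control_function`` — two-stage residual inclusion: OLS of X on Z, then a
  logistic regression of Y on the first-stage fitted values *and* residuals;
  the residual term absorbs unmeasured X-Y confounding.
* ``two_stage``        — the same second stage without the residual term.
* ``wald``             — ratio of the instrument-outcome log-odds coefficient
  to the instrument-exposure linear coefficient.
* ``msmm``             — multiplicative structural mean model, G-estimation:
  psi solves  sum_i (Z_i - Zhat_i) Y_i exp(-psi X_i) = 0; the exponentiated
  parameter is on the risk-ratio scale.
* ``lsmm``             — logistic structural mean model, double-logistic
  G-estimation: fit the association model logit P(Y|Z,X), then solve
  sum_i (Z_i - Zhat_i) expit(logit Phat_i - psi X_i) = 0.

Instrument strength is summarized by the first-stage partial F; values below
10 are flagged as weak by convention.  Confidence intervals are nonparametric
subject-level bootstrap percentile intervals (default 2,000 resamples)
re-running every stage, except the Wald ratio which defaults to the delta
method.  All estimates are reported per 1 ng/ml of 25-OHD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _glm
from ._glm import SeparationError
from .datatypes import FirstStageFit, IVEstimate
from .genetics import SCORE_COMPONENTS, build_allele_score

WEAK_F_THRESHOLD = 10.0
DEFAULT_BOOTSTRAP = 2000
Z975 = stats.norm.ppf(0.975)


class WeakInstrumentError(RuntimeError):
    """First-stage coefficient indistinguishable from zero; ratio unstable."""


class NonIdentifiedError(RuntimeError):
    """G-estimating equation has no sign change on the search interval."""


# ---------------------------------------------------------------------------
# data preparation

def _instrument_series(cohort: pd.DataFrame, instrument) -> pd.Series:
    """Resolve an instrument argument to a numeric per-subject series."""
    if hasattr(instrument, "values") and hasattr(instrument, "name") and \
            not isinstance(instrument, (str, pd.Series)):
        return instrument.values.rename(instrument.name)  # AlleleScore
    if isinstance(instrument, pd.Series):
        return instrument
    if instrument in cohort.columns:
        return cohort[instrument].astype(float)
    if instrument in SCORE_COMPONENTS:
        return build_allele_score(cohort, instrument).values
    raise KeyError(f"unknown instrument {instrument!r}")


def _exposure_col(cohort: pd.DataFrame, exposure: str | None) -> str:
    if exposure is not None:
        return exposure
    return "x_std" if "x_std" in cohort.columns else "x_raw"


@dataclass
class _IVData:
    """Complete-case arrays for one instrument/adjustment combination."""

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    C: np.ndarray  # covariates without intercept, shape (n, k) possibly k=0
    instrument: str
    adjusted: str

    @property
    def n(self) -> int:
        return self.y.size


def _prepare(cohort: pd.DataFrame, instrument, covariates=(), exposure=None) -> _IVData:
    z = _instrument_series(cohort, instrument)
    xcol = _exposure_col(cohort, exposure)
    frame = pd.DataFrame({
        "y": cohort["y"].astype(float),
        "x": cohort[xcol].astype(float),
        "z": z,
    })
    for c in covariates:
        frame[c] = cohort[c].astype(float)
    frame = frame.dropna()
    if frame.empty:
        raise ValueError("no complete cases for this instrument/covariate set")
    if frame["z"].nunique() < 2:
        raise ValueError(f"instrument {z.name!r} has no variation")
    label = "+".join(covariates) if covariates else "none"
    return _IVData(
        frame["y"].to_numpy(), frame["x"].to_numpy(), frame["z"].to_numpy(),
        frame[list(covariates)].to_numpy() if covariates else np.empty((len(frame), 0)),
        instrument=str(z.name), adjusted=label,
    )


def _with_const(*cols: np.ndarray) -> np.ndarray:
    n = cols[0].shape[0]
    parts = [np.ones((n, 1))]
    for c in cols:
        parts.append(c.reshape(n, -1))
    return np.concatenate(parts, axis=1)


# ---------------------------------------------------------------------------
# first stage

def first_stage(cohort: pd.DataFrame, instrument, covariates=(), exposure=None) -> FirstStageFit:
    """OLS of the phenotype on the instrument (plus covariates), with partial F.

    partial F = ((RSS_reduced - RSS_full)/q) / (RSS_full/(n-p)) for the q
    instrument columns, equal to the squared t statistic for a single
    instrument.  F < 10 sets the conventional weak-instrument flag.
    """
    d = _prepare(cohort, instrument, covariates, exposure)
    return _first_stage_arrays(d)


def _first_stage_arrays(d: _IVData) -> FirstStageFit:
    Xfull = _with_const(d.z, d.C)
    full = _glm.ols(Xfull, d.x)
    Xred = _with_const(d.C) if d.C.size else np.ones((d.n, 1))
    red = _glm.ols(Xred, d.x)
    q = 1
    df_resid = d.n - Xfull.shape[1]
    f = ((red.rss - full.rss) / q) / (full.rss / df_resid)
    f = max(0.0, float(f))
    r2 = float(1.0 - full.rss / red.rss)
    names = ["const", "instrument"] + [f"c{i}" for i in range(d.C.shape[1])]
    return FirstStageFit(
        coefficients=pd.Series(full.beta, index=names),
        fitted_x=full.fitted, residuals=full.residuals,
        partial_f=f, r2_instrument=r2, n=d.n,
        instrument=d.instrument, weak=f < WEAK_F_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# point-estimate kernels on arrays (shared by estimates and bootstrap)

def _cf_kernel(y, x, z, C, start=None):
    ols = _glm.ols(_with_const(z, C), x)
    X2 = _with_const(ols.fitted, ols.residuals, C)
    fit = _glm.logit(X2, y, beta0=start)
    return fit.beta[1], fit


def _tsls_kernel(y, x, z, C, start=None):
    ols = _glm.ols(_with_const(z, C), x)
    X2 = _with_const(ols.fitted, C)
    fit = _glm.logit(X2, y, beta0=start)
    return fit.beta[1], fit


def _wald_kernel(y, x, z, C):
    num = _glm.logit(_with_const(z, C), y)
    den = _glm.ols(_with_const(z, C), x)
    gamma, vg = num.beta[1], num.cov[1, 1]
    beta, vb = den.beta[1], den.cov[1, 1]
    psi = gamma / beta
    var = vg / beta**2 + gamma**2 * vb / beta**4  # independence approximation
    return psi, float(np.sqrt(var)), gamma, beta


def _centered_instrument(z, C):
    """Residual of Z on covariates (plain centering when there are none)."""
    if C.size:
        return _glm.ols(_with_const(C), z).residuals
    return z - z.mean()


def _solve_estimating_equation(g, lo=-2.0, hi=2.0, max_expand=2, xtol=1e-8,
                               n_grid: int = 81, hint: float | None = None):
    """Bracketed root of a G-estimating function, preferring the root nearest 0.

    The estimating functions are smooth but not globally monotone (extreme
    psi is dominated by single subjects with extreme exposure), so a plain
    endpoint bracket can miss an interior sign change.  A coarse grid over
    [lo, hi] locates sign changes; the interval closest to psi = 0 is refined
    by Brent's method.  If the grid shows none, the interval is doubled up to
    ``max_expand`` times before giving up.

    ``hint`` (e.g. the full-sample root during bootstrap resampling) is tried
    first with a narrow local bracket, skipping the grid scan when it works.
    """
    if hint is not None:
        for half_width in (0.1, 0.5):
            a, b = hint - half_width, hint + half_width
            ga, gb = g(a), g(b)
            if ga == 0.0:
                return float(a)
            if gb == 0.0:
                return float(b)
            if ga * gb < 0:
                return float(optimize.brentq(g, a, b, xtol=xtol))
    for _ in range(max_expand + 1):
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([g(t) for t in grid])
        exact = np.flatnonzero(vals == 0.0)
        if exact.size:
            return float(grid[exact[np.argmin(np.abs(grid[exact]))]])
        sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        if sign_change.size:
            mid = np.abs(grid[sign_change] + grid[sign_change + 1]) / 2
            k = sign_change[np.argmin(mid)]
            return float(optimize.brentq(g, grid[k], grid[k + 1], xtol=xtol))
        lo, hi = 2 * lo, 2 * hi
    raise NonIdentifiedError(
        f"estimating function has no sign change on [{lo/2:g},{hi/2:g}] "
        f"(g(lo)={g(lo/2):.3g}, g(hi)={g(hi/2):.3g})"
    )


def _msmm_kernel(y, x, z, C, bracket=(-2.0, 2.0), hint=None):
    w = _centered_instrument(z, C)
    xc = x - x.mean()  # centring keeps exp arguments moderate; roots unchanged
    wy = w * y

    def g(psi):
        e = -psi * xc
        e -= e.max()  # positive rescaling preserves the sign
        return float(np.sum(wy * np.exp(e)))

    return _solve_estimating_equation(g, *bracket, hint=hint)


def _lsmm_kernel(y, x, z, C, bracket=(-2.0, 2.0), start=None, hint=None):
    X = _with_const(z, x, C)
    assoc = _glm.logit(X, y, beta0=start)
    eta = X @ assoc.beta
    w = _centered_instrument(z, C)

    def g(psi):
        return float(np.sum(w * _glm._expit(eta - psi * x)))

    return _solve_estimating_equation(g, *bracket, hint=hint), assoc


# ---------------------------------------------------------------------------
# bootstrap machinery

def _bootstrap_ci(point_fn, d: _IVData, n_boot: int, seed, warm=None):
    """Percentile bootstrap over subjects, re-running every estimation stage.

    Resamples that fail (separation, unidentified estimating equation) are
    dropped; more than 20% failures raises, since the interval would be
    unreliable.
    """
    rng = np.random.default_rng(seed)
    psis = np.empty(n_boot)
    failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, d.n, d.n)
        try:
            psis[b] = point_fn(d.y[idx], d.x[idx], d.z[idx], d.C[idx], warm)
        except (SeparationError, NonIdentifiedError, np.linalg.LinAlgError):
            psis[b] = np.nan
            failed += 1
    if failed > 0.2 * n_boot:
        raise NonIdentifiedError(
            f"{failed}/{n_boot} bootstrap resamples failed; CI unreliable")
    lo, hi = np.nanpercentile(psis, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# public estimators

def control_function(cohort, instrument, covariates=(), exposure=None,
                     n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> IVEstimate:
    """Control-function (two-stage residual inclusion) causal odds ratio.

    Second-stage logistic regression of Y on the first-stage fitted values
    and residuals (plus covariates); the causal OR is exp(coefficient of the
    fitted values).  Bootstrap percentile CI re-runs both stages per resample.
    """
    d = _prepare(cohort, instrument, covariates, exposure)
    fs = _first_stage_arrays(d)
    psi, fit = _cf_kernel(d.y, d.x, d.z, d.C)

    if not n_boot:
        return _estimate("control_function", psi, psi, psi, "none", d, fs)

    def point(y, x, z, C, warm):
        return _cf_kernel(y, x, z, C, start=warm)[0]

    lo, hi = _bootstrap_ci(point, d, n_boot, seed, warm=fit.beta)
    return _estimate("control_function", psi, lo, hi, "bootstrap", d, fs)


def two_stage(cohort, instrument, covariates=(), exposure=None,
              n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> IVEstimate:
    """Two-stage estimator: logistic regression of Y on first-stage fitted values."""
    d = _prepare(cohort, instrument, covariates, exposure)
    fs = _first_stage_arrays(d)
    psi, fit = _tsls_kernel(d.y, d.x, d.z, d.C)

    if not n_boot:
        return _estimate("two_stage", psi, psi, psi, "none", d, fs)

    def point(y, x, z, C, warm):
        return _tsls_kernel(y, x, z, C, start=warm)[0]

    lo, hi = _bootstrap_ci(point, d, n_boot, seed, warm=fit.beta)
    return _estimate("two_stage", psi, lo, hi, "bootstrap", d, fs)


def wald_ratio(cohort, instrument, covariates=(), exposure=None,
               ci: str = "delta", n_boot: int = DEFAULT_BOOTSTRAP,
               seed: int = 0, min_f: float = 0.01) -> IVEstimate:
    """Wald (ratio) estimator: instrument-outcome over instrument-exposure slope.

    Refuses outright (``WeakInstrumentError``) when the first-stage partial F
    falls below ``min_f`` — a first-stage coefficient indistinguishable from
    zero makes the ratio unstable.  F < 10 is flagged as weak but estimated.
    """
    d = _prepare(cohort, instrument, covariates, exposure)
    fs = _first_stage_arrays(d)
    if fs.partial_f < min_f:
        raise WeakInstrumentError(
            f"first-stage F={fs.partial_f:.3g} < {min_f}; Wald ratio unstable")
    psi, se, gamma, beta = _wald_kernel(d.y, d.x, d.z, d.C)
    if ci == "delta":
        lo, hi = psi - Z975 * se, psi + Z975 * se
    elif ci == "bootstrap":
        def point(y, x, z, C, warm):
            return _wald_kernel(y, x, z, C)[0]
        lo, hi = _bootstrap_ci(point, d, n_boot, seed)
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return _estimate("wald", psi, lo, hi, ci, d, fs)


def msmm(cohort, instrument, covariates=(), exposure=None,
         n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> IVEstimate:
    """Multiplicative structural mean model by G-estimation.

    Solves  sum_i (Z_i - Zhat_i) Y_i exp(-psi X_i) = 0  by bracketed root
    finding (psi in [-2, 2] per ng/ml, expanded on failure, tolerance 1e-8).
    The reported exp(psi) is a risk-ratio-scale causal parameter and is
    labelled as such.
    """
    d = _prepare(cohort, instrument, covariates, exposure)
    fs = _first_stage_arrays(d)
    psi = _msmm_kernel(d.y, d.x, d.z, d.C)

    if not n_boot:
        est = _estimate("msmm", psi, psi, psi, "none", d, fs)
        est.scale = "risk ratio"
        return est

    def point(y, x, z, C, warm):
        return _msmm_kernel(y, x, z, C, hint=warm)

    lo, hi = _bootstrap_ci(point, d, n_boot, seed, warm=psi)
    est = _estimate("msmm", psi, lo, hi, "bootstrap", d, fs)
    est.scale = "risk ratio"
    return est


def lsmm(cohort, instrument, covariates=(), exposure=None,
         n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> IVEstimate:
    """Logistic structural mean model by double-logistic G-estimation.

    Fits the association model logit P(Y=1|Z,X,C) by maximum likelihood, then
    solves  sum_i (Z_i - Zhat_i) expit(logit Phat_i - psi X_i) = 0  for psi.
    The bootstrap re-runs both steps.
    """
    d = _prepare(cohort, instrument, covariates, exposure)
    fs = _first_stage_arrays(d)
    psi, assoc = _lsmm_kernel(d.y, d.x, d.z, d.C)

    if not n_boot:
        return _estimate("lsmm", psi, psi, psi, "none", d, fs)

    def point(y, x, z, C, warm):
        return _lsmm_kernel(y, x, z, C, start=warm[0], hint=warm[1])[0]

    lo, hi = _bootstrap_ci(point, d, n_boot, seed, warm=(assoc.beta, psi))
    return _estimate("lsmm", psi, lo, hi, "bootstrap", d, fs)


def _estimate(method, psi, lo, hi, ci_method, d: _IVData, fs: FirstStageFit) -> IVEstimate:
    lo, hi = min(lo, psi), max(hi, psi)  # guard against percentile edge ties
    return IVEstimate(
        method=method, or_per_unit=float(np.exp(psi)),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        ci_method=ci_method, instrument=d.instrument,
        f_stat=fs.partial_f, adjusted=d.adjusted, n=d.n,
    )


ESTIMATORS = {
    "control_function": control_function,
    "two_stage": two_stage,
    "wald": wald_ratio,
    "msmm": msmm,
    "lsmm": lsmm,
}

#: Default Table-4-style instrument set: each SNP plus the three allele scores.
DEFAULT_INSTRUMENTS = (
    "rs2282679", "rs12785878", "rs10741657", "rs6013897",
    "overall", "upstream", "downstream",
)
DEFAULT_ADJUSTMENTS = {"none": (), "age+sex": ("age", "sex")}


def run_table4(cohort: pd.DataFrame, estimators=("control_function",),
               instruments=DEFAULT_INSTRUMENTS,
               adjustments: dict | None = None,
               n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0,
               exposure=None) -> pd.DataFrame:
    """Full instrument x adjustment x estimator grid of causal odds ratios.

    One row per combination, shaped like the study's causal-estimate table:
    OR with 95% CI, first-stage F, n, and the weak-instrument flag.  A
    combination whose estimator fails is retained with the failure reason in
    ``note`` — one bad instrument never aborts the grid.
    """
    adjustments = DEFAULT_ADJUSTMENTS if adjustments is None else adjustments
    rows = []
    for inst in instruments:
        for adj_label, covs in adjustments.items():
            for est_name in estimators:
                fn = ESTIMATORS[est_name]
                row = {"instrument": inst, "adjusted": adj_label, "method": est_name}
                try:
                    e = fn(cohort, inst, covariates=covs, exposure=exposure,
                           n_boot=n_boot, seed=seed)
                    row.update(or_per_unit=e.or_per_unit, ci_low=e.ci_low,
                               ci_high=e.ci_high, f_stat=e.f_stat, n=e.n,
                               weak=e.f_stat < WEAK_F_THRESHOLD,
                               ci_method=e.ci_method, scale=e.scale, note="")
                except (WeakInstrumentError, NonIdentifiedError,
                        SeparationError, ValueError) as exc:
                    row.update(or_per_unit=np.nan, ci_low=np.nan, ci_high=np.nan,
                               f_stat=np.nan, n=np.nan, weak=True,
                               ci_method="", scale="", note=f"non-estimable: {exc}")
                rows.append(row)
    return pd.DataFrame(rows)
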