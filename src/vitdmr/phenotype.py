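"""Phenotype preparation: month standardization, deficiency flag, quintiles.

Plasma 25-OHD varies strongly with the month of blood draw (winter troughs at
northern latitudes).  Analyses therefore use month-standardized values: each
month stratum is recentred to the grand mean, which removes the seasonal
component while preserving the overall level and within-month variation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Clinical deficiency threshold for plasma 25-OHD, ng/ml.
DEFICIENCY_THRESHOLD = 10.0


def standardize_by_month(cohort: pd.DataFrame, value_col: str = "x_raw",
                         month_col: str = "month") -> pd.Series:
    """Remove month-of-draw means from the phenotype, preserving the grand mean.

    x_std = x_raw - mean(x_raw | month) + grand_mean.  Strata with fewer than
    two non-missing observations are left uncentred (with a warning), since a
    within-stratum mean estimated from one value would zero it out.
    Idempotent: standardizing already-standardized values is a no-op.
    """
    x = cohort[value_col].astype(float)
    month = cohort[month_col]
    present = x.notna()
    if (present & month.isna()).any():
        raise ValueError("month must be present wherever the phenotype is")
    grand = x[present].mean()
    x_std = x.copy()
    for m, idx in x[present].groupby(month[present]).groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"month stratum {m} has {len(idx)} observation(s); left uncentred",
                stacklevel=2,
            )
            continue
        x_std.loc[idx] = x.loc[idx] - x.loc[idx].mean() + grand
    return x_std.rename("x_std")


def deficiency_flag(x_std: pd.Series, threshold: float = DEFICIENCY_THRESHOLD) -> pd.Series:
    """Binary 25-OHD deficiency indicator (1 = below threshold)."""
    return (x_std < threshold).where(x_std.notna()).astype("float").rename("deficient")


def quintile_bounds(x: np.ndarray | pd.Series) -> np.ndarray:
    """20/40/60/80 empirical percentiles (linear interpolation) of pooled values."""
    x = np.asarray(pd.Series(x).dropna(), float)
    if x.size < 5:
        raise ValueError("need at least 5 non-missing values for quintiles")
    return np.percentile(x, [20, 40, 60, 80])


def assign_quintiles(x_std: pd.Series, bounds: np.ndarray | None = None) -> pd.Series:
    """Quintile label 1-5 from pooled case+control percentile boundaries.

    Each quintile is left-closed at its lower bound (a value equal to a
    boundary belongs to the higher quintile); the lowest quintile is open
    below.  With heavy ties several boundaries can coincide, collapsing the
    middle groups; a warning reports the realized group sizes.
    """
    x = pd.Series(x_std).astype(float)
    b = quintile_bounds(x) if bounds is None else np.asarray(bounds, float)
    if np.any(np.diff(b) < 0):
        raise ValueError("quintile boundaries must be non-decreasing")
    arr = x.to_numpy()
    q = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    q[ok] = 1 + (arr[ok, None] >= b[None, :]).sum(axis=1)
    sizes = pd.Series(q[ok]).value_counts().sort_index()
    if len(sizes) < 5 and ok.sum() >= 5:
        warnings.warn(
            f"ties collapsed quintile boundaries; populated groups: {sizes.to_dict()}",
            stacklevel=2,
        )
    return pd.Series(q, index=x.index, name="quintile")


def prepare_phenotype(cohort: pd.DataFrame) -> pd.DataFrame:
    """Month-standardize, flag deficiency, and assign pooled quintiles.

    Returns a copy of the cohort with ``x_std``, ``deficient`` and
    ``quintile`` columns appended.
    """
    out = cohort.copy()
    out["x_std"] = standardize_by_month(cohort)
    out["deficient"] = deficiency_flag(out["x_std"])
    out["quintile"] = assign_quintiles(out["x_std"])
    return out
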