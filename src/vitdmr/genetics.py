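"""Genotype QC and instrument construction.

Hardy-Weinberg testing of genotype counts and unweighted allele scores that
combine raising-allele dosages across SNPs into composite instruments:
``overall`` (all four SNPs), ``upstream`` (synthesis-arm SNPs rs12785878 and
rs10741657) and ``downstream`` (metabolism-arm SNPs rs2282679 and rs6013897).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UPSTREAM_SNPS, DOWNSTREAM_SNPS, ALL_SNPS

SCORE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "overall": ALL_SNPS,
    "upstream": UPSTREAM_SNPS,
    "downstream": DOWNSTREAM_SNPS,
}


def hwe_test(genotype_counts) -> tuple[float, float]:
    """One-degree-of-freedom Pearson chi-square test of Hardy-Weinberg equilibrium.

    ``genotype_counts`` is the (hom_ref, het, hom_alt) triple.  The allele
    frequency is estimated from the counts themselves, expected genotype
    counts follow p^2 : 2pq : q^2, and the statistic is sum (O-E)^2/E with one
    degree of freedom (two free genotype proportions minus one estimated
    allele frequency).  No continuity correction.

    Returns ``(chi2, p_value)``.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("genotype_counts must be a (hom_ref, het, hom_alt) triple")
    if np.any(counts < 0) or np.any(~np.isfinite(counts)):
        raise ValueError("genotype counts must be non-negative finite numbers")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    # monomorphic sample: observed == expected by construction
    nz = expected > 0
    chi2 = float(np.sum((counts[nz] - expected[nz]) ** 2 / expected[nz]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_test_dosages(dosages) -> tuple[float, float]:
    """HWE test from a vector of 0/1/2 dosages (missing values dropped)."""
    d = pd.Series(dosages).dropna().astype(int)
    counts = [(d == k).sum() for k in (0, 1, 2)]
    return hwe_test(counts)


@dataclass
class AlleleScore:
    """A composite instrument: unweighted sum of raising-allele dosages."""

    name: str
    component_snps: tuple[str, ...]
    values: pd.Series  # 0..2k, NaN where any component genotype is missing

    @property
    def max_value(self) -> int:
        return 2 * len(self.component_snps)


def build_allele_score(cohort: pd.DataFrame, name: str = "overall",
                       weights: dict[str, float] | None = None) -> AlleleScore:
    """Sum raising-allele dosages over a score's component SNPs.

    Genotype columns must already be oriented as raising-allele counts.  A
    subject missing any component genotype gets a missing score.  ``weights``
    (per-SNP multipliers, e.g. external per-allele effects) are off by
    default; the standard instrument is the unweighted sum.
    """
    if name not in SCORE_COMPONENTS:
        raise KeyError(f"unknown allele score {name!r}; choose from {sorted(SCORE_COMPONENTS)}")
    snps = SCORE_COMPONENTS[name]
    missing_cols = [s for s in snps if s not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks genotype column(s) {missing_cols}")
    block = cohort[list(snps)].astype(float)
    bad = block.stack(future_stack=True).dropna()
    if not bad.isin([0.0, 1.0, 2.0]).all():
        raise ValueError("genotype dosages must be 0/1/2 (raising-allele oriented)")
    if weights:
        block = block * pd.Series({s: weights.get(s, 1.0) for s in snps})
    values = block.sum(axis=1, skipna=False).rename(f"score_{name}")
    return AlleleScore(name, tuple(snps), values)


def add_allele_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ``score_overall``, ``score_upstream``, ``score_downstream`` columns."""
    out = cohort.copy()
    for name in SCORE_COMPONENTS:
        out[f"score_{name}"] = build_allele_score(cohort, name).values
    return out
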