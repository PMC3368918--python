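"""Synthetic case-control cohort generator.

Implements the data-generating process the Mendelian-randomization analysis
assumes (instrument -> phenotype -> outcome, with an unmeasured confounder of
the phenotype-outcome edge and no direct instrument-outcome path):

    X = mu_x + sum_j beta_j Z_j + month_effect[month] + gamma_u_x U + eps
    logit P(Y=1) = alpha0 + psi X + gamma_u_y U          (+ optional pleiotropy)

with Z_j ~ Binomial(2, p_j) i.i.d. (Hardy-Weinberg), U ~ N(0,1),
eps ~ N(0, sigma_x^2).  Cases and controls are then ascertained
retrospectively from the simulated population, mirroring the case-control
design of the modelled study.  The latent confounder U is retained in the
output for oracle checks; real data never has it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import SNPSpec, SimulationConfig, ALL_SNPS


class AscertainmentError(RuntimeError):
    """Population contains fewer cases/controls than the design requests."""


def generate_genotypes(n: int, spec: SNPSpec | float, seed=None) -> np.ndarray:
    """Draw n raising-allele dosages (0/1/2) under Hardy-Weinberg equilibrium.

    ``spec`` is a :class:`SNPSpec` or a bare allele frequency; the degenerate
    frequencies 0 and 1 are allowed here (fixed alleles) even though a
    polymorphic :class:`SNPSpec` requires the open interval.  ``seed`` may be
    an int or a :class:`numpy.random.Generator`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    freq = spec.raising_allele_freq if isinstance(spec, SNPSpec) else float(spec)
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {freq}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, freq, size=n)


def _covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Baseline covariates, drawn independently of genotype, U, X and Y.

    Independence encodes the core instrumental-variable assumption that
    genotype is unrelated to measured confounders; the balance diagnostics are
    calibrated against exactly this null.
    """
    return {
        "age": np.clip(rng.normal(62.0, 10.0, n), 25.0, 79.0).round(1),
        "sex": rng.integers(0, 2, n),
        "deprivation": rng.integers(1, 8, n),  # area-deprivation index 1-7
        "energy": np.clip(rng.normal(8.0, 2.5, n), 2.0, None).round(2),  # MJ/day
        "smoking": rng.choice(3, n, p=[0.5, 0.3, 0.2]),  # never/former/current
        "bmi": np.clip(rng.normal(27.0, 4.5, n), 15.0, 55.0).round(1),
        "nsaid": rng.binomial(1, 0.3, n),
        "family_history": rng.binomial(1, 0.1, n),  # medium/high vs low
        "activity": rng.choice(4, n, p=[0.4, 0.3, 0.2, 0.1]),
    }


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a population and ascertain a case-control cohort from it.

    Returns a DataFrame with one row per sampled subject (cases first) and
    the documented cohort columns.  Case-only fields (AJCC stage, symptom
    group, time-to-recruitment group) are missing for controls.  The
    generation is a pure function of ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_population

    genotypes = {s.snp_id: generate_genotypes(n, s, rng) for s in config.snps}
    u = rng.normal(0.0, 1.0, n)
    month = rng.integers(1, 13, n)
    eps = rng.normal(0.0, config.sigma_x, n)

    x = config.mu_x + config.gamma_u_x * u + eps
    x = x + np.asarray(config.month_effects)[month - 1]
    for s in config.snps:
        x = x + s.beta_x * genotypes[s.snp_id]
    x = np.clip(x, 0.0, None)  # plasma concentration cannot be negative

    eta = config.alpha0 + config.psi * x + config.gamma_u_y * u
    for snp_id, direct in config.pleiotropy.items():
        eta = eta + direct * genotypes[snp_id]  # exclusion-restriction violation
    p_case = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, p_case)

    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if len(case_idx) < config.n_cases or len(control_idx) < config.n_controls:
        raise AscertainmentError(
            f"population yielded {len(case_idx)} cases / {len(control_idx)} controls; "
            f"design requires {config.n_cases} / {config.n_controls}"
        )
    take_cases = rng.choice(case_idx, config.n_cases, replace=False)
    take_controls = rng.choice(control_idx, config.n_controls, replace=False)
    idx = np.concatenate([take_cases, take_controls])

    cov = _covariates(rng, n)
    m = len(idx)
    df = pd.DataFrame({
        "id": np.arange(m),
        "y": y[idx],
        "x_raw": x[idx].round(4),
        "month": month[idx],
    })
    for s in config.snps:
        df[s.snp_id] = genotypes[s.snp_id][idx].astype(float)
    for k, v in cov.items():
        df[k] = v[idx]

    # case-only descriptors
    is_case = df["y"].to_numpy() == 1
    stage = np.where(rng.random(m) < 0.45, "early", "late")
    symptoms = rng.choice(
        ["none", "mild", "severe", "both"], m, p=[0.138, 0.211, 0.160, 0.491]
    )
    tdr = np.where(rng.random(m) < 0.5, "early", "late")
    df["stage"] = np.where(is_case, stage, None)
    df["symptom_group"] = np.where(is_case, symptoms, None)
    df["tdr_group"] = np.where(is_case, tdr, None)
    df["u"] = u[idx]

    if config.missing_phenotype > 0:
        df.loc[rng.random(m) < config.missing_phenotype, "x_raw"] = np.nan
    if config.missing_genotype > 0:
        for s in config.snps:
            df.loc[rng.random(m) < config.missing_genotype, s.snp_id] = np.nan
    return df


def null_config(**overrides) -> SimulationConfig:
    """A convenience DGP with no causal effect and no confounding.

    Used by the coverage and calibration studies; everything else follows the
    default study-scale parameterization unless overridden.
    """
    base = dict(gamma_u_x=0.0, gamma_u_y=0.0, psi=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


def _required_population(n_cases: int, n_controls: int, prevalence: float, margin: float = 1.6) -> int:
    """Population size giving the requested counts with comfortable headroom."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0,1)")
    need = max(n_cases / prevalence, n_controls / (1.0 - prevalence))
    return int(np.ceil(need * margin))
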