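"""Shared fixtures: small seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from vitdmr import SimulationConfig, prepare_phenotype
from vitdmr.genetics import add_allele_scores
from vitdmr.simulate import generate_cohort


def scaled_config(**overrides) -> SimulationConfig:
    """Study-shaped DGP at reduced population scale for fast tests."""
    base = dict(n_population=30_000, n_cases=1_500, n_controls=1_500,
                alpha0=-2.2, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """Default confounded-null cohort (3,000 subjects), phenotype-prepared."""
    c = prepare_phenotype(generate_cohort(scaled_config()))
    return add_allele_scores(c)


@pytest.fixture(scope="session")
def clean_cohort():
    """No-confounding, no-season null cohort: the simplest IV testbed."""
    cfg = scaled_config(gamma_u_x=0.0, gamma_u_y=0.0, psi=0.0,
                        month_effects=(0.0,) * 12, seed=7)
    c = prepare_phenotype(generate_cohort(cfg))
    return add_allele_scores(c)


@pytest.fixture()
def iv_frame():
    """Hand-built mini dataset with binary instrument for algebraic identities."""
    rng = np.random.default_rng(42)
    n = 1500
    z = rng.binomial(1, 0.4, n).astype(float)
    x = 10 + 1.5 * z + rng.normal(0, 3, n)
    eta = -1.0 - 0.08 * x
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x": x, "z": z,
                         "age": rng.normal(60, 8, n), "sex": rng.binomial(1, 0.5, n)})
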