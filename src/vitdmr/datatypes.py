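"""Core value types shared across the pipeline.

The single data currency is the *cohort*: a :class:`pandas.DataFrame` with one
row per subject and the columns listed in :data:`COHORT_COLUMNS`.  Genotypes
are stored as raising-allele dosages (0/1/2), i.e. already oriented so that
each counted allele raises plasma 25-OHD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: SNP instruments used throughout: vitamin-D pathway variants grouped into an
#: upstream (synthesis: DHCR7, CYP2R1) and a downstream (metabolism: GC,
#: CYP24A1) arm.
UPSTREAM_SNPS = ("rs12785878", "rs10741657")
DOWNSTREAM_SNPS = ("rs2282679", "rs6013897")
ALL_SNPS = DOWNSTREAM_SNPS[:1] + UPSTREAM_SNPS + DOWNSTREAM_SNPS[1:]

#: Documented cohort column set (genotype columns are named by SNP id).
COHORT_COLUMNS = [
    "id", "y", "x_raw", "month",
    *ALL_SNPS,
    "age", "sex", "deprivation", "energy", "smoking", "bmi", "nsaid",
    "family_history", "activity", "stage", "symptom_group", "tdr_group",
    "u",
]


@dataclass(frozen=True)
class SNPSpec:
    """Per-SNP metadata: raising-allele frequency and effect on 25-OHD.

    ``beta_x`` is the additive per-raising-allele effect on plasma 25-OHD in
    ng/ml.  ``label`` assigns the SNP to the synthesis (upstream) or
    metabolism (downstream) arm of the vitamin-D pathway.
    """

    snp_id: str
    raising_allele_freq: float
    beta_x: float
    label: str  # "synthesis" | "metabolism"
    raising_allele: str = "?"

    def __post_init__(self):
        if not 0.0 < self.raising_allele_freq < 1.0:
            raise ValueError(
                f"raising_allele_freq must be in (0,1), got {self.raising_allele_freq}"
            )
        if self.label not in ("synthesis", "metabolism"):
            raise ValueError(f"unknown pathway label {self.label!r}")


def default_snp_panel() -> list[SNPSpec]:
    """The four-SNP instrument panel with approximate population parameters.

    Raising-allele frequencies are estimated from published control genotype
    counts of the Scottish colorectal-cancer case-control study this package
    models, and per-allele effects are back-calculated from the study's
    printed first-stage F statistics at n = 4,238 with the generator's own
    season-free residual SD (sqrt(sigma_x^2 + gamma_u_x^2) ~ 7.3 ng/ml):
    beta_j = sqrt(F_j * sigma^2 / (n * 2 p_j (1 - p_j))).  Both are
    approximations: the study never printed them directly.
    """
    return [
        SNPSpec("rs2282679", 0.713, 0.695, "metabolism", "A"),
        SNPSpec("rs12785878", 0.805, 0.733, "synthesis", "T"),
        SNPSpec("rs10741657", 0.400, 0.533, "synthesis", "A"),
        SNPSpec("rs6013897", 0.808, 0.199, "metabolism", "T"),
    ]


def _default_month_effects() -> tuple[float, ...]:
    # Sinusoidal seasonality peaking in late summer, amplitude ~40% of the
    # overall mean (5 ng/ml on a ~12.4 ng/ml cohort mean): the dominant month
    # effect that the phenotype-preparation stage standardizes away.
    months = np.arange(1, 13)
    return tuple(float(v) for v in 5.0 * np.cos(2 * np.pi * (months - 8) / 12.0))


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic case-control data-generating process.

    Defaults mirror the modelled study: ~2,000 cases and ~2,200 controls
    ascertained retrospectively from a large population, a four-SNP instrument
    panel whose strength matches the study's first-stage F statistics, strong
    seasonality in raw 25-OHD, and a confounded-null disease model (no causal
    25-OHD effect, ``psi = 0``, with an unmeasured confounder inducing the
    observational inverse association).
    """

    n_population: int = 200_000
    n_cases: int = 2_001
    n_controls: int = 2_237
    snps: list[SNPSpec] = field(default_factory=default_snp_panel)
    mu_x: float = 9.5         # baseline 25-OHD, ng/ml (cohort mean ~12.4 with genetics)
    sigma_x: float = 7.0      # residual SD of 25-OHD, ng/ml
    month_effects: tuple = field(default_factory=_default_month_effects)
    gamma_u_x: float = 2.0    # confounder -> 25-OHD (ng/ml per SD of U)
    gamma_u_y: float = -0.9   # confounder -> disease log-odds per SD of U
    psi: float = 0.0          # causal log-odds of disease per ng/ml 25-OHD
    alpha0: float = -2.9      # baseline disease log-odds (prevalence ~5%)
    seed: int = 0
    # optional knobs, all off by default
    pleiotropy: dict = field(default_factory=dict)  # snp_id -> direct log-odds/allele
    missing_phenotype: float = 0.0  # MCAR missingness proportions
    missing_genotype: float = 0.0

    def __post_init__(self):
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be positive")
        if len(self.month_effects) != 12:
            raise ValueError("month_effects must have exactly 12 entries")
        if self.n_cases + self.n_controls > self.n_population:
            raise ValueError("requested sample exceeds population size")
        for p in (self.missing_phenotype, self.missing_genotype):
            if not 0.0 <= p < 1.0:
                raise ValueError("missingness proportions must be in [0,1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["month_effects"] = [float(v) for v in self.month_effects]
        for k, v in d.items():
            if isinstance(v, (np.floating, np.integer)):
                d[k] = v.item()
        d["snps"] = [{**s, "raising_allele_freq": float(s["raising_allele_freq"]),
                      "beta_x": float(s["beta_x"])} for s in d["snps"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "snps" in d:
            d["snps"] = [s if isinstance(s, SNPSpec) else SNPSpec(**s) for s in d["snps"]]
        if "month_effects" in d:
            d["month_effects"] = tuple(d["month_effects"])
        return cls(**d)


@dataclass
class FirstStageFit:
    """Products of the first-stage linear regression of 25-OHD on the instrument."""

    coefficients: pd.Series
    fitted_x: np.ndarray
    residuals: np.ndarray
    partial_f: float
    r2_instrument: float
    n: int
    instrument: str
    weak: bool  # F < 10 convention

    def __post_init__(self):
        if self.partial_f < 0:
            raise ValueError("partial F cannot be negative")


@dataclass
class IVEstimate:
    """One instrumental-variable estimate of the causal odds ratio per ng/ml."""

    method: str              # control_function | wald | two_stage | msmm | lsmm
    or_per_unit: float
    ci_low: float
    ci_high: float
    ci_method: str           # bootstrap | delta
    instrument: str
    f_stat: float
    adjusted: str            # covariate-set label, e.g. "none" or "age+sex"
    n: int
    scale: str = "odds ratio"  # msmm reports a risk-ratio-scale parameter

    def __post_init__(self):
        if self.or_per_unit <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.or_per_unit <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class ORResult:
    """Odds ratio with Wald-type 95% CI, as printed in association tables."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    model_label: str = "crude"
    note: str = ""

    def __post_init__(self):
        if self.estimate <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class PowerResult:
    """Simulation-based power of the MR design at a given significance level."""

    power: float
    mc_se: float
    n_replicates: int
    alpha: float
    estimator: str
    dgp: dict

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0,1]")
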