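"""Cohort ingest and writing: CSV cohorts, YAML configs, JSON manifests."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import SimulationConfig, SNPSpec, ALL_SNPS

log = logging.getLogger("vitdmr")

_CASE_ONLY = ("stage", "symptom_group", "tdr_group")


def write_cohort(cohort: pd.DataFrame, path, config: SimulationConfig | None = None) -> None:
    """Write a cohort CSV, plus YAML config and JSON manifest when synthetic."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    if config is not None:
        write_config(config, path.with_suffix(".config.yaml"))
        manifest = {
            "seed": config.seed,
            "n_rows": int(len(cohort)),
            "n_cases": int((cohort["y"] == 1).sum()),
            "n_controls": int((cohort["y"] == 0).sum()),
            "columns": list(cohort.columns),
        }
        path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))


def write_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path) -> SimulationConfig:
    return SimulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _dosage_from_pair(value: str, raising: str) -> float:
    """Count raising alleles in an allele-pair string such as "AC"."""
    pair = value.strip().upper()
    if len(pair) != 2 or not pair.isalpha():
        raise ValueError(f"malformed genotype {value!r}")
    return float(sum(1 for a in pair if a == raising.upper()))


def ingest(path, snps: list[SNPSpec] | None = None) -> pd.DataFrame:
    """Read and validate a subject-level cohort table (CSV or TSV).

    Genotype columns may hold 0/1/2 dosages or allele-pair strings ("AC"),
    which are converted to raising-allele counts using each SNP's configured
    raising allele.  Rows with invalid values (unknown genotype symbol,
    month outside 1-12, negative phenotype, outcome not 0/1) are rejected and
    logged; a per-column missingness report is logged at INFO level.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "y" not in df.columns:
        raise ValueError("cohort file must have a 'y' case/control column")
    snps = snps or []
    raising = {s.snp_id: s.raising_allele for s in snps}

    for col in df.columns:
        if col in ALL_SNPS and df[col].dtype == object:
            allele = raising.get(col)
            if allele in (None, "?"):
                raise ValueError(
                    f"column {col!r} holds allele pairs but no raising allele is configured")
            converted = []
            for v in df[col]:
                if pd.isna(v):
                    converted.append(np.nan)
                    continue
                try:
                    converted.append(_dosage_from_pair(str(v), allele))
                except ValueError:
                    converted.append(np.inf)  # marks the row for rejection
            df[col] = converted

    bad = pd.Series(False, index=df.index)
    reasons = []

    def reject(mask, why):
        nonlocal bad
        n = int((mask & ~bad).sum())
        if n:
            reasons.append(f"{n} row(s): {why}")
        bad |= mask

    reject(~df["y"].isin([0, 1]), "case/control status not 0/1")
    if "month" in df.columns:
        reject(df["month"].notna() & ~df["month"].isin(range(1, 13)),
               "month outside 1..12")
    if "x_raw" in df.columns:
        reject(df["x_raw"].notna() & (df["x_raw"] < 0), "negative 25-OHD")
    for col in ALL_SNPS:
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce")
            reject(df[col].notna() & (~np.isfinite(v) | ~v.isin([0, 1, 2])),
                   f"invalid {col} genotype")
            df[col] = v
    for why in reasons:
        log.warning("ingest rejected %s", why)
    df = df[~bad].reset_index(drop=True)

    miss = df.isna().mean()
    for col, frac in miss[miss > 0].items():
        log.info("ingest: column %s %.1f%% missing", col, 100 * frac)
    return df
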