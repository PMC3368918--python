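"""Published count tables from the modelled Scottish CRC case-control study.

The subject-level data of the study this package models (2,001 colorectal
cancer cases / 2,237 population controls; genotyped series up to ~5,449) were
never deposited, but its printed tables give marginal counts that pin down
the contingency-table and grouped-logistic analyses exactly.  They serve as
reference inputs and regression fixtures.

Conventions: genotype counts are keyed by raising-allele dosage 0/1/2
(rs2282679: A raises 25-OHD; rs12785878: T; rs10741657: A; rs6013897: per its
printed per-T row).  "deficient" means plasma 25-OHD < 10 ng/ml.
"""

from __future__ import annotations

#: 25-OHD deficiency split of cases/controls: {category: (cases, controls)}.
TABLE1_BINARY = {
    "deficient": (973, 826),     # < 10 ng/ml (reference)
    "sufficient": (1028, 1411),  # >= 10 ng/ml
}

#: Pooled-quintile split of cases/controls, lowest to highest 25-OHD.
#: Printed quintile boundaries: 5.31, 9.39, 13.20, 18.36 ng/ml.
TABLE1_QUINTILES = [
    (486, 366),
    (461, 425),
    (376, 430),
    (358, 505),
    (320, 511),
]
TABLE1_QUINTILE_BOUNDS = (5.31, 9.39, 13.20, 18.36)

#: Genotype (dosage 0/1/2) vs deficiency: {snp: [(deficient, sufficient), ...]}.
TABLE2_DEFICIENCY = {
    "rs2282679": [(133, 165), (698, 905), (767, 1163)],
    "rs12785878": [(72, 66), (470, 620), (980, 1366)],
    "rs10741657": [(512, 672), (385, 925), (211, 318)],
    "rs6013897": [(47, 72), (470, 599), (968, 1319)],
}

#: Genotype vs case-control status, all genotyped samples:
#: {snp: [(cases, controls) for dosage 0,1,2]}.
TABLE3_ALL = {
    "rs2282679": [(216, 218), (1130, 1160), (1325, 1400)],
    "rs12785878": [(81, 112), (749, 798), (1667, 1713)],
    "rs10741657": [(851, 855), (1082, 1201), (402, 371)],
    "rs6013897": [(92, 83), (739, 806), (1615, 1648)],
}

#: As TABLE3_ALL, restricted to subjects with 25-OHD < 10 ng/ml.
TABLE3_DEFICIENT = {
    "rs2282679": [(66, 67), (392, 306), (399, 368)],
    "rs12785878": [(32, 40), (249, 221), (526, 454)],
    "rs10741657": [(296, 216), (346, 339), (113, 98)],
    "rs6013897": [(23, 24), (237, 233), (531, 437)],
}

#: As TABLE3_ALL, restricted to subjects with 25-OHD >= 10 ng/ml.
TABLE3_SUFFICIENT = {
    "rs2282679": [(69, 96), (380, 525), (487, 676)],
    "rs12785878": [(23, 43), (246, 374), (584, 782)],
    "rs10741657": [(271, 401), (383, 542), (148, 170)],
    "rs6013897": [(35, 37), (249, 350), (545, 774)],
}

#: First-stage F statistics printed for the age+sex-adjusted IV analyses.
PUBLISHED_FIRST_STAGE_F = {
    "rs2282679": 15.80,
    "rs12785878": 13.50,
    "rs10741657": 10.89,
    "rs6013897": 0.98,
    "overall": 16.52,
    "upstream": 7.87,
    "downstream": 12.67,
}


def genotype_totals(table: dict[str, list[tuple[int, int]]], snp: str) -> tuple[int, int, int]:
    """Collapse a (cases, controls)-by-dosage table to genotype totals.

    Returns totals for dosage 0, 1, 2 — a (hom, het, hom) triple as the HWE
    test expects (the chi-square is symmetric under allele relabelling, so
    which homozygote comes first is immaterial).
    """
    rows = table[snp]
    return tuple(cases + controls for cases, controls in rows)
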