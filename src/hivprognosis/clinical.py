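"""Deterministic clinical transforms: eGFR, BMI, FIB-4 and the banding flags
consumed by the score engines.

All functions are pure.  Units follow the cohort schema: creatinine in
umol/L (converted internally to mg/dL), haemoglobin in g/dL, CD4 in
cells/mm3, platelets in 10^3/uL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from hivprognosis.cohort import BaselineCovariates

#: umol/L per mg/dL for creatinine.
CREATININE_UMOL_PER_MGDL = 88.4

#: Sex-specific haemoglobin thresholds (g/dL) defining anaemia.
ANAEMIA_THRESHOLD = {"male": 13.0, "female": 12.0}

LOW_BMI_THRESHOLD = 18.5  # kg/m^2
RNA_SUPPRESSION_THRESHOLD = 50.0  # copies/mL

#: Half-open-left CD4 bands (cells/mm3), lowest risk last.
CD4_BANDS = ((0.0, 200.0), (200.0, 350.0), (350.0, 500.0), (500.0, math.inf))
CD4_BAND_LABELS = ("<200", "200-350", "350-500", ">500")

#: eGFR bands (mL/min/1.73m^2) used by the points tables.
EGFR_BANDS = ((0.0, 30.0), (30.0, 60.0), (60.0, math.inf))
EGFR_BAND_LABELS = ("<30", "30-59", ">=60")

AGE_BANDS = ((0.0, 65.0), (65.0, 75.0), (75.0, math.inf))
AGE_BAND_LABELS = ("<65", "65-74", ">=75")


@dataclass
class DerivedCovariates:
    """Derived quantities feeding the score engines; None marks a missing input."""

    egfr: float | None = None
    bmi: float | None = None
    fib4: float | None = None
    anemia: bool | None = None
    low_bmi: bool | None = None
    age_band: str | None = None
    cd4_band: str | None = None
    egfr_band: str | None = None
    rna_suppressed: bool | None = None


def ckd_epi_egfr(
    creatinine_umol_l: float,
    sex: Literal["male", "female"],
    age_years: float,
    black: bool = False,
) -> float:
    """Estimated GFR (mL/min/1.73m^2) from the 2009 CKD-EPI creatinine equation.

    The race coefficient is off by default (``black=False``): the cohorts this
    package targets do not record race.  Creatinine is converted from umol/L
    to mg/dL before the piecewise power form is applied.

    References: Levey et al., Ann Intern Med 2009;150:604-612.
    """
    if creatinine_umol_l <= 0:
        raise ValueError("creatinine must be positive")
    scr = creatinine_umol_l / CREATININE_UMOL_PER_MGDL
    if sex == "female":
        kappa, alpha, sex_mult = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_mult = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    egfr = (
        141.0
        * min(scr / kappa, 1.0) ** alpha
        * max(scr / kappa, 1.0) ** -1.209
        * 0.993 ** age_years
        * sex_mult
    )
    if black:
        egfr *= 1.159
    return egfr


def body_mass_index(weight_kg: float, height_m: float) -> float:
    """BMI = weight (kg) / height^2 (m^2)."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


def fib4(age_years: float, ast_u_l: float, alt_u_l: float, platelets_1e3_ul: float) -> float:
    """FIB-4 liver-fibrosis index: age x AST / (platelets x sqrt(ALT)).

    AST/ALT in U/L (== IU/L), platelets in 10^3/uL.
    """
    if min(age_years, ast_u_l, alt_u_l, platelets_1e3_ul) <= 0:
        raise ValueError("all FIB-4 inputs must be positive")
    return age_years * ast_u_l / (platelets_1e3_ul * math.sqrt(alt_u_l))


def _band(value: float, bands, labels) -> str:
    for (lo, hi), label in zip(bands, labels):
        if lo <= value < hi:
            return label
    raise ValueError(f"value {value} outside banded domain")


def cd4_band(cd4: float) -> str:
    """CD4 band with half-open-left boundaries: [0,200), [200,350), [350,500), [500,inf)."""
    return _band(cd4, CD4_BANDS, CD4_BAND_LABELS)


def egfr_band(egfr: float) -> str:
    return _band(egfr, EGFR_BANDS, EGFR_BAND_LABELS)


def age_band(age: float) -> str:
    return _band(age, AGE_BANDS, AGE_BAND_LABELS)


def derive_flags(
    hemoglobin: float | None,
    sex: Literal["male", "female"],
    bmi: float | None,
    cd4: float | None,
    rna: float | None,
) -> tuple[bool | None, bool | None, str | None, bool | None]:
    """(anemia, low_bmi, cd4_band, rna_suppressed); missing inputs give None flags.

    Anaemia: haemoglobin <13 g/dL (male) / <12 g/dL (female).
    Low BMI: <18.5 kg/m^2.  Suppression: HIV-1 RNA <=50 copies/mL.
    """
    anemia = None if hemoglobin is None else hemoglobin < ANAEMIA_THRESHOLD[sex]
    low = None if bmi is None else bmi < LOW_BMI_THRESHOLD
    band = None if cd4 is None else cd4_band(cd4)
    suppressed = None if rna is None else rna <= RNA_SUPPRESSION_THRESHOLD
    return anemia, low, band, suppressed


def derive_covariates(cov: BaselineCovariates) -> DerivedCovariates:
    """All derived quantities for one participant's baseline covariates."""
    d = DerivedCovariates(age_band=age_band(cov.age))
    creat = cov.get("creatinine")
    if creat is not None:
        d.egfr = ckd_epi_egfr(creat, cov.sex, cov.age)
        d.egfr_band = egfr_band(d.egfr)
    weight, height = cov.get("weight"), cov.get("height")
    if weight is not None and height is not None:
        d.bmi = body_mass_index(weight, height)
        cov.bmi = d.bmi
    ast_v, alt_v, plt = cov.get("ast"), cov.get("alt"), cov.get("platelets")
    if None not in (ast_v, alt_v, plt):
        d.fib4 = fib4(cov.age, ast_v, alt_v, plt)
    d.anemia, d.low_bmi, d.cd4_band, d.rna_suppressed = derive_flags(
        cov.get("hemoglobin"), cov.sex, d.bmi, cov.get("cd4"), cov.get("hiv_rna")
    )
    return d
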