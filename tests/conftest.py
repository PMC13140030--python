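"""Shared fixtures: covariate factories and small random survival datasets."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from hivprognosis.cohort import BaselineCovariates, ResolvedValue
from hivprognosis.validation import SurvivalDataset

ENTRY = date(2015, 6, 1)


def make_covariates(
    sex: str = "male",
    age: float = 72.0,
    *,
    cd4: float | None = 600.0,
    creatinine: float | None = 70.0,
    hemoglobin: float | None = 15.0,
    weight: float | None = 75.0,
    height: float | None = 1.75,
    hiv_rna: float | None = 20.0,
    ast: float | None = 25.0,
    alt: float | None = 25.0,
    platelets: float | None = 200.0,
    wbc: float | None = 6.0,
    albumin: float | None = 42.0,
    cd4_nadir: float | None = 200.0,
    **flags,
) -> BaselineCovariates:
    """A baseline-covariate record whose defaults land in every zero-point category."""
    cov = BaselineCovariates(
        participant_id="T", sex=sex, age=age,
        non_hiv_cancer=flags.get("non_hiv_cancer", False),
        cvd=flags.get("cvd", False),
        cirrhosis=flags.get("cirrhosis", False),
        aids=flags.get("aids", False),
        hbv=flags.get("hbv", False),
        hcv=flags.get("hcv", False),
    )
    values = dict(cd4=cd4, creatinine=creatinine, hemoglobin=hemoglobin,
                  weight=weight, height=height, hiv_rna=hiv_rna, ast=ast, alt=alt,
                  platelets=platelets, wbc=wbc, albumin=albumin, cd4_nadir=cd4_nadir)
    for analyte, v in values.items():
        if v is not None:
            cov.values[analyte] = ResolvedValue(float(v), ENTRY, "after")
    return cov


@pytest.fixture
def cov_factory():
    return make_covariates


def random_survival_dataset(rng: np.random.Generator, n: int) -> SurvivalDataset:
    """Small dataset with mixed censoring and integer markers (marker ties likely)."""
    time = rng.exponential(3.0, n) + 0.01
    event = (rng.random(n) < 0.6).astype(int)
    marker = rng.integers(0, 8, n).astype(float)
    return SurvivalDataset(time, event, marker)


@pytest.fixture
def rng():
    return np.random.default_rng(20250101)
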