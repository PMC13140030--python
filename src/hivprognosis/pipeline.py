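"""End-to-end orchestration: screen, resolve baselines, score, and build the
per-subject analysis table every validation statistic consumes."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from hivprognosis.clinical import derive_covariates
from hivprognosis.cohort import (
    MeasurementSeries,
    ParticipantRecord,
    assemble_baseline,
    compute_followup,
    screen_eligibility,
)
from hivprognosis.scores import (
    ScoreDefinition,
    compute_score,
    feature_map,
    impute_normal_values,
    load_score_definition,
)
from hivprognosis.validation import SurvivalDataset

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-table style), e.g. 0.25 -> 0.3 at 1 digit."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: Subgroup labellings used for discrimination: name -> (feature, threshold, op)
SUBGROUP_DEFS = {
    "sex": None,  # categorical, taken directly
    "cd4_lt_350": ("cd4", 350.0),
    "cd4_nadir_lt_200": ("cd4_nadir", 200.0),
    "cd4_lt_median": ("cd4", "median"),
    "rna_lt_200": ("hiv_rna", 200.0),
}


@dataclass
class ScoreSpec:
    """One score run: a label, a definition, and whether normal-value
    imputation (albumin/ALT/AST) is applied first."""

    label: str
    definition: ScoreDefinition
    impute: bool = False


@dataclass
class AnalysisResult:
    """Flow accounting plus the per-subject analysis table.

    ``table`` has one row per included participant: follow-up time/event,
    each score's total / computability / risk group / prediction, and the
    subgroup labels.
    """

    table: pd.DataFrame
    flow: dict[str, int | float]
    score_specs: list[ScoreSpec] = field(default_factory=list)

    def survival_dataset(self, marker_column: str, require_computable: str | None = None) -> SurvivalDataset:
        """A SurvivalDataset using ``marker_column`` as the risk marker.

        ``require_computable`` restricts to rows where that score label is
        computable (defaults to the marker's own score when the column is a
        score total or group).
        """
        df = self.table
        if require_computable is not None:
            df = df[df[f"{require_computable}_computable"]]
        df = df[df[marker_column].notna()]
        subgroups = {
            name: df[f"subgroup_{name}"].to_numpy()
            for name in SUBGROUP_DEFS
            if f"subgroup_{name}" in df.columns
        }
        return SurvivalDataset(
            df["time"].to_numpy(float), df["event"].to_numpy(int),
            df[marker_column].to_numpy(), subgroups,
        )


def default_score_specs(which: Sequence[str] = ("dataids", "vacs1", "vacs2", "vacs2_imputed")) -> list[ScoreSpec]:
    defs = {name: load_score_definition(name) for name in {w.removesuffix("_imputed") for w in which}}
    specs = []
    for w in which:
        base = w.removesuffix("_imputed")
        specs.append(ScoreSpec(w, defs[base], impute=w.endswith("_imputed")))
    return specs


def build_analysis_table(
    participants: Sequence[ParticipantRecord],
    measurements: Sequence[MeasurementSeries],
    study_end: date,
    score_specs: Sequence[ScoreSpec] | None = None,
    horizon_years: float = 5.0,
    window_months: float = 12.0,
    bmi_mode: Literal["windowed", "unrestricted"] = "windowed",
) -> AnalysisResult:
    """Screen eligibility, truncate follow-up, resolve baselines and score everyone."""
    if score_specs is None:
        score_specs = default_score_specs()
    by_pid: dict[str, list[MeasurementSeries]] = {}
    for s in measurements:
        by_pid.setdefault(s.participant_id, []).append(s)

    n_screened = len(participants)
    excluded: dict[str, int] = {}
    rows = []
    for p in participants:
        elig = screen_eligibility(p, by_pid.get(p.participant_id, []), window_months)
        if not elig.included:
            excluded[elig.reason] = excluded.get(elig.reason, 0) + 1
            continue
        time, event = compute_followup(p, study_end, horizon_years)
        cov = assemble_baseline(p, by_pid.get(p.participant_id, []), window_months, bmi_mode)
        row: dict = {"participant_id": p.participant_id, "time": time, "event": event,
                     "sex": cov.sex, "age": cov.age,
                     "cd4": cov.get("cd4"), "cd4_nadir": cov.get("cd4_nadir"),
                     "hiv_rna": cov.get("hiv_rna")}
        for spec in score_specs:
            c = impute_normal_values(cov) if spec.impute else cov
            res = compute_score(feature_map(c, derive_covariates(c)), spec.definition)
            row[f"{spec.label}_total"] = res.total
            row[f"{spec.label}_computable"] = res.computable
            row[f"{spec.label}_group"] = res.risk_group
            row[f"{spec.label}_pred5y"] = res.predicted_survival_5y
        rows.append(row)

    table = pd.DataFrame(rows)
    n_included = len(table)
    if n_included:
        cd4_median = float(table["cd4"].median())
        table["subgroup_sex"] = table["sex"]
        table["subgroup_cd4_lt_350"] = np.where(table["cd4"] < 350, "cd4<350", "cd4>=350")
        table["subgroup_cd4_nadir_lt_200"] = np.where(
            table["cd4_nadir"].isna(), "unknown",
            np.where(table["cd4_nadir"] < 200, "nadir<200", "nadir>=200"))
        table["subgroup_cd4_lt_median"] = np.where(
            table["cd4"] < cd4_median, "cd4<median", "cd4>=median")
        table["subgroup_rna_lt_200"] = np.where(
            table["hiv_rna"].isna(), "unknown",
            np.where(table["hiv_rna"] < 200, "rna<200", "rna>=200"))
    flow = {
        "n_screened": n_screened,
        "n_included": n_included,
        "included_pct": round_half_up(100.0 * n_included / n_screened, 1) if n_screened else 0.0,
        **{f"excluded_{k}": v for k, v in sorted(excluded.items())},
    }
    return AnalysisResult(table, flow, list(score_specs))


def score_cohort(
    participants: Sequence[ParticipantRecord],
    measurements: Sequence[MeasurementSeries],
    study_end: date,
    **kwargs,
) -> pd.DataFrame:
    """Thin wrapper: the per-subject score table from :func:`build_analysis_table`."""
    return build_analysis_table(participants, measurements, study_end, **kwargs).table
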