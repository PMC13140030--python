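"""Score engines: evaluate points-based prognostic scores from baseline covariates.

Three definitions ship as YAML assets: the Dat'AIDS score (categorical
points, four risk groups with 5-year survival predictions), the VACS 1.0
index (categorical points) and a VACS 2.0 stand-in (continuous).  A
definition is a list of components, each mapping one covariate to points
via half-open intervals, a boolean indicator, or a piecewise-linear
function; the total is the sum over components.  Missing covariates make
the score non-computable unless the normal-value imputation policy fills
them first.
"""

from __future__ import annotations

import dataclasses
import math
from datetime import date
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping, Sequence

import yaml

from hivprognosis.clinical import DerivedCovariates, derive_covariates
from hivprognosis.cohort import BaselineCovariates, ResolvedValue

#: Normal values used by the missing-data imputation policy.
#: Albumin is stored in g/L in the cohort schema: 4 g/dL == 40 g/L.
NORMAL_VALUES = {"albumin": 40.0, "alt": 25.0, "ast": 20.0}

_ASSET_FILES = {
    "dataids": "dataids_score_synthetic.yaml",
    "vacs1": "vacs1_index.yaml",
    "vacs2": "vacs2_index_synthetic.yaml",
}


class ScoreDefinitionError(ValueError):
    """Raised when a score asset fails schema validation."""


@dataclass(frozen=True)
class Component:
    covariate: str
    type: Literal["interval", "boolean", "piecewise_linear"]
    intervals: tuple[tuple[float, float, float], ...] = ()  # (min, max, points)
    points_if_true: float = 0.0
    knots: tuple[tuple[float, float], ...] = ()
    log10_x: bool = False

    def evaluate(self, value: Any) -> float:
        if self.type == "boolean":
            return self.points_if_true if value else 0.0
        x = float(value)
        if self.type == "interval":
            for lo, hi, pts in self.intervals:
                if lo <= x < hi:
                    return pts
            raise ScoreDefinitionError(
                f"component {self.covariate!r}: value {x} outside definition domain"
            )
        # piecewise linear, clamped to the knot range
        if self.log10_x:
            x = math.log10(x)
        xs = [k[0] for k in self.knots]
        ys = [k[1] for k in self.knots]
        if x <= xs[0]:
            return ys[0]
        if x >= xs[-1]:
            return ys[-1]
        for (x0, y0), (x1, y1) in zip(self.knots, self.knots[1:]):
            if x0 <= x <= x1:
                return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        raise AssertionError("unreachable")

    @property
    def max_points(self) -> float:
        if self.type == "boolean":
            return max(self.points_if_true, 0.0)
        if self.type == "interval":
            return max(p for _, _, p in self.intervals)
        return max(y for _, y in self.knots)


@dataclass(frozen=True)
class RiskGroup:
    name: str
    min_score: float
    max_score: float  # inclusive upper bound; inf for the top group
    predicted_survival_5y: float


@dataclass(frozen=True)
class ScoreDefinition:
    """A validated points table with optional risk grouping and continuous prediction."""

    name: str
    kind: Literal["categorical_points", "continuous"]
    components: tuple[Component, ...]
    risk_groups: tuple[RiskGroup, ...] | None = None
    offset: float = 0.0
    #: optional (baseline 5-year survival, log-hazard per point) from a derivation study
    continuous_prediction: tuple[float, float] | None = None

    @property
    def max_total(self) -> float:
        return self.offset + sum(c.max_points for c in self.components)

    def required_covariates(self) -> tuple[str, ...]:
        return tuple(c.covariate for c in self.components)


@dataclass
class ScoreResult:
    score_name: str
    total: float | None
    breakdown: dict[str, float] = field(default_factory=dict)
    missing_components: list[str] = field(default_factory=list)
    computable: bool = True
    risk_group: str | None = None
    predicted_survival_5y: float | None = None


# ---------------------------------------------------------------------------
# Asset loading / validation


def _validate_intervals(cov: str, intervals: Sequence[tuple[float, float, float]]) -> None:
    ordered = sorted(intervals)
    if ordered[0][0] != 0.0 and ordered[0][0] > -math.inf:
        pass  # domains start at the stated minimum (age bands start at 0)
    for (lo, hi, _), (lo2, _hi2, _) in zip(ordered, ordered[1:]):
        if hi != lo2:
            raise ScoreDefinitionError(
                f"component {cov!r}: intervals do not tile the domain ({hi} != {lo2})"
            )
        if lo >= hi:
            raise ScoreDefinitionError(f"component {cov!r}: empty interval [{lo}, {hi})")
    if not math.isinf(ordered[-1][1]):
        raise ScoreDefinitionError(f"component {cov!r}: top interval must be unbounded")


def _parse_definition(raw: Mapping[str, Any], source: str) -> ScoreDefinition:
    try:
        components = []
        for c in raw["components"]:
            ctype = c["type"]
            if ctype == "interval":
                ivs = tuple(
                    (float(i["min"]), float(i["max"]), float(i["points"]))
                    for i in c["intervals"]
                )
                _validate_intervals(c["covariate"], ivs)
                comp = Component(c["covariate"], "interval", intervals=tuple(sorted(ivs)))
            elif ctype == "boolean":
                comp = Component(c["covariate"], "boolean", points_if_true=float(c["points_if_true"]))
            elif ctype == "piecewise_linear":
                knots = tuple((float(x), float(y)) for x, y in c["knots"])
                if any(a[0] >= b[0] for a, b in zip(knots, knots[1:])):
                    raise ScoreDefinitionError(
                        f"component {c['covariate']!r}: knot x-values must increase"
                    )
                comp = Component(c["covariate"], "piecewise_linear", knots=knots,
                                 log10_x=bool(c.get("log10_x", False)))
            else:
                raise ScoreDefinitionError(f"unknown component type {ctype!r}")
            if comp.max_points < 0:
                raise ScoreDefinitionError(f"component {comp.covariate!r}: negative points")
            components.append(comp)
        groups = None
        if raw.get("risk_groups"):
            groups = tuple(
                RiskGroup(g["name"], float(g["min_score"]), float(g["max_score"]),
                          float(g["predicted_survival_5y"]))
                for g in raw["risk_groups"]
            )
            bounds = [g.min_score for g in groups]
            if bounds != sorted(bounds):
                raise ScoreDefinitionError("risk-group cut-points must increase")
            for g in groups:
                if not 0.0 < g.predicted_survival_5y <= 1.0:
                    raise ScoreDefinitionError(f"group {g.name!r}: survival outside (0, 1]")
            surv = [g.predicted_survival_5y for g in groups]
            if surv != sorted(surv, reverse=True):
                raise ScoreDefinitionError("predicted survival must be non-increasing across groups")
        cont = None
        if raw.get("continuous"):
            cont = (float(raw["continuous"]["s0_5y"]), float(raw["continuous"]["coefficient"]))
        return ScoreDefinition(
            name=raw["name"],
            kind=raw["kind"],
            components=tuple(components),
            risk_groups=groups,
            offset=float(raw.get("offset", 0.0)),
            continuous_prediction=cont,
        )
    except (KeyError, TypeError) as exc:
        raise ScoreDefinitionError(f"{source}: malformed score asset: {exc}") from exc


def load_score_definition(name_or_path: str | Path) -> ScoreDefinition:
    """Load a packaged definition by name ('dataids', 'vacs1', 'vacs2') or a YAML path."""
    key = str(name_or_path)
    if key in _ASSET_FILES:
        text = resources.files("hivprognosis.assets").joinpath(_ASSET_FILES[key]).read_text()
        source = _ASSET_FILES[key]
    else:
        text = Path(name_or_path).read_text()
        source = str(name_or_path)
    return _parse_definition(yaml.safe_load(text), source)


# ---------------------------------------------------------------------------
# Feature extraction and evaluation


def feature_map(cov: BaselineCovariates, derived: DerivedCovariates | None = None) -> dict[str, Any]:
    """Flatten baseline + derived covariates into the namespace score assets use.

    Albumin is converted g/L -> g/dL here (``albumin_gdl``); boolean flags
    may be None (unknown), which counts as missing for scoring.
    """
    if derived is None:
        derived = derive_covariates(cov)
    albumin = cov.get("albumin")
    return {
        "age": cov.age,
        "cd4": cov.get("cd4"),
        "cd4_nadir": cov.get("cd4_nadir"),
        "hiv_rna": cov.get("hiv_rna"),
        "hemoglobin": cov.get("hemoglobin"),
        "ast": cov.get("ast"),
        "alt": cov.get("alt"),
        "platelets": cov.get("platelets"),
        "wbc": cov.get("wbc"),
        "albumin_gdl": None if albumin is None else albumin / 10.0,
        "egfr": derived.egfr,
        "fib4": derived.fib4,
        "bmi": derived.bmi,
        "anemia": derived.anemia,
        "low_bmi": derived.low_bmi,
        "non_hiv_cancer": cov.non_hiv_cancer,
        "cvd": cov.cvd,
        "cirrhosis": cov.cirrhosis,
        "aids": cov.aids,
        "hcv": cov.hcv,
        "hbv": cov.hbv,
    }


def compute_score(
    features: Mapping[str, Any] | BaselineCovariates,
    definition: ScoreDefinition,
) -> ScoreResult:
    """Evaluate one score; a result with ``computable=False`` lists what was missing."""
    if isinstance(features, BaselineCovariates):
        features = feature_map(features)
    result = ScoreResult(score_name=definition.name, total=None)
    total = definition.offset
    for comp in definition.components:
        value = features.get(comp.covariate)
        if value is None:
            result.missing_components.append(comp.covariate)
            continue
        pts = comp.evaluate(value)
        result.breakdown[comp.covariate] = pts
        total += pts
    result.computable = not result.missing_components
    if result.computable:
        result.total = total if definition.kind == "continuous" else int(round(total))
        if definition.risk_groups:
            result.risk_group, result.predicted_survival_5y = assign_risk_group(
                result.total, definition
            )
    return result


def assign_risk_group(total: float, definition: ScoreDefinition) -> tuple[str, float]:
    """Map a total score to (risk group, group-level predicted 5-year survival)."""
    if total < 0:
        raise ValueError("total score must be non-negative")
    if not definition.risk_groups:
        raise ValueError(f"score {definition.name!r} defines no risk groups")
    for g in definition.risk_groups:
        if g.min_score <= total <= g.max_score:
            return g.name, g.predicted_survival_5y
    raise AssertionError("risk groups do not cover the score range")


def predicted_survival_curve(
    definition: ScoreDefinition,
    t_years: float,
    total: float | None = None,
    group: str | None = None,
) -> float:
    """Predicted survival probability at ``t_years`` (0 < t <= 5).

    With a derivation continuous-prediction asset present and a total score:
    S(t) = S0(t)^exp(coef * total), with S0 bridged from its 5-year value at
    constant hazard.  Otherwise the group-level mapping is bridged the same
    way: S_g(t) = S_g(5)^(t/5).
    """
    if t_years <= 0:
        raise ValueError("t must be positive")
    if definition.continuous_prediction is not None and total is not None:
        s0_5, coef = definition.continuous_prediction
        s0_t = s0_5 ** (t_years / 5.0)
        return s0_t ** math.exp(coef * total)
    if group is None:
        if total is None:
            raise ValueError("need a total score or a risk group")
        group, _ = assign_risk_group(total, definition)
    for g in definition.risk_groups or ():
        if g.name == group:
            return g.predicted_survival_5y ** (t_years / 5.0)
    raise ValueError(f"unknown risk group {group!r}")


def compute_dataids(cov: BaselineCovariates | Mapping[str, Any]) -> ScoreResult:
    """Dat'AIDS score from the packaged definition."""
    return compute_score(cov, load_score_definition("dataids"))


def compute_vacs1(cov: BaselineCovariates | Mapping[str, Any]) -> ScoreResult:
    """VACS 1.0 index from the packaged definition."""
    return compute_score(cov, load_score_definition("vacs1"))


def compute_vacs2(
    cov: BaselineCovariates, imputation: Literal["none", "normal-values"] = "none"
) -> ScoreResult:
    """VACS 2.0 index; ``normal-values`` fills missing albumin/ALT/AST first."""
    if imputation == "normal-values":
        cov = impute_normal_values(cov)
    elif imputation != "none":
        raise ValueError(f"unknown imputation policy {imputation!r}")
    return compute_score(cov, load_score_definition("vacs2"))


def predicted_hazard_parts(
    definition: ScoreDefinition,
    totals,
    times,
    horizon_years: float = 5.0,
):
    """Per-subject (prognostic index, baseline cumulative hazard at exit).

    These are the two pieces of the predicted cumulative hazard
    H_i = H0(t_i) * exp(PI_i) the Poisson calibration model consumes.  With a
    derivation continuous-prediction asset, PI = coef * total and
    H0(t) = -ln(S0(5)) * t/5 (constant-hazard bridge of the baseline).
    Otherwise the group-level mapping supplies the whole horizon hazard:
    PI = ln(-ln S_group(5)) and H0(t) = t/5.
    """
    import numpy as np

    totals = np.asarray(totals, dtype=float)
    times = np.asarray(times, dtype=float)
    if definition.continuous_prediction is not None:
        s0_5, coef = definition.continuous_prediction
        pi = coef * totals
        h0 = -math.log(s0_5) * times / horizon_years
    else:
        s5 = np.array([assign_risk_group(t, definition)[1] for t in totals])
        pi = np.log(-np.log(s5))
        h0 = times / horizon_years
    return pi, h0


# ---------------------------------------------------------------------------
# Imputation policy and completeness accounting


def impute_normal_values(cov: BaselineCovariates) -> BaselineCovariates:
    """Return a copy with missing albumin/ALT/AST set to their normal values.

    Albumin -> 40 g/L (4 g/dL), ALT -> 25 U/L, AST -> 20 U/L; everything else
    untouched; imputed values carry a provenance flag.  Idempotent.
    """
    out = dataclasses.replace(cov)
    out.values = dict(cov.values)
    for analyte, normal in NORMAL_VALUES.items():
        if analyte not in out.values:
            out.values[analyte] = ResolvedValue(
                value=normal, source_date=date.min, side="none", imputed=True,
            )
    return out


def completeness_table(
    score_results: Mapping[str, Sequence[ScoreResult]],
) -> "pd.DataFrame":
    """Per-score and pairwise common-complete counts over one cohort.

    ``score_results`` maps a label (e.g. ``"dataids"`` or
    ``"vacs2+imputed"``) to the per-subject results, all in the same subject
    order.  Rows cover each single score and each pair.
    """
    import itertools

    import pandas as pd

    labels = list(score_results)
    n = {lab: len(rs) for lab, rs in score_results.items()}
    if len(set(n.values())) > 1:
        raise ValueError("score result lists must cover the same subjects")
    total = next(iter(n.values()))
    masks = {lab: [r.computable for r in rs] for lab, rs in score_results.items()}
    rows = []
    for lab in labels:
        k = sum(masks[lab])
        rows.append({"scores": lab, "n_computable": k, "fraction": k / total if total else 0.0})
    for a, b in itertools.combinations(labels, 2):
        k = sum(x and y for x, y in zip(masks[a], masks[b]))
        rows.append({"scores": f"{a} & {b}", "n_computable": k,
                     "fraction": k / total if total else 0.0})
    return pd.DataFrame(rows)
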