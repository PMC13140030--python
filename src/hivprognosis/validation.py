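"""Validation statistics for prognostic scores under right-censoring.

Implements the external-validation toolkit: Kaplan-Meier observed survival,
person-time mortality rates, Harrell's concordance statistic (whole-cohort
and by subgroup, with a jackknife CI), Cox proportional-hazards contrasts
across predefined risk groups, calibration intercept/slope via the Poisson
regression representation of a Cox model, group-level predicted-vs-observed
survival, and head-to-head score comparison on common complete cases.

Conventions: markers are oriented toward mortality (higher marker = higher
risk), so a concordant pair is one where the higher-marker subject dies
first.  A pair is comparable when the two follow-up times differ and the
shorter time ends in death.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)

MIN_FOLLOWUP_YEARS = 0.5 / 365.25  # same-day exits shifted to half a day


@dataclass
class SurvivalDataset:
    """Per-subject follow-up time (years), death indicator, risk marker and
    optional subgroup labels."""

    time: np.ndarray
    event: np.ndarray
    marker: np.ndarray
    subgroups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.marker = np.asarray(self.marker)
        if self.time.shape != self.event.shape or self.time.shape != self.marker.shape:
            raise ValueError("time, event and marker must have equal length")
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be non-negative")
        if np.any(self.time == 0):
            logger.info("shifting %d zero follow-up times to half a day", int((self.time == 0).sum()))
            self.time = np.where(self.time == 0, MIN_FOLLOWUP_YEARS, self.time)
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be 0/1")
        for name, lab in self.subgroups.items():
            if len(lab) != len(self.time):
                raise ValueError(f"subgroup {name!r} has wrong length")

    def __len__(self) -> int:
        return len(self.time)

    def restrict(self, mask: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            self.time[mask], self.event[mask], self.marker[mask],
            {k: np.asarray(v)[mask] for k, v in self.subgroups.items()},
        )


# ---------------------------------------------------------------------------
# Kaplan-Meier and person-time


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log(-log) 95% CI."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    _kmf: KaplanMeierFitter | None = None

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimate at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])


def kaplan_meier(ds: SurvivalDataset) -> KMCurve:
    """Kaplan-Meier curve over the dataset's event times.

    Survival and the log(-log)-transformed CI come from lifelines; the
    Greenwood variance is accumulated from the event table.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    kmf = KaplanMeierFitter()
    kmf.fit(ds.time, ds.event)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    times = observed.index.to_numpy(dtype=float)
    d = observed["observed"].to_numpy(dtype=float)
    n = observed["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    greenwood_terms = np.cumsum(d / (n * (n - d)))
    variance = surv**2 * greenwood_terms
    ci = kmf.confidence_interval_survival_function_
    lo = ci.iloc[:, 0].loc[times].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].loc[times].to_numpy(dtype=float)
    return KMCurve(times, n, d, surv, variance, lo, hi, _kmf=kmf)


def person_time_rate(ds: SurvivalDataset) -> tuple[float, int, float]:
    """(total person-years, deaths, death rate per 100 person-years).

    The rate is rounded to 2 decimals for reporting.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    py = float(ds.time.sum())
    if py <= 0:
        raise ValueError("zero person-time")
    deaths = int(ds.event.sum())
    return py, deaths, round(100.0 * deaths / py, 2)


# ---------------------------------------------------------------------------
# Harrell's C


@dataclass
class ConcordanceResult:
    c: float
    comparable: int
    concordant: int
    discordant: int
    tied_marker: int
    se: float
    ci: tuple[float, float]


def _pair_matrices(time: np.ndarray, event: np.ndarray, marker: np.ndarray):
    """Boolean pair matrices for comparability / concordance (mortality orientation)."""
    t_i = time[:, None]
    t_j = time[None, :]
    d_i = event.astype(bool)[:, None]
    m_i = marker[:, None].astype(float)
    m_j = marker[None, :].astype(float)
    earlier = (t_i < t_j) & d_i  # subject i dies strictly first, observed
    concordant = earlier & (m_i > m_j)
    discordant = earlier & (m_i < m_j)
    tied = earlier & (m_i == m_j)
    return earlier, concordant, discordant, tied


def harrells_c(ds: SurvivalDataset, alpha: float = 0.05) -> ConcordanceResult:
    """Harrell's C for a mortality-oriented marker, with a jackknife CI.

    C = (#concordant + 0.5 #marker-ties) / #comparable over pairs where the
    shorter follow-up ends in death.  The standard error is the
    leave-one-subject-out jackknife; the interval is normal-theory, clipped
    to [0, 1].
    """
    if len(ds) < 2:
        raise ValueError("need at least two subjects")
    if ds.event.sum() < 1:
        raise ValueError("need at least one event")
    comp, conc, disc, tied = _pair_matrices(ds.time, ds.event, ds.marker)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    n_conc = int(conc.sum())
    n_disc = int(disc.sum())
    n_tied = int(tied.sum())
    num = n_conc + 0.5 * n_tied
    c = num / n_comp
    # leave-one-out totals from per-subject row+column pair sums
    num_k = (conc.sum(0) + conc.sum(1) + 0.5 * (tied.sum(0) + tied.sum(1))).astype(float)
    den_k = (comp.sum(0) + comp.sum(1)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (num - num_k) / (n_comp - den_k)
    c_loo = np.where(np.isfinite(c_loo), c_loo, c)
    n = len(ds)
    se = math.sqrt((n - 1) / n * float(((c_loo - c_loo.mean()) ** 2).sum()))
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    ci = (max(0.0, c - z * se), min(1.0, c + z * se))
    return ConcordanceResult(c, n_comp, n_conc, n_disc, n_tied, se, ci)


def subgroup_discrimination(
    ds: SurvivalDataset, subgroup_names: Sequence[str] | None = None, min_events: int = 5
) -> pd.DataFrame:
    """Harrell's C within each level of each subgroup labelling.

    Levels with fewer than ``min_events`` events are skipped with a warning.
    Returns a tidy table (subgroup, level, n, events, c, ci_lower, ci_upper).
    """
    names = list(subgroup_names) if subgroup_names is not None else list(ds.subgroups)
    rows = [_c_row("overall", "all", ds)]
    for name in names:
        labels = np.asarray(ds.subgroups[name])
        for level in pd.unique(labels):
            sub = ds.restrict(labels == level)
            if len(sub) < 2 or sub.event.sum() < min_events:
                warnings.warn(f"subgroup {name}={level}: too few events, skipped", stacklevel=2)
                continue
            rows.append(_c_row(name, level, sub))
    return pd.DataFrame(rows)


def _c_row(name: str, level, sub: SurvivalDataset) -> dict:
    res = harrells_c(sub)
    return {
        "subgroup": name, "level": str(level), "n": len(sub),
        "events": int(sub.event.sum()), "c": res.c,
        "ci_lower": res.ci[0], "ci_upper": res.ci[1],
    }


# ---------------------------------------------------------------------------
# Cox PH across risk groups


@dataclass
class CoxFit:
    """Risk-group contrasts from a Cox PH fit (Efron ties, Wald CIs)."""

    reference: str
    summary: pd.DataFrame  # index: group; columns coef, se, hr, hr_ci_lower, hr_ci_upper, unstable
    log_likelihood: float
    model: CoxPHFitter


def cox_risk_groups(
    ds: SurvivalDataset, group_order: Sequence[str] | None = None
) -> CoxFit:
    """Hazard ratios between predefined risk groups, lowest group as reference.

    Groups are entered as indicator covariates in a Cox proportional-hazards
    model (partial likelihood, Efron tie correction, Newton solver).  A
    non-reference group with no events yields a monotone likelihood; its
    coefficient is flagged unstable.
    """
    groups = np.asarray(ds.marker, dtype=object).astype(str)
    order = [str(g) for g in (group_order or list(pd.unique(groups)))]
    if len(order) < 2:
        raise ValueError("need at least two risk groups")
    present = [g for g in order if (groups == g).any()]
    reference = present[0]
    events_by_group = {g: int(ds.event[groups == g].sum()) for g in present}
    if ds.event.sum() < 1:
        raise ValueError("need at least one event")
    df = pd.DataFrame({"time": ds.time, "event": ds.event})
    for g in present[1:]:
        df[f"grp_{g}"] = (groups == g).astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    def _exp(x: float) -> float:
        if x > 700:
            return math.inf
        if x < -700:
            return 0.0
        return math.exp(x)

    rows = []
    for g in present[1:]:
        key = f"grp_{g}"
        coef = float(cph.params_[key])
        se = float(cph.standard_errors_[key])
        unstable = events_by_group[g] == 0 or se > 100
        rows.append({
            "group": g, "coef": coef, "se": se, "hr": _exp(coef),
            "hr_ci_lower": _exp(coef - 1.96 * se),
            "hr_ci_upper": _exp(coef + 1.96 * se),
            "unstable": unstable,
        })
        if unstable:
            warnings.warn(f"group {g!r}: no events or monotone likelihood; "
                          "coefficient unstable", stacklevel=2)
    summary = pd.DataFrame(rows).set_index("group")
    ref_row = pd.DataFrame([{"coef": 0.0, "se": 0.0, "hr": 1.0,
                             "hr_ci_lower": 1.0, "hr_ci_upper": 1.0,
                             "unstable": False}], index=[reference])
    summary = pd.concat([ref_row, summary])
    return CoxFit(reference, summary, float(cph.log_likelihood_), cph)


# ---------------------------------------------------------------------------
# Calibration via the Poisson representation


@dataclass
class CalibrationResult:
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    n: int
    events: int


def calibration_poisson(
    time: np.ndarray,
    event: np.ndarray,
    prognostic_index: np.ndarray,
    baseline_cum_hazard: np.ndarray,
) -> CalibrationResult:
    """Calibration intercept and slope from the Poisson representation of a Cox model.

    One record per subject at the (truncated) exit time.  With predicted
    cumulative hazard H_i = H0(t_i) * exp(PI_i):

    * intercept model: d_i ~ Poisson(exp(alpha + log H_i)); the MLE is
      alpha = log(sum d / sum H) — calibration-in-the-large;
    * slope model: d_i ~ Poisson(exp(a + b * PI_i + log H0(t_i))); b is the
      calibration slope (1 = perfectly scaled prognostic index).

    Both are fitted by Poisson GLM; CIs are Wald from the information matrix.
    """
    import statsmodels.api as sm

    time = np.asarray(time, float)
    event = np.asarray(event, float)
    pi = np.asarray(prognostic_index, float)
    h0 = np.asarray(baseline_cum_hazard, float)
    if np.any(h0 <= 0):
        raise ValueError("baseline cumulative hazard must be positive")
    h_pred = h0 * np.exp(pi)
    glm_int = sm.GLM(event, np.ones((len(event), 1)), family=sm.families.Poisson(),
                     offset=np.log(h_pred)).fit()
    alpha = float(glm_int.params[0])
    a_lo, a_hi = (float(x) for x in glm_int.conf_int()[0])
    X = sm.add_constant(pi)
    glm_slope = sm.GLM(event, X, family=sm.families.Poisson(), offset=np.log(h0)).fit()
    beta = float(glm_slope.params[1])
    b_lo, b_hi = (float(x) for x in glm_slope.conf_int()[1])
    return CalibrationResult(alpha, (a_lo, a_hi), beta, (b_lo, b_hi),
                             n=len(event), events=int(event.sum()))


def calibration_by_group(
    ds: SurvivalDataset,
    predicted_by_group: Mapping[str, float],
    horizon_years: float = 5.0,
) -> pd.DataFrame:
    """Per-risk-group predicted vs observed (Kaplan-Meier) survival at the horizon.

    ``ds.marker`` must hold group labels.  Groups with no subjects are
    omitted with a warning.  Differences are predicted - observed, so a
    positive difference means the score under-predicts mortality.
    """
    groups = np.asarray(ds.marker, dtype=object).astype(str)
    rows = []
    for g, predicted in predicted_by_group.items():
        mask = groups == str(g)
        if not mask.any():
            warnings.warn(f"risk group {g!r}: no subjects, omitted", stacklevel=2)
            continue
        sub = ds.restrict(mask)
        if sub.event.sum() == 0:
            observed, lo, hi = 1.0, float("nan"), float("nan")
        else:
            km = kaplan_meier(sub)
            observed = km.survival_at(horizon_years)
            lo, hi = km.ci_at(horizon_years)
        rows.append({
            "group": str(g), "n": int(mask.sum()), "events": int(sub.event.sum()),
            "predicted": float(predicted), "observed": observed,
            "observed_ci_lower": lo, "observed_ci_upper": hi,
            "difference": float(predicted) - observed,
            "abs_difference": abs(float(predicted) - observed),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Head-to-head comparison on common complete cases


def compare_scores(
    time: np.ndarray,
    event: np.ndarray,
    marker_a: np.ndarray,
    marker_b: np.ndarray,
    computable_a: np.ndarray,
    computable_b: np.ndarray,
) -> dict:
    """Paired C-statistics restricted to subjects where both scores are computable."""
    common = np.asarray(computable_a, bool) & np.asarray(computable_b, bool)
    if not common.any():
        raise ValueError("no subjects with both scores computable")
    time = np.asarray(time, float)[common]
    event = np.asarray(event, int)[common]
    res_a = harrells_c(SurvivalDataset(time, event, np.asarray(marker_a, float)[common]))
    res_b = harrells_c(SurvivalDataset(time, event, np.asarray(marker_b, float)[common]))
    return {
        "n_common": int(common.sum()),
        "events_common": int(event.sum()),
        "c_a": res_a.c, "ci_a": res_a.ci,
        "c_b": res_b.c, "ci_b": res_b.ci,
    }
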