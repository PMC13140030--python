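"""Synthetic cohort generator emulating an aged (>=70) HIV-1 cohort.

Covariates are drawn independently from marginal distributions matching the
study population this package targets (age-band mix, CD4 around a median of
553 cells/mm3, comorbidity prevalences, eGFR band mix, ~66% missing albumin,
~32% of weights dated outside the +/-12-month window).  Survival is
exponential with hazard h0 * exp(lambda * score), where the score is the
packaged Dat'AIDS points total computed from the generated covariates; the
default (h0, lambda) pair is chosen so the four risk groups' 5-year survival
approximates the published group-level predictions (0.95/0.90/0.80/0.53).
Censoring combines the administrative study end, the 5-year horizon, and a
configurable loss-to-follow-up fraction censored uniformly over (0, 5].

Everything is deterministic given the seed; outputs are the exact CSV
schemas the cohort loader consumes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from hivprognosis.clinical import CREATININE_UMOL_PER_MGDL
from hivprognosis.cohort import (
    BaselineCovariates,
    MeasurementSeries,
    ParticipantRecord,
    ResolvedValue,
    write_cohort,
)
from hivprognosis.scores import ScoreDefinition, compute_score, load_score_definition


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the target study population."""

    n: int = 1330
    seed: int = 20140601

    # recruitment and administrative censoring
    recruit_start: date = date(2014, 6, 1)
    recruit_end: date = date(2017, 12, 31)
    study_end: date = date(2019, 12, 31)
    horizon_years: float = 5.0

    # covariate marginals
    male_fraction: float = 0.758
    # band mixes as counts/total so they sum to one exactly
    age_band_probs: tuple[float, float, float] = (809 / 1330, 486 / 1330, 35 / 1330)  # 70-74 / 75-84 / >=85
    cd4_median: float = 553.0
    cd4_log_sigma: float = 0.45
    cd4_nadir_median: float = 174.0
    cd4_nadir_log_sigma: float = 0.95
    rna_suppressed_fraction: float = 0.887
    rna_unsuppressed_median: float = 1556.0
    rna_unsuppressed_log_sigma: float = 4.5
    prev_cancer: float = 0.112
    prev_cvd: float = 0.133
    prev_cirrhosis: float = 0.030
    prev_hcv: float = 0.047
    prev_hbv: float = 0.013
    prev_aids: float = 0.25
    egfr_band_probs: tuple[float, float, float] = (47 / 1330, 399 / 1330, 884 / 1330)  # <30 / 30-59 / >=60
    hemoglobin_male: tuple[float, float] = (14.2, 1.5)   # mean, sd -> ~21% anaemia
    hemoglobin_female: tuple[float, float] = (13.0, 1.25)
    bmi_mean: float = 24.3
    bmi_sd: float = 3.6
    height_male: tuple[float, float] = (1.75, 0.07)
    height_female: tuple[float, float] = (1.62, 0.065)
    ast_median: float = 25.0
    ast_log_sigma: float = 0.32
    alt_median: float = 23.0
    alt_log_sigma: float = 0.45
    platelets_mean: float = 200.0
    platelets_sd: float = 55.0
    wbc_median: float = 6.0
    wbc_log_sigma: float = 0.27
    albumin_mean: float = 41.5  # g/L
    albumin_sd: float = 4.6

    # survival model: hazard = h0 * exp(lambda_true * score)
    lambda_true: float = 0.105
    h0: float = 0.00925

    # censoring and missingness (MCAR)
    ltfu_fraction: float = 0.11
    missing_albumin: float = 0.659
    weight_outside_window: float = 0.317
    missing_rates: dict = field(default_factory=lambda: {
        "alt": 0.005, "ast": 0.005, "platelets": 0.002, "wbc": 0.008,
        "hiv_rna": 0.003, "cd4_nadir": 0.02, "hemoglobin": 0.002,
        "creatinine": 0.002,
    })

    # extra screened-but-ineligible records appended to the tables
    # (116/1330 reproduces a ~92% inclusion fraction at the default n)
    ineligible_fraction: float = 116.0 / 1330.0

    def validate(self) -> None:
        problems = []
        if self.n <= 0:
            problems.append("n must be positive")
        probs = [self.male_fraction, self.rna_suppressed_fraction, self.prev_cancer,
                 self.prev_cvd, self.prev_cirrhosis, self.prev_hcv, self.prev_hbv,
                 self.ltfu_fraction, self.missing_albumin, self.weight_outside_window,
                 *self.age_band_probs, *self.egfr_band_probs]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            problems.append("all probabilities must lie in [0, 1]")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            problems.append("age_band_probs must sum to 1")
        if abs(sum(self.egfr_band_probs) - 1.0) > 1e-9:
            problems.append("egfr_band_probs must sum to 1")
        if self.h0 <= 0:
            problems.append("h0 must be positive")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    """Per-subject ground truth retained alongside the written CSVs."""

    participant_id: list[str]
    score: np.ndarray
    risk_group: list[str]
    death_time: np.ndarray      # uncensored exponential draw (years)
    followup: np.ndarray        # observed time after censoring
    event: np.ndarray


def _invert_ckd_epi(egfr: np.ndarray, female: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Creatinine (umol/L) giving the requested 2009 CKD-EPI eGFR."""
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    a = 141.0 * 0.993**age * np.where(female, 1.018, 1.0)
    ratio = egfr / a
    x = np.where(ratio < 1.0, ratio ** (-1.0 / 1.209), ratio ** (1.0 / alpha))
    return kappa * x * CREATININE_UMOL_PER_MGDL


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(math.log(median), sigma, n))


def generate_cohort(
    cfg: SyntheticConfig,
    out_dir: str | Path | None = None,
    definition: ScoreDefinition | None = None,
) -> tuple[list[ParticipantRecord], list[MeasurementSeries], SyntheticTruth]:
    """Draw a cohort; optionally write participants.csv / measurements.csv / meta.json.

    Returns the records, the measurement series, and the retained ground
    truth (true score, uncensored death time).  Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if definition is None:
        definition = load_score_definition("dataids")
    n = cfg.n

    female = rng.random(n) >= cfg.male_fraction
    band = rng.choice(3, size=n, p=cfg.age_band_probs)
    age = np.select(
        [band == 0, band == 1, band == 2],
        [rng.uniform(70.0, 75.0, n), rng.uniform(75.0, 85.0, n), rng.uniform(85.0, 95.0, n)],
    )
    cd4 = _lognormal(rng, cfg.cd4_median, cfg.cd4_log_sigma, n)
    cd4_nadir = np.minimum(_lognormal(rng, cfg.cd4_nadir_median, cfg.cd4_nadir_log_sigma, n), cd4)
    suppressed = rng.random(n) < cfg.rna_suppressed_fraction
    rna = np.where(suppressed, rng.uniform(10.0, 50.0, n),
                   50.0 + _lognormal(rng, cfg.rna_unsuppressed_median, cfg.rna_unsuppressed_log_sigma, n))
    cancer = rng.random(n) < cfg.prev_cancer
    cvd = rng.random(n) < cfg.prev_cvd
    cirrhosis = rng.random(n) < cfg.prev_cirrhosis
    hcv = rng.random(n) < cfg.prev_hcv
    hbv = rng.random(n) < cfg.prev_hbv
    aids = rng.random(n) < cfg.prev_aids
    egfr_band = rng.choice(3, size=n, p=cfg.egfr_band_probs)
    egfr = np.select(
        [egfr_band == 0, egfr_band == 1, egfr_band == 2],
        [rng.uniform(12.0, 30.0, n), rng.uniform(30.0, 60.0, n), rng.uniform(60.0, 110.0, n)],
    )
    creatinine = _invert_ckd_epi(egfr, female, age)
    hgb = np.where(
        female,
        rng.normal(*cfg.hemoglobin_female, n),
        rng.normal(*cfg.hemoglobin_male, n),
    ).clip(6.0, 20.0)
    height = np.where(female, rng.normal(*cfg.height_female, n),
                      rng.normal(*cfg.height_male, n)).clip(1.40, 2.05)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, n).clip(13.0, 45.0)
    weight = bmi * height**2
    ast = _lognormal(rng, cfg.ast_median, cfg.ast_log_sigma, n)
    alt = _lognormal(rng, cfg.alt_median, cfg.alt_log_sigma, n)
    platelets = rng.normal(cfg.platelets_mean, cfg.platelets_sd, n).clip(20.0, 600.0)
    wbc = _lognormal(rng, cfg.wbc_median, cfg.wbc_log_sigma, n)
    albumin = rng.normal(cfg.albumin_mean, cfg.albumin_sd, n).clip(15.0, 55.0)

    # true score from the full (pre-missingness) covariates
    scores = np.empty(n)
    groups: list[str] = []
    for i in range(n):
        cov = BaselineCovariates(
            participant_id=str(i), sex="female" if female[i] else "male", age=float(age[i]),
            non_hiv_cancer=bool(cancer[i]), cvd=bool(cvd[i]), cirrhosis=bool(cirrhosis[i]),
            aids=bool(aids[i]), hbv=bool(hbv[i]), hcv=bool(hcv[i]),
        )
        today = cfg.recruit_start
        for analyte, val in (("cd4", cd4[i]), ("creatinine", creatinine[i]),
                             ("hemoglobin", hgb[i]), ("weight", weight[i]),
                             ("height", height[i])):
            cov.values[analyte] = ResolvedValue(float(val), today, "after")
        res = compute_score(cov, definition)
        scores[i] = res.total
        groups.append(res.risk_group or "")

    # survival: exponential given the true score; censoring
    rate = cfg.h0 * np.exp(cfg.lambda_true * scores)
    death_time = rng.exponential(1.0 / rate)
    recruit_days = (cfg.recruit_end - cfg.recruit_start).days
    entry_offset = rng.integers(0, recruit_days + 1, n)
    entry = np.array([cfg.recruit_start + timedelta(days=int(o)) for o in entry_offset])
    admin_cap = np.array([
        min(cfg.horizon_years, (cfg.study_end - e).days / 365.25) for e in entry
    ])
    ltfu = rng.random(n) < cfg.ltfu_fraction
    ltfu_time = rng.uniform(0.0, cfg.horizon_years, n)
    censor = np.where(ltfu, np.minimum(admin_cap, ltfu_time), admin_cap)
    followup = np.minimum(death_time, censor)
    event = (death_time <= censor).astype(int)

    participants: list[ParticipantRecord] = []
    measurements: list[MeasurementSeries] = []
    ids = [f"P{i:05d}" for i in range(n)]

    def add_meas(pid: str, analyte: str, when: date, value: float) -> None:
        from hivprognosis.cohort import EXPECTED_UNITS
        measurements.append(
            MeasurementSeries(pid, analyte, [(when, round(float(value), 4), EXPECTED_UNITS[analyte])])
        )

    for i in range(n):
        e: date = entry[i]
        birth = e - timedelta(days=int(round(age[i] * 365.25)))
        exit_d = e + timedelta(days=max(0, int(round(followup[i] * 365.25))))
        participants.append(ParticipantRecord(
            participant_id=ids[i], sex_at_birth="female" if female[i] else "male",
            birth_date=birth, entry_date=e, exit_date=exit_d,
            event="death" if event[i] else "censored",
            hiv2=False, non_hiv_cancer=bool(cancer[i]), cvd=bool(cvd[i]),
            cirrhosis=bool(cirrhosis[i]), aids=bool(aids[i]),
            hbsag_pos=bool(hbv[i]), hcv_ab_pos=bool(hcv[i]),
        ))
        # dated labs, mostly shortly after entry and inside the window
        lab_offset = int(np.clip(round(rng.normal(20.0, 40.0)), -300, 300))
        lab_date = e + timedelta(days=lab_offset)
        values = {
            "cd4": cd4[i], "cd4_nadir": cd4_nadir[i], "hiv_rna": rna[i],
            "hemoglobin": hgb[i], "creatinine": creatinine[i], "ast": ast[i],
            "alt": alt[i], "platelets": platelets[i], "wbc": wbc[i],
            "albumin": albumin[i],
        }
        for analyte, val in values.items():
            if analyte == "albumin":
                if rng.random() < cfg.missing_albumin:
                    continue
            elif analyte != "cd4" and rng.random() < cfg.missing_rates.get(analyte, 0.0):
                continue
            add_meas(ids[i], analyte, lab_date, val)
        # weight: inside the window for most, far before entry for the rest
        if rng.random() < cfg.weight_outside_window:
            wdate = e - timedelta(days=int(rng.integers(420, 1400)))
        else:
            wdate = lab_date
        add_meas(ids[i], "weight", wdate, weight[i])
        add_meas(ids[i], "height", e - timedelta(days=int(rng.integers(0, 1000))), height[i])

    # screened-but-ineligible extras exercising the eligibility filter
    n_extra = int(round(cfg.ineligible_fraction * n))
    for j in range(n_extra):
        pid = f"X{j:05d}"
        kind = rng.choice(3, p=[0.45, 0.45, 0.10])  # age / no CD4 in window / HIV-2
        e = cfg.recruit_start + timedelta(days=int(rng.integers(0, recruit_days + 1)))
        a = float(rng.uniform(64.0, 69.9)) if kind == 0 else float(rng.uniform(70.0, 85.0))
        participants.append(ParticipantRecord(
            participant_id=pid, sex_at_birth="male",
            birth_date=e - timedelta(days=int(round(a * 365.25))),
            entry_date=e, exit_date=e + timedelta(days=365), event="censored",
            hiv2=bool(kind == 2),
        ))
        cd4_date = e + timedelta(days=500) if kind == 1 else e + timedelta(days=10)
        add_meas(pid, "cd4", cd4_date, float(rng.uniform(200, 800)))

    truth = SyntheticTruth(ids, scores, groups, death_time, followup, event)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(participants, measurements, out / "participants.csv", out / "measurements.csv")
        meta = {"seed": cfg.seed, "n": cfg.n, "n_screened": len(participants),
                "config": {k: str(v) if isinstance(v, date) else v
                           for k, v in dataclasses.asdict(cfg).items()}}
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return participants, measurements, truth


def generate_worked_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the small hand-checkable fixtures used in worked examples.

    * ``km_fixture.csv`` — 5 subjects whose product-limit estimate steps
      through 0.8, 0.5333, 0.2667;
    * ``c_fixture.csv`` — 3 fully-observed subjects with perfectly
      discriminating markers (C = 1);
    * ``calibration_fixture.csv`` — 3 subjects whose predicted cumulative
      hazards sum to the death count (intercept 0).
    """
    import csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    km = out / "km_fixture.csv"
    with open(km, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "event"])
        for t, d in zip((2, 3, 4, 5, 6), (1, 0, 1, 1, 0)):
            w.writerow([t, d])
    paths["km"] = km

    cfx = out / "c_fixture.csv"
    with open(cfx, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "event", "marker"])
        for t, d, m in zip((1, 2, 3), (1, 1, 1), (3, 2, 1)):
            w.writerow([t, d, m])
    paths["c"] = cfx

    cal = out / "calibration_fixture.csv"
    with open(cal, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["event", "predicted_cum_hazard"])
        for d, h in zip((1, 0, 1), (0.5, 0.5, 1.0)):
            w.writerow([d, h])
    paths["calibration"] = cal
    return paths
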