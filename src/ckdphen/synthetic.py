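"""Synthetic longitudinal hospital records with known CKD/AKI ground truth.

Real routine-care records of this kind are held under hospital-law
restrictions and cannot be redistributed, so every downstream stage of the
phenotyping pipeline is exercised against a simulator instead.  The
generator emulates an adult inpatient population with repeated admissions
over several years:

* each patient carries a latent "true" advanced-CKD status drawn with an
  age-dependent probability (older patients are more likely CKD, which
  induces the age-CKD point-biserial correlation observed in routine
  cohorts, r ~ 0.3-0.45);
* CKD patients sit at a baseline eGFR drawn below 60 mL/min/1.73 m^2,
  non-CKD patients well above it; the baseline creatinine is obtained by
  inverting the CKD-EPI 2009 equation at that target eGFR;
* per-stay creatinine series are the baseline creatinine times a transient
  acute-kidney-injury multiplier (piecewise-linear rise to a peak, then
  recovery) times multiplicative lognormal noise;
* ICD-10 CKD billing codes and a binary discharge-summary CKD mention are
  emitted with configurable sensitivity/specificity, emulating imperfect
  administrative coding and documentation.

Determinism: each patient owns a private random stream seeded from
``(seed, patient_index)``, so cohorts are byte-identical across runs and
independent of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .egfr import invert_egfr_to_creatinine

# representative ICD-10 codes per comorbidity group; one code per group is
# enough because downstream matching is by prefix
_COMORBIDITY_CODES = {
    "cardiovascular": "I50.9",
    "diabetes": "E11.9",
    "liver": "K70.3",
    "malignancy": "C34.9",
}

# per-group emission probability given (CKD, non-CKD) truth; values shaped
# after the comorbidity burden of a mixed internal-medicine/surgery
# validation cohort (CKD patients carry more cardiovascular and diabetic
# disease, slightly less malignancy)
_DEFAULT_COMORBIDITY_RATES = {
    "cardiovascular": (0.38, 0.15),
    "diabetes": (0.30, 0.10),
    "liver": (0.13, 0.11),
    "malignancy": (0.21, 0.27),
}

HOURS_PER_DAY = 24.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    Defaults describe a validation-style cohort: ~12 % advanced-CKD
    prevalence, ages centred near 60 years, a couple of prior stays per
    patient over a 7-year history window, and coding error rates matching
    rule-based classifiers observed in routine data (ICD sensitivity
    0.931 / specificity 0.872; discharge-summary 0.862 / 0.684).
    """

    n_patients: int = 1000
    ckd_prevalence: float = 0.12
    seed: int = 0
    age_mean: float = 60.0
    age_sd: float = 14.0
    stays_per_patient_rate: float = 2.0  # Poisson mean of *previous* stays
    labs_per_stay_rate: float = 4.0  # mean creatinine count per stay (>=1)
    history_span: float = 7.0  # years before index admission
    aki_rate_ckd: float = 0.30  # per-stay AKI probability
    aki_rate_nonckd: float = 0.08
    aki_peak_multiplier: float = 2.5  # creatinine fold-rise at AKI peak
    aki_rise_days: float = 2.0
    aki_fall_days: float = 3.0
    creatinine_noise_cv: float = 0.12
    icd_sensitivity: float = 0.931
    icd_specificity: float = 0.872
    summary_sensitivity: float = 0.862
    summary_specificity: float = 0.684
    target_egfr_ckd_range: tuple[float, float] = (15.0, 50.0)
    target_egfr_nonckd_range: tuple[float, float] = (65.0, 110.0)
    age_ckd_effect: float = 0.10  # log-odds of CKD per year of age
    ed_fraction: float = 0.05  # single-stay patients routed via emergency dept
    min_stay_days: float = 3.0
    max_stay_days: float = 14.0
    index_window: tuple[str, str] = ("2018-01-01", "2020-04-30")
    history_start: str = "2011-01-01"
    comorbidity_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_RATES)
    )

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "ckd_prevalence",
            "aki_rate_ckd",
            "aki_rate_nonckd",
            "icd_sensitivity",
            "icd_specificity",
            "summary_sensitivity",
            "summary_specificity",
            "ed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.target_egfr_ckd_range
        nlo, nhi = self.target_egfr_nonckd_range
        if not (0 < lo < hi):
            raise ValueError("invalid CKD eGFR range")
        if hi >= 60.0:
            raise ValueError("CKD eGFR range must stay below 60 mL/min/1.73 m^2")
        if nlo <= hi:
            raise ValueError("eGFR ranges must not overlap")
        if self.aki_peak_multiplier <= 1.0:
            raise ValueError("aki_peak_multiplier must exceed 1")
        if self.creatinine_noise_cv < 0:
            raise ValueError("creatinine_noise_cv must be >= 0")
        if self.min_stay_days < 1.0:
            raise ValueError("stays must last at least one day")


@dataclass
class RawRecordBundle:
    """Flattened FHIR-like resource tables produced by the generator."""

    patients: pd.DataFrame  # patient_id, sex, birth_date
    stays: pd.DataFrame  # stay_id, patient_id, admission, discharge, department
    observations: pd.DataFrame  # obs_id, patient_id, stay_id, timestamp, value, unit
    conditions: pd.DataFrame  # patient_id, code
    summaries: pd.DataFrame  # patient_id, ckd_mentioned


@dataclass
class TruthLabels:
    """Per-patient ground truth plus the injected AKI episodes."""

    labels: pd.DataFrame  # patient_id, ckd_true, baseline_egfr
    aki_episodes: pd.DataFrame  # patient_id, stay_id, onset_hours, duration_hours


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _solve_prevalence_intercept(ages: np.ndarray, cfg: SimulationConfig) -> float:
    """Intercept of the age->CKD logistic link hitting the target prevalence."""
    centred = ages - cfg.age_mean

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + cfg.age_ckd_effect * centred))) - cfg.ckd_prevalence

    return brentq(gap, -40.0, 40.0)


def _aki_multiplier(t_hours: np.ndarray, onset: float, rise_h: float,
                    fall_h: float, peak: float) -> np.ndarray:
    """Piecewise-linear creatinine fold-change of one AKI episode."""
    t = np.asarray(t_hours, dtype=float)
    mult = np.ones_like(t)
    rising = (t >= onset) & (t < onset + rise_h)
    mult[rising] = 1.0 + (peak - 1.0) * (t[rising] - onset) / rise_h
    falling = (t >= onset + rise_h) & (t < onset + rise_h + fall_h)
    mult[falling] = peak - (peak - 1.0) * (t[falling] - onset - rise_h) / fall_h
    return mult


def _simulate_series_arrays(
    rng: np.random.Generator,
    baseline_creatinine: float,
    duration_h: float,
    config: SimulationConfig,
    aki_onset_hours: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (minutes from admission) and creatinine values of one stay."""
    if duration_h < HOURS_PER_DAY:
        raise ValueError("stay must last at least one day")
    n_labs = 1 + rng.poisson(max(config.labs_per_stay_rate - 1.0, 0.0))
    offsets = np.sort(rng.uniform(0.0, duration_h, size=n_labs))
    offsets[0] = offsets[0] * 0.1  # first draw shortly after admission
    # enforce strictly increasing timestamps at minute resolution
    offsets = np.maximum.accumulate(offsets + np.arange(n_labs) * (1.0 / 60.0))

    mult = np.ones(n_labs)
    if aki_onset_hours is not None:
        mult = _aki_multiplier(
            offsets,
            aki_onset_hours,
            config.aki_rise_days * HOURS_PER_DAY,
            config.aki_fall_days * HOURS_PER_DAY,
            config.aki_peak_multiplier,
        )
    cv = config.creatinine_noise_cv
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv**2)))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_labs))
    else:
        noise = np.ones(n_labs)
    values = baseline_creatinine * mult * noise
    minutes = np.round(offsets * 60.0)
    return minutes, values


def simulate_creatinine_series(
    rng: np.random.Generator,
    baseline_creatinine: float,
    admission: pd.Timestamp,
    discharge: pd.Timestamp,
    config: SimulationConfig,
    aki_onset_hours: float | None = None,
) -> pd.DataFrame:
    """Creatinine observations of one stay.

    Timestamps are strictly increasing within ``[admission, discharge)``;
    values are ``baseline * AKI multiplier * lognormal noise`` and hence
    always positive.  ``aki_onset_hours`` of ``None`` means no episode.
    """
    duration_h = (discharge - admission) / pd.Timedelta(hours=1)
    minutes, values = _simulate_series_arrays(
        rng, baseline_creatinine, duration_h, config, aki_onset_hours
    )
    timestamps = admission + pd.to_timedelta(minutes, unit="m")
    return pd.DataFrame({"timestamp": timestamps, "value": values})


def generate_cohort(config: SimulationConfig) -> tuple[RawRecordBundle, TruthLabels]:
    """Generate a full synthetic cohort with ground-truth labels.

    Every patient has one index stay inside the configured evaluation
    window plus ``Poisson(stays_per_patient_rate)`` previous stays spread
    over the history span; every stay carries at least one creatinine
    observation.
    """
    cfg = config
    window_start = pd.Timestamp(cfg.index_window[0])
    window_end = pd.Timestamp(cfg.index_window[1])
    window_days = (window_end - window_start).days

    rngs = [_patient_rng(cfg.seed, i) for i in range(cfg.n_patients)]
    ages = np.array(
        [float(np.clip(r.normal(cfg.age_mean, cfg.age_sd), 18.5, 95.0)) for r in rngs]
    )
    if cfg.ckd_prevalence <= 0.0:
        ckd = np.zeros(cfg.n_patients, dtype=bool)
    elif cfg.ckd_prevalence >= 1.0:
        ckd = np.ones(cfg.n_patients, dtype=bool)
    else:
        b0 = _solve_prevalence_intercept(ages, cfg)
        p = expit(b0 + cfg.age_ckd_effect * (ages - cfg.age_mean))
        ckd = np.array([r.uniform() < pi for r, pi in zip(rngs, p)])

    patients, stays, observations, conditions, summaries = [], [], [], [], []
    truth_rows, aki_rows = [], []

    for i, rng in enumerate(rngs):
        pid = f"P{i:06d}"
        sex = "male" if rng.uniform() < 0.5 else "female"
        age = ages[i]
        is_ckd = bool(ckd[i])
        lo, hi = cfg.target_egfr_ckd_range if is_ckd else cfg.target_egfr_nonckd_range
        baseline_egfr = float(rng.uniform(lo, hi))
        baseline_cr = invert_egfr_to_creatinine(baseline_egfr, age, sex)

        n_prev = int(rng.poisson(cfg.stays_per_patient_rate))
        index_adm = window_start + pd.Timedelta(days=float(rng.uniform(0, window_days)))
        birth_date = (index_adm - pd.Timedelta(days=age * 365.25)).normalize()

        emergency = n_prev == 0 and rng.uniform() < cfg.ed_fraction
        stay_specs: list[tuple[pd.Timestamp, float, str, bool]] = []
        # previous stays: discharge strictly before index admission
        if n_prev > 0:
            span_days = cfg.history_span * 365.25
            offs = np.sort(
                rng.uniform(cfg.max_stay_days + 7.0, span_days, size=n_prev)
            )[::-1]
            for off in offs:
                adm = index_adm - pd.Timedelta(days=float(off))
                dur = float(rng.uniform(cfg.min_stay_days, cfg.max_stay_days))
                stay_specs.append((adm, dur, "ward", False))
        index_dur = float(
            rng.uniform(cfg.min_stay_days, 5.0 if emergency else cfg.max_stay_days)
        )
        stay_specs.append(
            (index_adm, index_dur, "emergency" if emergency else "ward", True)
        )

        aki_rate = cfg.aki_rate_ckd if is_ckd else cfg.aki_rate_nonckd
        for j, (adm, dur_days, dept, _is_index) in enumerate(stay_specs):
            sid = f"{pid}-S{j}"
            disch = adm + pd.Timedelta(days=dur_days)
            onset = None
            if rng.uniform() < aki_rate:
                onset = float(rng.uniform(0.0, 0.6 * dur_days * HOURS_PER_DAY))
                aki_rows.append(
                    {
                        "patient_id": pid,
                        "stay_id": sid,
                        "onset_hours": onset,
                        "duration_hours": (cfg.aki_rise_days + cfg.aki_fall_days)
                        * HOURS_PER_DAY,
                    }
                )
            duration_h = dur_days * HOURS_PER_DAY
            minutes, values = _simulate_series_arrays(
                rng, baseline_cr, duration_h, cfg, onset
            )
            stays.append(
                {
                    "stay_id": sid,
                    "patient_id": pid,
                    "admission": adm,
                    "discharge": disch,
                    "department": dept,
                }
            )
            for k, (m, v) in enumerate(zip(minutes, values)):
                observations.append(
                    {
                        "obs_id": f"{sid}-O{k}",
                        "patient_id": pid,
                        "stay_id": sid,
                        "timestamp": adm + pd.Timedelta(minutes=float(m)),
                        "value": float(v),
                        "unit": "mg/dL",
                    }
                )

        patients.append({"patient_id": pid, "sex": sex, "birth_date": birth_date})

        # imperfect administrative CKD coding
        if is_ckd:
            if rng.uniform() < cfg.icd_sensitivity:
                conditions.append({"patient_id": pid, "code": "N18.4"})
        else:
            if rng.uniform() >= cfg.icd_specificity:
                conditions.append({"patient_id": pid, "code": "N18.9"})
        mention = (
            rng.uniform() < cfg.summary_sensitivity
            if is_ckd
            else rng.uniform() >= cfg.summary_specificity
        )
        summaries.append({"patient_id": pid, "ckd_mentioned": bool(mention)})

        for group, (p_ckd, p_non) in cfg.comorbidity_rates.items():
            if rng.uniform() < (p_ckd if is_ckd else p_non):
                conditions.append(
                    {"patient_id": pid, "code": _COMORBIDITY_CODES[group]}
                )

        truth_rows.append(
            {"patient_id": pid, "ckd_true": is_ckd, "baseline_egfr": baseline_egfr}
        )

    bundle = RawRecordBundle(
        patients=pd.DataFrame(patients),
        stays=pd.DataFrame(stays),
        observations=pd.DataFrame(observations),
        conditions=pd.DataFrame(conditions, columns=["patient_id", "code"]),
        summaries=pd.DataFrame(summaries),
    )
    truth = TruthLabels(
        labels=pd.DataFrame(truth_rows),
        aki_episodes=pd.DataFrame(
            aki_rows, columns=["patient_id", "stay_id", "onset_hours", "duration_hours"]
        ),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# serialization: NDJSON (one FHIR-like resource per line) and flat CSV tables


def _ts(x) -> str:
    return pd.Timestamp(x).isoformat()


def bundle_to_ndjson(bundle: RawRecordBundle) -> str:
    """Serialize a bundle as newline-delimited JSON, one resource per line."""
    lines = []
    for _, p in bundle.patients.iterrows():
        lines.append(
            json.dumps(
                {
                    "resourceType": "Patient",
                    "id": p["patient_id"],
                    "gender": p["sex"],
                    "birthDate": _ts(p["birth_date"])[:10],
                },
                sort_keys=True,
            )
        )
    for _, s in bundle.stays.iterrows():
        lines.append(
            json.dumps(
                {
                    "resourceType": "Encounter",
                    "id": s["stay_id"],
                    "subject": s["patient_id"],
                    "period": {"start": _ts(s["admission"]), "end": _ts(s["discharge"])},
                    "department": s["department"],
                },
                sort_keys=True,
            )
        )
    for _, o in bundle.observations.iterrows():
        lines.append(
            json.dumps(
                {
                    "resourceType": "Observation",
                    "id": o["obs_id"],
                    "subject": o["patient_id"],
                    "encounter": o["stay_id"],
                    "effectiveDateTime": _ts(o["timestamp"]),
                    "valueQuantity": {"value": round(float(o["value"]), 6),
                                      "unit": o["unit"]},
                },
                sort_keys=True,
            )
        )
    for _, c in bundle.conditions.iterrows():
        lines.append(
            json.dumps(
                {
                    "resourceType": "Condition",
                    "subject": c["patient_id"],
                    "code": {"coding": [{"code": c["code"]}]},
                },
                sort_keys=True,
            )
        )
    for _, f in bundle.summaries.iterrows():
        lines.append(
            json.dumps(
                {
                    "resourceType": "SummaryFlag",
                    "subject": f["patient_id"],
                    "ckd_mentioned": bool(f["ckd_mentioned"]),
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + "\n"


def write_bundle(bundle: RawRecordBundle, truth: TruthLabels, out_dir: str | Path,
                 fmt: str = "csv") -> None:
    """Write a bundle (and truth labels) to ``out_dir`` as CSV tables or NDJSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "ndjson":
        (out / "bundle.ndjson").write_text(bundle_to_ndjson(bundle))
    elif fmt == "csv":
        bundle.patients.to_csv(out / "patients.csv", index=False)
        bundle.stays.to_csv(out / "stays.csv", index=False)
        bundle.observations.to_csv(out / "observations.csv", index=False)
        bundle.conditions.to_csv(out / "conditions.csv", index=False)
        bundle.summaries.to_csv(out / "summaries.csv", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    truth.labels.to_csv(out / "truth.csv", index=False)
    truth.aki_episodes.to_csv(out / "aki_episodes.csv", index=False)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["target_egfr_ckd_range"] = list(d["target_egfr_ckd_range"])
    d["target_egfr_nonckd_range"] = list(d["target_egfr_nonckd_range"])
    d["index_window"] = list(d["index_window"])
    d["comorbidity_rates"] = {k: list(v) for k, v in d["comorbidity_rates"].items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("target_egfr_ckd_range", "target_egfr_nonckd_range", "index_window"):
        if key in d:
            d[key] = tuple(d[key])
    if "comorbidity_rates" in d:
        d["comorbidity_rates"] = {k: tuple(v) for k, v in d["comorbidity_rates"].items()}
    return SimulationConfig(**d)
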