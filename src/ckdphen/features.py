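"""Renal feature profiles: eGFR series, AKI flags, and predictor vectors.

Three predictor profiles are assembled per patient, differing in what is
knowable at the moment a biobanking decision must be made:

* ``admissionHIB`` — age, sex, eGFR from the first creatinine of the index
  stay; everything available at admission.
* ``historyHIB``   — admissionHIB plus the mean eGFR over previous stays
  (since a configurable history start), with an explicit missing-history
  indicator for patients seen for the first time.
* ``historyCKD``   — the full 15-variable retrospective profile: index-stay
  summaries (length of stay, discharge and mean eGFR, measurement counts,
  KDIGO AKI, reverted AKI, the below-60 index classifier) plus history
  ratios; only computable at/after discharge, which is why it serves as a
  silver-standard labeler rather than an admission-time classifier.

Conventions (documented, deliberately strict):
- eGFR thresholds use strict ``< 60``; no rounding before thresholding.
- All three history ratios are 0 when their denominator is 0; the history
  mean falls back to the admission eGFR with the indicator set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import FlattenedData, MissingEgfrError, age_at, select_admission_observation
from .egfr import compute_egfr

HOURS = pd.Timedelta(hours=1)
DAYS = pd.Timedelta(days=1)

KDIGO_ABS_RISE_MGDL = 0.3
KDIGO_ABS_WINDOW_H = 48.0
KDIGO_REL_FACTOR = 1.5
KDIGO_REL_WINDOW_D = 7.0
REVERTED_AKI_FACTOR = 0.66
REVERTED_AKI_WINDOW_D = 7.0
EGFR_THRESHOLD = 60.0

PROFILES = ("admissionHIB", "historyHIB", "historyCKD")

PROFILE_COLUMNS = {
    "admissionHIB": ["age", "sex_male", "egfr_admission"],
    "historyHIB": [
        "age",
        "sex_male",
        "egfr_admission",
        "mean_egfr_history",
        "history_missing",
    ],
    "historyCKD": [
        "age",
        "sex_male",
        "egfr_admission",
        "mean_egfr_history",
        "length_of_stay",
        "egfr_discharge",
        "mean_egfr_index",
        "egfr_count_index",
        "egfr_count_lt60_index",
        "aki_kdigo",
        "reverted_aki",
        "ratio_hosp_with_egfr",
        "ratio_measurements_per_hosp",
        "ratio_lt60_per_hosp",
        "index_classifier_max_lt60",
    ],
}


def _sorted_series(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = series.sort_values("timestamp", kind="mergesort")
    t = s["timestamp"].to_numpy()
    hours = (t - t[0]) / np.timedelta64(1, "h") if len(t) else np.array([])
    return np.asarray(hours, dtype=float), s["value"].to_numpy(dtype=float)


def detect_aki_kdigo(series: pd.DataFrame) -> bool:
    """Creatinine-based KDIGO acute kidney injury flag for one stay.

    True iff some observation rises >= 0.3 mg/dL above an earlier value
    within 48 h, or reaches >= 1.5x its baseline within 7 days, the
    baseline being the minimum value in the 7 days preceding the candidate
    elevation (rolling-minimum convention).  Urine-output criteria are out
    of scope (no urine data).
    """
    if series.empty:
        raise ValueError("need at least one observation")
    hours, values = _sorted_series(series)
    n = len(values)
    for j in range(1, n):
        prior_48h = values[(hours >= hours[j] - KDIGO_ABS_WINDOW_H) & (hours < hours[j])]
        if prior_48h.size and values[j] - prior_48h.min() >= KDIGO_ABS_RISE_MGDL:
            return True
        prior_7d = values[
            (hours >= hours[j] - KDIGO_REL_WINDOW_D * 24.0) & (hours < hours[j])
        ]
        if prior_7d.size and values[j] >= KDIGO_REL_FACTOR * prior_7d.min():
            return True
    return False


def detect_reverted_aki(series: pd.DataFrame) -> bool:
    """Transient-injury flag: creatinine falls below 66 % of its 7-day maximum.

    A pure ratio rule, so it is invariant to uniform rescaling of the
    series (unlike the absolute-rise arm of the KDIGO flag).
    """
    if series.empty:
        raise ValueError("need at least one observation")
    hours, values = _sorted_series(series)
    n = len(values)
    for j in range(1, n):
        prior = values[
            (hours >= hours[j] - REVERTED_AKI_WINDOW_D * 24.0) & (hours < hours[j])
        ]
        if prior.size and values[j] < REVERTED_AKI_FACTOR * prior.max():
            return True
    return False


def egfr_series(obs: pd.DataFrame, age: float, sex: str) -> pd.DataFrame:
    """Attach CKD-EPI eGFR to a creatinine observation table."""
    out = obs.sort_values("timestamp", kind="mergesort").copy()
    out["egfr"] = compute_egfr(out["value"].to_numpy(dtype=float), age, sex)
    return out


def summarize_index_stay(stay: pd.Series, egfr_values: np.ndarray) -> dict:
    """Index-stay summary block of the historyCKD profile."""
    g = np.asarray(egfr_values, dtype=float)
    if g.size == 0:
        raise MissingEgfrError("index stay has no eGFR values")
    return {
        "length_of_stay": float(
            (stay["discharge"] - stay["admission"]) / DAYS
        ),
        "egfr_discharge": float(g[-1]),
        "mean_egfr_index": float(g.mean()),
        "egfr_count_index": int(g.size),
        "egfr_count_lt60_index": int((g < EGFR_THRESHOLD).sum()),
        "index_classifier_max_lt60": bool(g.max() < EGFR_THRESHOLD),
    }


def summarize_history(
    history_egfr_by_stay: list[np.ndarray],
    fallback_egfr: float,
) -> dict:
    """History block: mean pre-index eGFR and the three per-stay ratios.

    ``history_egfr_by_stay`` holds one array of eGFR values per previous
    stay (possibly empty arrays for stays without measurements).  All
    ratios are 0 when their denominator is 0; with no history at all the
    mean falls back to ``fallback_egfr`` and the indicator is set.
    """
    n_prev = len(history_egfr_by_stay)
    with_egfr = [g for g in history_egfr_by_stay if len(g)]
    all_values = np.concatenate(with_egfr) if with_egfr else np.array([])
    if all_values.size:
        mean_hist = float(all_values.mean())
        missing = False
    else:
        mean_hist = float(fallback_egfr)
        missing = True
    n_with = len(with_egfr)
    return {
        "mean_egfr_history": mean_hist,
        "history_missing": missing,
        "ratio_hosp_with_egfr": (n_with / n_prev) if n_prev else 0.0,
        "ratio_measurements_per_hosp": (all_values.size / n_with) if n_with else 0.0,
        "ratio_lt60_per_hosp": (
            float((all_values < EGFR_THRESHOLD).sum()) / n_with if n_with else 0.0
        ),
    }


def build_feature_vector(profile: str, full_features: dict) -> pd.Series:
    """Project a patient's full feature dict onto one profile's columns."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cols = PROFILE_COLUMNS[profile]
    missing = [c for c in cols if c not in full_features]
    if missing:
        raise KeyError(f"features missing for profile {profile}: {missing}")
    return pd.Series({c: full_features[c] for c in cols}, index=cols)


def build_feature_matrices(
    data: FlattenedData,
    linked_stays: pd.DataFrame,
    included: list[str],
    profiles=PROFILES,
) -> dict[str, pd.DataFrame]:
    """Feature matrices for several profiles in one pass over the cohort.

    Features are computed from timestamp-sorted observations, so the result
    is invariant to input record order.  Booleans are emitted as 0/1 floats
    ready for model fitting.
    """
    for profile in profiles:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
    patients = data.patients.set_index("patient_id")
    stays_by_patient = dict(tuple(linked_stays.groupby("patient_id")))
    obs_by_stay = dict(tuple(data.observations.groupby("stay_id")))

    full_rows = {}
    for pid in included:
        pstays = stays_by_patient[pid]
        index_stay = pstays[pstays["is_index"]].iloc[0]
        sex = patients.loc[pid, "sex"]
        age = age_at(patients.loc[pid, "birth_date"], index_stay["admission"])

        index_obs = obs_by_stay.get(index_stay["stay_id"])
        if index_obs is None or index_obs.empty:
            raise MissingEgfrError(f"patient {pid}: index stay has no creatinine")
        index_obs = egfr_series(index_obs, age, sex)
        admission_row = select_admission_observation(index_obs)
        feat = {
            "age": float(age),
            "sex_male": 1.0 if str(sex).lower().startswith("m") else 0.0,
            "egfr_admission": float(compute_egfr(admission_row["value"], age, sex)),
        }
        feat.update(summarize_index_stay(index_stay, index_obs["egfr"].to_numpy()))
        feat["aki_kdigo"] = detect_aki_kdigo(index_obs)
        feat["reverted_aki"] = detect_reverted_aki(index_obs)

        hist_stays = pstays[pstays["is_history"]]
        hist_values = []
        for _, hstay in hist_stays.iterrows():
            hobs = obs_by_stay.get(hstay["stay_id"])
            if hobs is None or hobs.empty:
                hist_values.append(np.array([]))
            else:
                hobs = egfr_series(hobs, age, sex)
                hist_values.append(hobs["egfr"].to_numpy())
        feat.update(summarize_history(hist_values, feat["egfr_admission"]))
        full_rows[pid] = feat

    out: dict[str, pd.DataFrame] = {}
    for profile in profiles:
        if full_rows:
            mat = pd.DataFrame(
                {pid: build_feature_vector(profile, f) for pid, f in full_rows.items()}
            ).T
        else:
            mat = pd.DataFrame(columns=PROFILE_COLUMNS[profile])
        mat.index.name = "patient_id"
        out[profile] = mat.astype(float)
    return out


def build_feature_matrix(
    data: FlattenedData,
    linked_stays: pd.DataFrame,
    included: list[str],
    profile: str = "historyCKD",
) -> pd.DataFrame:
    """Feature matrix (patients x profile columns) for one profile."""
    return build_feature_matrices(data, linked_stays, included, (profile,))[profile]
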