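"""Flatten raw records, link stays, pick the index stay, apply cohort criteria.

The raw input is either a directory of flat CSV tables or an NDJSON file
with one FHIR-like resource per line (Patient, Encounter, Observation,
Condition, SummaryFlag).  Flattening validates referential integrity:
orphan observations and malformed records are reported, never silently
dropped.

Cohort criteria come in two profiles mirroring a gold-standard versus a
silver-standard recruitment design:

* ``gold``   — age > 18 at index admission, index stay >= 3 days, not
  directly discharged from the emergency department, admission eGFR
  computable;
* ``silver`` — age > 18 and admission eGFR computable (the minimum-stay and
  emergency-department rules apply only to the gold profile).

Exclusion rules are evaluated in a fixed order (age -> minimum stay ->
emergency discharge -> missing eGFR) and each excluded patient is logged
once with the first rule that fired, so that screening flow counts add up
reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
MIN_STAY_HOURS = 72.0

EXCLUSION_ORDER = ("age", "min_stay", "ed_discharge", "missing_egfr")


class MissingEgfrError(ValueError):
    """A stay has no usable creatinine observation."""


@dataclass
class FlattenReport:
    """Bookkeeping from flattening: nothing disappears without a trace."""

    unknown_resource_types: dict = field(default_factory=dict)
    orphan_observations: list = field(default_factory=list)
    rejected_records: list = field(default_factory=list)


@dataclass
class FlattenedData:
    patients: pd.DataFrame
    stays: pd.DataFrame
    observations: pd.DataFrame
    conditions: pd.DataFrame
    summaries: pd.DataFrame
    report: FlattenReport = field(default_factory=FlattenReport)


_PATIENT_COLS = ["patient_id", "sex", "birth_date"]
_STAY_COLS = ["stay_id", "patient_id", "admission", "discharge", "department"]
_OBS_COLS = ["obs_id", "patient_id", "stay_id", "timestamp", "value", "unit"]


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def _parse_ndjson(path: Path, report: FlattenReport) -> FlattenedData:
    patients, stays, obs, conds, summ = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError:
                report.rejected_records.append({"line": lineno, "reason": "bad json"})
                continue
            rt = rec.get("resourceType")
            if rt == "Patient":
                patients.append(
                    {
                        "patient_id": rec["id"],
                        "sex": rec.get("gender"),
                        "birth_date": rec.get("birthDate"),
                    }
                )
            elif rt == "Encounter":
                stays.append(
                    {
                        "stay_id": rec["id"],
                        "patient_id": rec["subject"],
                        "admission": rec["period"]["start"],
                        "discharge": rec["period"]["end"],
                        "department": rec.get("department", "ward"),
                    }
                )
            elif rt == "Observation":
                vq = rec.get("valueQuantity", {})
                obs.append(
                    {
                        "obs_id": rec.get("id"),
                        "patient_id": rec["subject"],
                        "stay_id": rec.get("encounter"),
                        "timestamp": rec.get("effectiveDateTime"),
                        "value": vq.get("value"),
                        "unit": vq.get("unit", "mg/dL"),
                    }
                )
            elif rt == "Condition":
                coding = rec.get("code", {}).get("coding", [{}])
                conds.append(
                    {"patient_id": rec["subject"], "code": coding[0].get("code")}
                )
            elif rt == "SummaryFlag":
                summ.append(
                    {
                        "patient_id": rec["subject"],
                        "ckd_mentioned": bool(rec.get("ckd_mentioned", False)),
                    }
                )
            else:
                report.unknown_resource_types[rt] = (
                    report.unknown_resource_types.get(rt, 0) + 1
                )
    return FlattenedData(
        patients=pd.DataFrame(patients, columns=_PATIENT_COLS),
        stays=pd.DataFrame(stays, columns=_STAY_COLS),
        observations=pd.DataFrame(obs, columns=_OBS_COLS),
        conditions=pd.DataFrame(conds, columns=["patient_id", "code"]),
        summaries=pd.DataFrame(summ, columns=["patient_id", "ckd_mentioned"]),
        report=report,
    )


def flatten_bundle(source) -> FlattenedData:
    """Flatten raw records into linked tables.

    ``source`` may be a directory of CSV tables (patients.csv, stays.csv,
    observations.csv, conditions.csv, summaries.csv), an ``.ndjson`` file,
    or an in-memory :class:`~ckdphen.synthetic.RawRecordBundle`.  Timestamps
    are parsed, record-level problems (malformed timestamps, non-positive
    creatinine) are rejected with a log entry, and observations referencing
    unknown patients or stays are listed as orphans.
    """
    report = FlattenReport()
    if hasattr(source, "observations") and hasattr(source, "patients"):
        data = FlattenedData(
            patients=source.patients.copy(),
            stays=source.stays.copy(),
            observations=source.observations.copy(),
            conditions=source.conditions.copy(),
            summaries=source.summaries.copy(),
            report=report,
        )
    else:
        path = Path(source)
        if path.is_file() and path.suffix == ".ndjson":
            data = _parse_ndjson(path, report)
        elif path.is_dir() and (path / "bundle.ndjson").exists():
            data = _parse_ndjson(path / "bundle.ndjson", report)
        elif path.is_dir():
            def read(name, cols):
                f = path / name
                return pd.read_csv(f) if f.exists() else _empty(cols)

            data = FlattenedData(
                patients=read("patients.csv", _PATIENT_COLS),
                stays=read("stays.csv", _STAY_COLS),
                observations=read("observations.csv", _OBS_COLS),
                conditions=read("conditions.csv", ["patient_id", "code"]),
                summaries=read("summaries.csv", ["patient_id", "ckd_mentioned"]),
                report=report,
            )
        else:
            raise FileNotFoundError(f"no readable bundle at {source}")

    # parse timestamps; malformed rows are rejected, not crashed on
    for frame, cols in (
        (data.stays, ["admission", "discharge"]),
        (data.observations, ["timestamp"]),
    ):
        for col in cols:
            frame[col] = pd.to_datetime(frame[col], errors="coerce")
    if not data.patients.empty:
        data.patients["birth_date"] = pd.to_datetime(
            data.patients["birth_date"], errors="coerce"
        )

    bad_stay = data.stays["admission"].isna() | data.stays["discharge"].isna()
    for _, row in data.stays[bad_stay].iterrows():
        report.rejected_records.append(
            {"stay_id": row["stay_id"], "reason": "malformed timestamp"}
        )
    data.stays = data.stays[~bad_stay].reset_index(drop=True)

    obs = data.observations
    obs["value"] = pd.to_numeric(obs["value"], errors="coerce")
    # µmol/L inputs converted to mg/dL at ingestion
    umol = obs["unit"].astype(str).str.contains("mol", case=False, na=False)
    obs.loc[umol, "value"] = obs.loc[umol, "value"] / 88.4
    obs.loc[umol, "unit"] = "mg/dL"
    bad_obs = obs["timestamp"].isna() | (obs["value"] <= 0)
    for _, row in obs[bad_obs].iterrows():
        report.rejected_records.append(
            {"obs_id": row["obs_id"], "reason": "malformed timestamp or value"}
        )
    obs = obs[~bad_obs].reset_index(drop=True)

    known_patients = set(data.patients["patient_id"])
    known_stays = set(data.stays["stay_id"])
    orphan = ~(obs["patient_id"].isin(known_patients) & obs["stay_id"].isin(known_stays))
    report.orphan_observations = obs.loc[orphan, "obs_id"].tolist()
    data.observations = obs[~orphan].reset_index(drop=True)
    return data


def link_stays(
    stays: pd.DataFrame,
    evaluation_window: tuple[str, str],
    history_start: str,
    policy: str = "first_in_window",
) -> tuple[pd.DataFrame, list[str]]:
    """Order stays per patient and flag the index stay.

    The index stay is the first (default policy) or longest
    (``policy="longest"``) stay whose admission falls within the evaluation
    window.  History stays are those discharged before the index admission
    and admitted on/after ``history_start``.  Patients without any stay in
    the window are returned in the second element and excluded upstream.
    """
    if policy not in ("first_in_window", "longest"):
        raise ValueError(f"unknown index-stay policy {policy!r}")
    w0, w1 = pd.Timestamp(evaluation_window[0]), pd.Timestamp(evaluation_window[1])
    h0 = pd.Timestamp(history_start)
    stays = stays.sort_values(["patient_id", "admission"], kind="mergesort").copy()
    stays["is_index"] = False
    stays["is_history"] = False
    no_index: list[str] = []
    for pid, grp in stays.groupby("patient_id", sort=True):
        in_window = grp[(grp["admission"] >= w0) & (grp["admission"] <= w1)]
        if in_window.empty:
            no_index.append(pid)
            continue
        if policy == "first_in_window":
            idx = in_window.index[0]
        else:
            idx = (in_window["discharge"] - in_window["admission"]).idxmax()
        stays.loc[idx, "is_index"] = True
        index_adm = stays.loc[idx, "admission"]
        hist = (
            (grp["discharge"] < index_adm)
            & (grp["admission"] >= h0)
            & (grp.index != idx)
        )
        stays.loc[hist[hist].index, "is_history"] = True
    return stays.reset_index(drop=True), no_index


def select_admission_observation(stay_obs: pd.DataFrame) -> pd.Series:
    """Earliest non-missing creatinine of a stay (ties: stable input order)."""
    ok = stay_obs[stay_obs["value"].notna()]
    if ok.empty:
        raise MissingEgfrError("no non-missing creatinine observation")
    return ok.loc[ok["timestamp"].idxmin()]


def age_at(birth_date, when) -> float:
    """Age in fractional years at a timestamp."""
    return (pd.Timestamp(when) - pd.Timestamp(birth_date)) / pd.Timedelta(
        days=DAYS_PER_YEAR
    )


def apply_inclusion_criteria(
    data: FlattenedData,
    linked_stays: pd.DataFrame,
    profile: str = "gold",
) -> tuple[list[str], pd.DataFrame]:
    """Apply cohort criteria; return included patient ids and an exclusion log.

    Exclusions record the *first* failing rule per patient in the fixed
    order age -> min_stay -> ed_discharge -> missing_egfr.  The included
    and excluded sets always partition the set of patients that own an
    index stay.
    """
    if profile not in ("gold", "silver"):
        raise ValueError(f"unknown cohort profile {profile!r}")
    strict = profile == "gold"
    index_stays = linked_stays[linked_stays["is_index"]].set_index("patient_id")
    patients = data.patients.set_index("patient_id")
    obs_by_stay = dict(tuple(data.observations.groupby("stay_id")))

    included: list[str] = []
    log_rows: list[dict] = []
    for pid in index_stays.index:
        stay = index_stays.loc[pid]
        age = age_at(patients.loc[pid, "birth_date"], stay["admission"])
        if not age > 18.0:
            log_rows.append({"patient_id": pid, "rule": "age",
                             "detail": f"age {age:.1f} at admission"})
            continue
        stay_hours = (stay["discharge"] - stay["admission"]) / pd.Timedelta(hours=1)
        if strict and stay_hours < MIN_STAY_HOURS:
            log_rows.append({"patient_id": pid, "rule": "min_stay",
                             "detail": f"stay {stay_hours:.0f} h < 72 h"})
            continue
        if strict and str(stay["department"]).lower() == "emergency":
            log_rows.append({"patient_id": pid, "rule": "ed_discharge",
                             "detail": "direct discharge from emergency department"})
            continue
        stay_obs = obs_by_stay.get(stay["stay_id"])
        try:
            if stay_obs is None or stay_obs.empty:
                raise MissingEgfrError("no creatinine observation")
            select_admission_observation(stay_obs)
        except MissingEgfrError:
            log_rows.append({"patient_id": pid, "rule": "missing_egfr",
                             "detail": "no admission creatinine"})
            continue
        included.append(pid)
    log = pd.DataFrame(log_rows, columns=["patient_id", "rule", "detail"])
    return included, log
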