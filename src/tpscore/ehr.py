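"""Encoding of MIMIC-style event tables into the binary time-series dataset.

A *case* is one hospital admission. Its reference date D0 is the calendar
date of discharge (or death); the encoder looks at the T=10 calendar days
before D0 (D-10 ... D-1, D0 itself excluded to avoid outcome leakage) and
binarizes three sources of events:

* lab events — 1 on a day iff at least one result that day is flagged
  abnormal (a missing flag counts as normal);
* procedure events — 1 on a day iff at least one procedure record falls on
  that day;
* prescriptions — 1 on every day of the [start, end] span of an order.

Feature identifiers are prefixed with their source table (``lab:50912``,
``rx:Heparin`` ...) so item ids cannot collide across tables.

Expected CSV columns (a subset of the MIMIC-III public schema):

* ADMISSIONS: ``HADM_ID, DISCHTIME, HOSPITAL_EXPIRE_FLAG``
* DIAGNOSES_ICD: ``HADM_ID, ICD9_CODE``
* LABEVENTS: ``HADM_ID, CHARTTIME, ITEMID, FLAG``
* PROCEDUREEVENTS_MV: ``HADM_ID, STARTTIME, ITEMID``
* PRESCRIPTIONS: ``HADM_ID, STARTDATE, ENDDATE, DRUG``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EventTensor, OutcomeVector, day_labels_for

logger = logging.getLogger(__name__)

CATEGORY_PREFIX = {"lab": "lab", "procedure": "proc", "prescription": "rx"}


@dataclass
class RawEventRecord:
    """One row from LABEVENTS / PROCEDUREEVENTS / PRESCRIPTIONS."""

    case_id: str
    timestamp: datetime
    item_id: str
    category: str  # "lab" | "procedure" | "prescription"
    abnormal_flag: bool | None = None
    end_timestamp: datetime | None = None  # prescriptions: last day of the span

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PREFIX:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.item_id:
            raise ValueError("item_id must be non-empty")

    @property
    def feature_id(self) -> str:
        return f"{CATEGORY_PREFIX[self.category]}:{self.item_id}"


@dataclass
class AdmissionRecord:
    """One admission: defines the case, its reference date D0 and outcome."""

    case_id: str
    discharge_datetime: datetime | None
    death_flag: bool
    diagnosis_codes: list[str] = field(default_factory=list)


def select_cohort(admissions: list[AdmissionRecord], codes: list[str]) -> list[str]:
    """Case ids whose diagnosis list intersects ``codes`` (undotted ICD-9 strings)."""
    if not codes:
        raise ValueError("codes must be non-empty")
    if not admissions:
        raise ValueError("empty diagnosis table")
    wanted = set(codes)
    hits = {a.case_id for a in admissions if wanted & set(a.diagnosis_codes)}
    if not hits:
        logger.warning("no admission matched ICD-9 codes %s", sorted(wanted))
    return sorted(hits)


def label_outcome(admission: AdmissionRecord) -> tuple[date, int]:
    """Reference date D0 (calendar date of discharge) and outcome label."""
    if admission.discharge_datetime is None:
        raise ValueError(f"admission {admission.case_id!r} lacks a discharge datetime")
    return admission.discharge_datetime.date(), int(admission.death_flag)


def encode_case(
    events: list[RawEventRecord],
    reference_date: date,
    n_days: int,
    feature_ids: list[str],
) -> np.ndarray:
    """Binary T x F matrix for one case.

    Row ``t`` covers calendar day ``reference_date - (n_days - t)``; events on
    D0 or before D-T are outside the window and never set a cell. Events whose
    feature id is not in ``feature_ids`` are dropped with a logged count.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    col = {fid: j for j, fid in enumerate(feature_ids)}
    out = np.zeros((n_days, len(feature_ids)), dtype=np.uint8)
    window_start = reference_date - timedelta(days=n_days)
    n_unknown = 0
    for ev in events:
        j = col.get(ev.feature_id)
        if j is None:
            n_unknown += 1
            continue
        if ev.category == "lab" and not ev.abnormal_flag:
            continue
        start_day = ev.timestamp.date()
        end_day = ev.end_timestamp.date() if ev.end_timestamp is not None else start_day
        day = max(start_day, window_start)
        while day <= min(end_day, reference_date - timedelta(days=1)):
            t = n_days - (reference_date - day).days
            out[t, j] = 1
            day += timedelta(days=1)
    if n_unknown:
        logger.info("dropped %d events with unknown item ids", n_unknown)
    return out


def prune_features(X: EventTensor) -> EventTensor:
    """Drop event variables that never occur (all-zero columns), keeping order."""
    keep = np.flatnonzero(X.data.sum(axis=(0, 1)) > 0)
    if keep.size == 0:
        raise ValueError("all features are all-zero; degenerate dataset")
    return EventTensor(
        X.data[:, :, keep],
        list(X.case_ids),
        list(X.day_labels),
        [X.feature_ids[j] for j in keep],
        [X.feature_category[j] for j in keep],
    )


def collapse_time(X: EventTensor) -> np.ndarray:
    """Union over the day axis: N x F matrix with (i,f)=1 iff any x_{i,t,f}=1."""
    return X.data.max(axis=1).astype(np.uint8)


# ---------------------------------------------------------------- CSV front end


def _parse_dt(s) -> datetime | None:
    if pd.isna(s):
        return None
    return pd.Timestamp(s).to_pydatetime()


def read_admissions(admissions_csv: str | Path, diagnoses_csv: str | Path) -> list[AdmissionRecord]:
    adm = pd.read_csv(admissions_csv, dtype={"HADM_ID": str})
    dx = pd.read_csv(diagnoses_csv, dtype={"HADM_ID": str, "ICD9_CODE": str})
    codes = dx.groupby("HADM_ID")["ICD9_CODE"].apply(list).to_dict()
    records = []
    for row in adm.itertuples(index=False):
        records.append(
            AdmissionRecord(
                case_id=str(row.HADM_ID),
                discharge_datetime=_parse_dt(row.DISCHTIME),
                death_flag=bool(int(row.HOSPITAL_EXPIRE_FLAG)),
                diagnosis_codes=[c for c in codes.get(str(row.HADM_ID), []) if pd.notna(c)],
            )
        )
    return records


def read_events(
    labevents_csv: str | Path | None = None,
    procedures_csv: str | Path | None = None,
    prescriptions_csv: str | Path | None = None,
) -> list[RawEventRecord]:
    """Load event rows from any subset of the three source tables."""
    events: list[RawEventRecord] = []
    if labevents_csv is not None:
        lab = pd.read_csv(labevents_csv, dtype={"HADM_ID": str, "ITEMID": str})
        for row in lab.itertuples(index=False):
            ts = _parse_dt(row.CHARTTIME)
            if ts is None:
                continue
            flag = getattr(row, "FLAG", None)
            abnormal = isinstance(flag, str) and flag.strip().lower() == "abnormal"
            events.append(RawEventRecord(str(row.HADM_ID), ts, str(row.ITEMID), "lab", abnormal))
    if procedures_csv is not None:
        proc = pd.read_csv(procedures_csv, dtype={"HADM_ID": str, "ITEMID": str})
        for row in proc.itertuples(index=False):
            ts = _parse_dt(row.STARTTIME)
            if ts is None:
                continue
            events.append(RawEventRecord(str(row.HADM_ID), ts, str(row.ITEMID), "procedure"))
    if prescriptions_csv is not None:
        rx = pd.read_csv(prescriptions_csv, dtype={"HADM_ID": str, "DRUG": str})
        for row in rx.itertuples(index=False):
            start = _parse_dt(row.STARTDATE)
            if start is None:
                continue
            end = _parse_dt(getattr(row, "ENDDATE", None)) or start
            events.append(
                RawEventRecord(str(row.HADM_ID), start, str(row.DRUG), "prescription", None, end)
            )
    return events


def encode_dataset(
    admissions: list[AdmissionRecord],
    events: list[RawEventRecord],
    cohort_codes: list[str] | None = None,
    n_days: int = 10,
    prune: bool = True,
) -> tuple[EventTensor, OutcomeVector]:
    """Full pipeline: cohort selection, per-case encoding, pruning, labels."""
    if cohort_codes is not None:
        case_ids = select_cohort(admissions, cohort_codes)
    else:
        case_ids = sorted({a.case_id for a in admissions})
    if not case_ids:
        raise ValueError("cohort is empty")
    by_case_adm = {a.case_id: a for a in admissions}
    by_case_ev: dict[str, list[RawEventRecord]] = {c: [] for c in case_ids}
    for ev in events:
        if ev.case_id in by_case_ev:
            by_case_ev[ev.case_id].append(ev)

    # global feature vocabulary: every (category, item) seen for the cohort
    seen: dict[str, str] = {}
    for evs in by_case_ev.values():
        for ev in evs:
            seen.setdefault(ev.feature_id, ev.category)
    feature_ids = sorted(seen)
    feature_category = [seen[f] for f in feature_ids]

    mats, labels = [], []
    for cid in case_ids:
        d0, y = label_outcome(by_case_adm[cid])
        mats.append(encode_case(by_case_ev[cid], d0, n_days, feature_ids))
        labels.append(y)
    X = EventTensor(
        np.stack(mats) if mats else np.zeros((0, n_days, len(feature_ids)), dtype=np.uint8),
        case_ids,
        day_labels_for(n_days),
        feature_ids,
        feature_category,
    )
    if prune:
        X = prune_features(X)
    return X, OutcomeVector(np.array(labels), case_ids)
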