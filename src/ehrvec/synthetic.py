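"""Synthetic longitudinal EHR cohorts with planted diagnosis-event structure.

Real critical-care EHR corpora are access-restricted, so every downstream
stage of the pipeline (sequence construction, embedding training, similarity
scoring, cross-validated evaluation) is exercised on cohorts generated here.
Each synthetic patient accumulates admissions of lab, prescription and
diagnosis events; one "destined" discharge diagnosis is planted per patient,
and a disjoint set of signature lab/prescription events for that diagnosis is
emitted into the preceding admissions. The planted structure gives exact
oracles: with ``signature_strength=1`` and ``background_rate=0`` a patient's
history contains precisely the signature events of their destined diagnosis.

Recency structure: a configurable fraction of diagnoses are "recency-type" —
their signature events appear only in the admission immediately preceding the
final one. The remaining diagnoses leave their signatures in older admissions,
so exponential time-decay weighting helps the former and hurts the latter.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

_CATEGORIES = ("lab", "prescription", "diagnosis", "condition", "symptom")
_EPOCH = pd.Timestamp("2010-01-01")


@dataclass(frozen=True)
class EventRecord:
    """One timestamped medical event belonging to a patient admission."""

    patient_id: str
    admission_id: str
    timestamp: pd.Timestamp
    category: str
    code: str

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown event category: {self.category!r}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_patients:
        Number of patients to generate.
    n_lab_codes, n_rx_codes, n_dx_codes:
        Vocabulary sizes for lab tests, prescriptions and diagnoses.
    signature_size:
        Number of lab/prescription events forming each diagnosis signature.
        Signature sets are disjoint across diagnoses by construction.
    signature_strength:
        Probability that each signature event of the destined diagnosis is
        emitted into the patient's history.
    background_rate:
        Mean number of background (uniform-random lab/rx) events per
        admission; Poisson distributed.
    admissions_per_patient:
        Inclusive (min, max) range; sampled uniformly.
    gap_days:
        Inclusive (min, max) range of days between consecutive admission
        starts; sampled uniformly. Keep the max at or below 365 if admission
        chains should stay unbroken downstream.
    recency_mix:
        Fraction of diagnosis codes whose signature events are emitted only
        in the most recent prior admission (recency-type diagnoses).
    prior_dx_rate:
        Probability that the destined diagnosis is also recorded as a
        diagnosis event in each prior admission. Zero keeps every planted
        label "novel" (absent from history).
    seed:
        Base RNG seed; identical config + seed reproduces the cohort exactly.
    """

    n_patients: int = 1000
    n_lab_codes: int = 80
    n_rx_codes: int = 80
    n_dx_codes: int = 20
    signature_size: int = 4
    signature_strength: float = 0.8
    background_rate: float = 5.0
    admissions_per_patient: tuple[int, int] = (2, 5)
    gap_days: tuple[int, int] = (30, 300)
    recency_mix: float = 0.3
    prior_dx_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_lab_codes", "n_rx_codes", "n_dx_codes",
                     "signature_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("signature_strength", "recency_mix", "prior_dx_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name in ("admissions_per_patient", "gap_days"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.admissions_per_patient[0] < 2 and self.n_patients > 0:
            # one-admission patients have no history; allow but the generator
            # needs at least 2 to plant anything, so forbid outright
            raise ValueError("admissions_per_patient minimum must be >= 2")
        if self.signature_size * self.n_dx_codes > self.n_lab_codes + self.n_rx_codes:
            raise ValueError(
                "not enough lab+rx codes for disjoint signatures: need "
                f"{self.signature_size * self.n_dx_codes}, have "
                f"{self.n_lab_codes + self.n_rx_codes}")


@dataclass
class CohortTruth:
    """Ground-truth side channel for test oracles; never mixed into events.

    ``assignments`` has one row per patient: patient_id, diagnosis (raw dx
    code), recency_type (bool). ``signatures`` maps each diagnosis code to
    its list of (category, code) signature events.
    """

    assignments: pd.DataFrame
    signatures: dict[str, list[tuple[str, str]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": self.assignments.to_dict(orient="records"),
            "signatures": {d: [list(ev) for ev in evs]
                           for d, evs in self.signatures.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        assignments = pd.DataFrame(
            payload["assignments"],
            columns=["patient_id", "diagnosis", "recency_type"])
        signatures = {d: [tuple(ev) for ev in evs]
                      for d, evs in payload["signatures"].items()}
        return cls(assignments=assignments, signatures=signatures)


def _dx_code(i: int) -> str:
    # ICD-9-looking strings, e.g. "401.17"
    return f"{400 + i // 100}.{i % 100:02d}"


def generate_cohort(config: SynthConfig) -> tuple[list[EventRecord], CohortTruth]:
    """Generate a cohort of event records plus its ground-truth table.

    Returns ``(records, truth)``. Each patient receives 2+ admissions; the
    destined diagnosis is recorded in the final admission, and its signature
    events are scattered over prior admissions (only the last prior one for
    recency-type diagnoses, only older ones — when available — otherwise).
    """
    rng = np.random.default_rng(config.seed)

    lab_codes = [f"{50000 + i}" for i in range(config.n_lab_codes)]
    rx_codes = [f"RX{i:04d}" for i in range(config.n_rx_codes)]
    dx_codes = [_dx_code(i) for i in range(config.n_dx_codes)]
    n_recency = int(np.floor(config.recency_mix * config.n_dx_codes))
    recency_type = {d: i < n_recency for i, d in enumerate(dx_codes)}

    # disjoint signature sets drawn from the pooled lab+rx vocabulary
    pool = [("lab", c) for c in lab_codes] + [("prescription", c) for c in rx_codes]
    perm = rng.permutation(len(pool))
    signatures: dict[str, list[tuple[str, str]]] = {}
    for i, d in enumerate(dx_codes):
        lo = i * config.signature_size
        signatures[d] = [pool[j] for j in perm[lo:lo + config.signature_size]]

    records: list[EventRecord] = []
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p:06d}"
        n_adm = int(rng.integers(config.admissions_per_patient[0],
                                 config.admissions_per_patient[1] + 1))
        destined = dx_codes[int(rng.integers(config.n_dx_codes))] if dx_codes else None

        # admission start offsets (days from a per-patient anchor) and stays
        start = float(rng.integers(0, 365))
        starts, stays = [], []
        for _ in range(n_adm):
            starts.append(start)
            stay = int(rng.integers(1, 11))  # 1-10 day stays
            stays.append(stay)
            start += float(rng.integers(config.gap_days[0], config.gap_days[1] + 1))

        # choose the admission carrying each emitted signature event
        sig_events: list[tuple[int, str, str]] = []  # (admission index, cat, code)
        if destined is not None:
            last_prior = n_adm - 2
            if recency_type[destined]:
                candidates = [last_prior]
            elif last_prior >= 1:
                candidates = list(range(last_prior))  # strictly older admissions
            else:
                candidates = [last_prior]
            for cat, code in signatures[destined]:
                if rng.random() < config.signature_strength:
                    a = candidates[int(rng.integers(len(candidates)))]
                    sig_events.append((a, cat, code))

        for a in range(n_adm):
            aid = f"{pid}-A{a}"
            adm_start = _EPOCH + pd.Timedelta(days=starts[a])

            def stamp() -> pd.Timestamp:
                return adm_start + pd.Timedelta(
                    seconds=float(rng.random()) * stays[a] * 86400.0)

            if a == n_adm - 1:
                if destined is not None:
                    records.append(EventRecord(pid, aid, stamp(), "diagnosis", destined))
            else:
                n_bg = int(rng.poisson(config.background_rate))
                for _ in range(n_bg):
                    cat, code = pool[int(rng.integers(len(pool)))] if pool else ("lab", "0")
                    records.append(EventRecord(pid, aid, stamp(), cat, code))
                if destined is not None and rng.random() < config.prior_dx_rate:
                    records.append(EventRecord(pid, aid, stamp(), "diagnosis", destined))
            # final admission also gets background events? No: it is the
            # prediction window; only its discharge diagnoses matter downstream.

        for a, cat, code in sig_events:
            aid = f"{pid}-A{a}"
            adm_start = _EPOCH + pd.Timedelta(days=starts[a])
            ts = adm_start + pd.Timedelta(
                seconds=float(rng.random()) * stays[a] * 86400.0)
            records.append(EventRecord(pid, aid, ts, cat, code))

        if destined is not None:
            rows.append({"patient_id": pid, "diagnosis": destined,
                         "recency_type": recency_type[destined]})

    truth = CohortTruth(
        assignments=pd.DataFrame(rows, columns=["patient_id", "diagnosis",
                                                "recency_type"]),
        signatures=signatures,
    )
    return records, truth


_COLUMNS = ["patient_id", "admission_id", "timestamp", "category", "code"]


def write_event_table(cohort: Iterable[EventRecord], path: str | Path,
                      format: str = "csv") -> None:
    """Write events as a long-format table (one row per event).

    ``format`` is ``"csv"`` (quoted, ISO-8601 timestamps, UTF-8) or
    ``"jsonl"`` (one object per line, same five fields). Round-trips
    losslessly through :func:`ehrvec.sequences.read_event_table`.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC)
            writer.writerow(_COLUMNS)
            for r in cohort:
                writer.writerow([r.patient_id, r.admission_id,
                                 r.timestamp.isoformat(), r.category, r.code])
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in cohort:
                fh.write(json.dumps({
                    "patient_id": r.patient_id,
                    "admission_id": r.admission_id,
                    "timestamp": r.timestamp.isoformat(),
                    "category": r.category,
                    "code": r.code,
                }, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")
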