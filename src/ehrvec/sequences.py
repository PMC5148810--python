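"""Prefixed, time-ordered patient sequences from raw event tables.

An event table is turned into per-patient *admission chains* (maximal runs of
admissions whose consecutive start-to-start gaps are at most 365 days). For
each chain with at least two admissions, the final admission is sliced off:
its discharge diagnoses become the prediction labels and everything before it
becomes the feature history, sorted oldest to latest. Event codes are
prefixed by category ("l_" labs, "p_" prescriptions, "d_" diagnoses, "c_"
conditions, "s_" symptoms) so that identical raw identifiers from different
sources stay distinct tokens. ICD-9 diagnosis codes are kept verbatim at the
specificity the physician recorded — no hierarchy rollup.

Rare tokens are removed afterwards: a non-diagnosis token survives only if it
appears in at least 1% of sequences *and* in at least 50 distinct admissions
(both thresholds configurable, boundaries inclusive); diagnosis tokens and
labels are held to the sequence-fraction rule alone.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import EventRecord

logger = logging.getLogger(__name__)

PREFIXES = {
    "lab": "l_",
    "prescription": "p_",
    "diagnosis": "d_",
    "condition": "c_",
    "symptom": "s_",
}
DIAGNOSIS_PREFIX = "d_"


def token_text(category: str, code: str) -> str:
    try:
        return PREFIXES[category] + code
    except KeyError:
        raise ValueError(f"unknown event category: {category!r}") from None


@dataclass(frozen=True)
class Token:
    """A category-prefixed event token with its timestamp and admission."""

    text: str
    timestamp: pd.Timestamp
    category: str
    admission_id: str


@dataclass
class PatientSequence:
    """Ordered event history plus the final-admission label set.

    ``days`` holds, for each history token, the time in days between that
    event and the most recent history event ``t_latest`` (so the latest event
    has offset 0); this is the decay clock t_c used by the predictors.
    ``novel_labels`` are labels whose token never occurs in the history —
    the harder prediction task restricts scoring to these.
    """

    patient_id: str
    tokens: list[str]
    days: np.ndarray
    admission_ids: list[str]
    categories: list[str]
    label_diagnoses: frozenset[str]
    novel_labels: frozenset[str]
    t_latest: pd.Timestamp
    sequence_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Admission:
    admission_id: str
    start: pd.Timestamp
    events: list[EventRecord]


def read_event_table(path: str | Path, format: str | None = None,
                     on_error: str = "skip") -> list[EventRecord]:
    """Parse a five-column event table (CSV or JSONL) back into records.

    ``format`` is inferred from the file suffix when None. Malformed rows are
    counted and logged when ``on_error="skip"``; ``on_error="raise"`` aborts
    on the first bad row. A missing required column always raises.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif format == "jsonl":
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines()
                if line.strip()]
        df = pd.DataFrame(rows, dtype=str)
        if df.empty:
            df = pd.DataFrame(columns=["patient_id", "admission_id", "timestamp",
                                       "category", "code"])
    else:
        raise ValueError(f"unknown format: {format!r}")

    required = ["patient_id", "admission_id", "timestamp", "category", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing required columns: {missing}")

    records: list[EventRecord] = []
    n_bad = 0
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for i, row in enumerate(df.itertuples(index=False)):
        t = ts.iloc[i]
        try:
            if pd.isna(t):
                raise ValueError(f"unparseable timestamp: {row.timestamp!r}")
            records.append(EventRecord(row.patient_id, row.admission_id,
                                       t, row.category, row.code))
        except ValueError as exc:
            if on_error == "raise":
                raise
            n_bad += 1
            logger.warning("skipping malformed row %d: %s", i, exc)
    if n_bad:
        logger.warning("read_event_table: skipped %d malformed rows", n_bad)
    return records


def chain_admissions(records: Iterable[EventRecord],
                     max_gap_days: float = 365.0) -> list[list[Admission]]:
    """Group events into per-patient admission chains.

    Admissions are sorted by start time (earliest event in the admission);
    maximal runs with every consecutive start-to-start gap <= ``max_gap_days``
    form one chain. Chains with fewer than two admissions are discarded —
    they offer no history/label split. Chaining partitions the admissions:
    every admission lands in exactly one (possibly discarded) chain.
    """
    by_adm: dict[tuple[str, str], list[EventRecord]] = defaultdict(list)
    for r in records:
        by_adm[(r.patient_id, r.admission_id)].append(r)

    by_patient: dict[str, list[Admission]] = defaultdict(list)
    for (pid, aid), evs in by_adm.items():
        start = min(e.timestamp for e in evs)
        by_patient[pid].append(Admission(aid, start, evs))

    chains: list[list[Admission]] = []
    for pid in sorted(by_patient):
        adms = sorted(by_patient[pid], key=lambda a: (a.start, a.admission_id))
        run: list[Admission] = [adms[0]]
        for adm in adms[1:]:
            gap = (adm.start - run[-1].start) / pd.Timedelta(days=1)
            if gap <= max_gap_days:
                run.append(adm)
            else:
                if len(run) >= 2:
                    chains.append(run)
                run = [adm]
        if len(run) >= 2:
            chains.append(run)
    return chains


def build_sequences(chains: Sequence[list[Admission]]) -> list[PatientSequence]:
    """Slice each chain into (history, final-admission labels).

    History tokens come from every admission except the last, sorted by
    (timestamp, token text) — the text tie-break makes runs reproducible.
    One patient can contribute several sequences (one per chain).
    """
    sequences: list[PatientSequence] = []
    per_patient_count: dict[str, int] = defaultdict(int)
    for chain in chains:
        if len(chain) < 2:
            raise ValueError("chains must contain at least 2 admissions")
        pid = chain[0].events[0].patient_id
        hist: list[Token] = []
        for adm in chain[:-1]:
            for e in adm.events:
                hist.append(Token(token_text(e.category, e.code), e.timestamp,
                                  e.category, e.admission_id))
        hist.sort(key=lambda t: (t.timestamp, t.text))
        labels = frozenset(token_text(e.category, e.code)
                           for e in chain[-1].events if e.category == "diagnosis")
        if not hist:
            continue
        if not labels:
            logger.info("chain for patient %s has no final-admission diagnoses; "
                        "emitting all-negative sequence", pid)
        t_latest = hist[-1].timestamp
        days = np.array([(t_latest - t.timestamp) / pd.Timedelta(days=1)
                         for t in hist], dtype=float)
        hist_set = {t.text for t in hist}
        idx = per_patient_count[pid]
        per_patient_count[pid] += 1
        sequences.append(PatientSequence(
            patient_id=pid,
            tokens=[t.text for t in hist],
            days=days,
            admission_ids=[t.admission_id for t in hist],
            categories=[t.category for t in hist],
            label_diagnoses=labels,
            novel_labels=frozenset(l for l in labels if l not in hist_set),
            t_latest=t_latest,
            sequence_id=f"{pid}#{idx}",
        ))
    return sequences


@dataclass
class FilterReport:
    n_sequences_in: int
    n_sequences_out: int
    n_tokens_removed: int
    n_sequences_dropped_empty: int
    kept_vocabulary: dict[str, tuple[int, int]]  # token -> (seq count, adm count)
    kept_labels: set[str]


def filter_rare_events(sequences: Sequence[PatientSequence],
                       min_seq_fraction: float = 0.01,
                       min_admission_count: int = 50,
                       ) -> tuple[list[PatientSequence], FilterReport]:
    """Drop rare tokens from histories and rare diagnoses from labels.

    A non-diagnosis history token is kept iff it occurs in at least
    ``min_seq_fraction`` of sequences AND in at least ``min_admission_count``
    distinct admissions (both inclusive: a token exactly at threshold
    survives). Diagnosis tokens — in history or labels — are held only to the
    sequence-fraction rule. Sequences whose history empties out are dropped
    and counted.
    """
    if not 0.0 <= min_seq_fraction <= 1.0:
        raise ValueError("min_seq_fraction must lie in [0, 1]")
    if min_admission_count < 0:
        raise ValueError("min_admission_count must be >= 0")

    n_seq = len(sequences)
    seq_count: dict[str, int] = defaultdict(int)
    adm_sets: dict[str, set[str]] = defaultdict(set)
    for s in sequences:
        seen = set(s.tokens) | s.label_diagnoses
        for tok in seen:
            seq_count[tok] += 1
        for tok, aid in zip(s.tokens, s.admission_ids):
            adm_sets[tok].add(aid)

    min_seq_count = min_seq_fraction * n_seq
    kept: dict[str, tuple[int, int]] = {}
    for tok, sc in seq_count.items():
        ac = len(adm_sets.get(tok, ()))
        if tok.startswith(DIAGNOSIS_PREFIX):
            ok = sc >= min_seq_count
        else:
            ok = sc >= min_seq_count and ac >= min_admission_count
        if ok:
            kept[tok] = (sc, ac)

    out: list[PatientSequence] = []
    n_removed = 0
    n_dropped = 0
    for s in sequences:
        mask = [tok in kept for tok in s.tokens]
        n_removed += mask.count(False)
        if not any(mask):
            n_dropped += 1
            continue
        labels = frozenset(l for l in s.label_diagnoses if l in kept)
        toks = [t for t, m in zip(s.tokens, mask) if m]
        out.append(PatientSequence(
            patient_id=s.patient_id,
            tokens=toks,
            days=s.days[np.array(mask, dtype=bool)],
            admission_ids=[a for a, m in zip(s.admission_ids, mask) if m],
            categories=[c for c, m in zip(s.categories, mask) if m],
            label_diagnoses=labels,
            novel_labels=frozenset(l for l in labels if l not in set(toks)),
            t_latest=s.t_latest,
            sequence_id=s.sequence_id,
        ))
    report = FilterReport(
        n_sequences_in=n_seq,
        n_sequences_out=len(out),
        n_tokens_removed=n_removed,
        n_sequences_dropped_empty=n_dropped,
        kept_vocabulary=kept,
        kept_labels={t for t in kept if t.startswith(DIAGNOSIS_PREFIX)},
    )
    return out, report


def select_target_diagnoses(sequences: Sequence[PatientSequence],
                            k: int = 80) -> list[str]:
    """The k most common label diagnoses, ties broken lexicographically."""
    counts: dict[str, int] = defaultdict(int)
    for s in sequences:
        for d in s.label_diagnoses:
            counts[d] += 1
    ranked = sorted(counts, key=lambda d: (-counts[d], d))
    if len(ranked) < k:
        logger.info("only %d distinct label diagnoses (< k=%d)", len(ranked), k)
    return ranked[:k]


def write_corpus(sequences: Sequence[PatientSequence], path: str | Path) -> None:
    """Write sequences as TSV (id, history, labels) plus a day-offset sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sequences:
            fh.write(f"{s.sequence_id or s.patient_id}\t"
                     f"{' '.join(s.tokens)}\t{' '.join(sorted(s.label_diagnoses))}\n")
    sidecar = {s.sequence_id or s.patient_id: [round(float(d), 6) for d in s.days]
               for s in sequences}
    Path(str(path) + ".days.json").write_text(json.dumps(sidecar))


def read_corpus(path: str | Path) -> list[PatientSequence]:
    """Read a corpus file back (timestamps are reconstructed from offsets)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".days.json").read_text())
    out: list[PatientSequence] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        sid, hist, labels = line.split("\t")
        toks = hist.split() if hist else []
        labs = frozenset(labels.split()) if labels else frozenset()
        days = np.asarray(sidecar[sid], dtype=float)
        out.append(PatientSequence(
            patient_id=sid.split("#")[0],
            tokens=toks,
            days=days,
            admission_ids=[""] * len(toks),
            categories=[_category_of(t) for t in toks],
            label_diagnoses=labs,
            novel_labels=frozenset(l for l in labs if l not in set(toks)),
            t_latest=pd.Timestamp("2010-01-01"),
            sequence_id=sid,
        ))
    return out


_PREFIX_TO_CATEGORY = {v: k for k, v in PREFIXES.items()}


def _category_of(token: str) -> str:
    return _PREFIX_TO_CATEGORY.get(token[:2], "lab")
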