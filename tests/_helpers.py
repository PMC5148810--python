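"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ehrvec.embedding import EventEmbedding
from ehrvec.sequences import PatientSequence


def make_seq(tokens, days=None, labels=(), pid="P0", sid=None) -> PatientSequence:
    """Build a PatientSequence directly; ``days`` are t_c offsets (days
    before the latest history event)."""
    days = np.zeros(len(tokens)) if days is None else np.asarray(days, float)
    labels = frozenset(labels)
    return PatientSequence(
        patient_id=pid,
        tokens=list(tokens),
        days=days,
        admission_ids=[f"{pid}-A0"] * len(tokens),
        categories=["lab"] * len(tokens),
        label_diagnoses=labels,
        novel_labels=frozenset(l for l in labels if l not in set(tokens)),
        t_latest=pd.Timestamp("2010-06-01"),
        sequence_id=sid or f"{pid}#0",
    )


def toy_model(vectors: dict[str, list[float]]) -> EventEmbedding:
    """An EventEmbedding with hand-set vectors (no training)."""
    dim = len(next(iter(vectors.values())))
    m = EventEmbedding(size=dim)
    m.vocab_ = list(vectors)
    m.index_ = {t: i for i, t in enumerate(m.vocab_)}
    m.vectors_ = np.array([vectors[t] for t in m.vocab_], dtype=float)
    m.counts_ = np.ones(len(m.vocab_), dtype=np.int64)
    m.context_vectors_ = np.zeros_like(m.vectors_)
    return m


def signature_tokens(truth, diagnosis_code) -> set[str]:
    """Prefixed token texts of a diagnosis's signature events."""
    prefix = {"lab": "l_", "prescription": "p_"}
    return {prefix[cat] + code for cat, code in truth.signatures[diagnosis_code]}
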