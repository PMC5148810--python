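"""Similarity-based diagnosis risk scorers over embedded event histories.

All four methods score a (patient sequence, diagnosis) pair; recency is
handled by the exponential temporal factor e^(-lambda * t_c), where t_c is
the age of event c in days relative to the latest history event:

PDPS (patient-diagnosis projection similarity)
    project the history into the embedding space as the decay-weighted sum
    of its event vectors, then take the cosine to the diagnosis vector.
PDES (patient-diagnosis event similarity)
    precompute S, the (events x diagnoses) cosine similarity matrix
    (negative entries clipped to 0 by default); the score is the
    decay-weighted mean of S[c, d] over the history, normalized by
    sigma = sum of temporal factors so that scores are comparable across
    history lengths.
CF (collaborative filtering)
    weighted vote among training patients: each neighbor votes for the
    diagnoses it eventually received, weighted by the (non-negative) cosine
    between the two patients' projections.
LR baseline
    per-diagnosis logistic regression on decay-weighted one-hot event counts
    — no embedding, the standard-learning yardstick.

Estimators follow scikit-learn conventions: parameters in ``__init__``,
fitted state in trailing-underscore attributes, ``decision_function``
returning an (n_sequences, n_targets) score matrix with NaN where a pair
could not be scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .embedding import EventEmbedding, cosine
from .sequences import PatientSequence

logger = logging.getLogger(__name__)

__all__ = [
    "temporal_factor", "project_patient", "PatientProjection",
    "SimilarityMatrix", "build_similarity_matrix",
    "pdps_score", "pdes_score", "cf_score",
    "PDPSClassifier", "PDESClassifier", "CFClassifier",
    "DecayedLogisticBaseline",
]


def temporal_factor(t_c: float | np.ndarray, lam: float) -> float | np.ndarray:
    """e^(-lambda * t_c): the weight of an event t_c days before the latest.

    lambda is per day and must be >= 0; lambda=0 gives every event weight 1.
    """
    if lam < 0:
        raise ValueError("decay rate lambda must be >= 0")
    t = np.asarray(t_c, dtype=float)
    if np.any(t < 0):
        raise ValueError("event age t_c must be >= 0")
    out = np.exp(-lam * t)
    return float(out) if np.isscalar(t_c) else out


@dataclass
class PatientProjection:
    """Decay-weighted sum of history event vectors plus the weight mass."""

    vector: np.ndarray
    weight_sum: float
    n_oov: int = 0


def project_patient(seq: PatientSequence, model: EventEmbedding,
                    lam: float = 0.0) -> PatientProjection:
    """Sum_c e^(-lambda t_c) V[c] over the history; OOV tokens are skipped
    and counted; all-OOV histories raise."""
    ids, days = [], []
    n_oov = 0
    for tok, d in zip(seq.tokens, seq.days):
        i = model.index_.get(tok)
        if i is None:
            n_oov += 1
        else:
            ids.append(i)
            days.append(d)
    if not ids:
        raise ValueError(
            f"cannot project sequence {seq.sequence_id or seq.patient_id}: "
            "every history token is out of vocabulary")
    w = temporal_factor(np.asarray(days, dtype=float), lam)
    vec = w @ model.vectors_[ids]
    return PatientProjection(vector=vec, weight_sum=float(w.sum()), n_oov=n_oov)


@dataclass
class SimilarityMatrix:
    """Event-by-diagnosis cosine table S (optionally clipped at zero)."""

    tokens: list[str]
    targets: list[str]
    values: np.ndarray          # (N, D)
    clipped: bool

    def __post_init__(self) -> None:
        self.token_index = {t: i for i, t in enumerate(self.tokens)}
        self.target_index = {t: i for i, t in enumerate(self.targets)}

    def column(self, diagnosis: str) -> np.ndarray:
        try:
            return self.values[:, self.target_index[diagnosis]]
        except KeyError:
            raise KeyError(f"diagnosis not in similarity matrix: {diagnosis!r}") from None


def build_similarity_matrix(model: EventEmbedding, target_diagnoses: Sequence[str],
                            clip_negative: bool = True) -> SimilarityMatrix:
    """S[c, d] = cos(V[c], V[d]) over the whole vocabulary x targets.

    Clipping negatives to zero is the default: empirically, dissimilar
    events carry no useful anti-evidence and negative entries only add
    noise to the weighted mean.
    """
    missing = [d for d in target_diagnoses if d not in model.index_]
    if missing:
        raise KeyError(f"target diagnoses not in vocabulary: {missing}")
    V = model.vectors_
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = V / norms
    cols = np.array([model.index_[d] for d in target_diagnoses])
    S = U @ U[cols].T
    np.clip(S, -1.0, 1.0, out=S)
    if clip_negative:
        S = np.maximum(S, 0.0)
    return SimilarityMatrix(tokens=list(model.vocab_),
                            targets=list(target_diagnoses),
                            values=S, clipped=clip_negative)


# ------------------------------------------------------- functional scorers

def pdps_score(seq: PatientSequence, diagnosis_token: str,
               model: EventEmbedding, lam: float = 0.0) -> float:
    """cos(projection(seq), V[d]) in [-1, 1]."""
    proj = project_patient(seq, model, lam)
    return cosine(proj.vector, model.get_vector(diagnosis_token))


def pdes_score(seq: PatientSequence, diagnosis_token: str,
               S: SimilarityMatrix, lam: float = 0.0,
               clip_score: bool = False) -> float:
    """(1/sigma) sum_c e^(-lambda t_c) S[c, d], sigma the temporal-factor sum.

    OOV history tokens contribute nothing (neither to the sum nor to sigma).
    """
    col = S.column(diagnosis_token)
    num = 0.0
    sigma = 0.0
    for tok, d in zip(seq.tokens, seq.days):
        i = S.token_index.get(tok)
        if i is None:
            continue
        w = temporal_factor(float(d), lam)
        num += w * col[i]
        sigma += w
    if sigma == 0.0:
        raise ValueError("pdes_score undefined: no in-vocabulary history events")
    score = num / sigma
    return max(0.0, score) if clip_score else score


def cf_score(seq_projection: PatientProjection | np.ndarray, diagnosis_token: str,
             train_projections: Sequence[tuple[np.ndarray, frozenset[str]]],
             k: int | None = None) -> float:
    """Weighted vote among the k nearest training patients.

    Weight of a neighbor = max(0, cosine(test projection, neighbor
    projection)); score = (weight of neighbors labeled with d) / (total
    weight). k=None votes over the whole training set.
    """
    if not train_projections:
        raise ValueError("cf_score requires a non-empty training set")
    v = seq_projection.vector if isinstance(seq_projection, PatientProjection) \
        else np.asarray(seq_projection, dtype=float)
    sims = np.empty(len(train_projections))
    for i, (p, _) in enumerate(train_projections):
        sims[i] = cosine(v, p)
    weights = np.maximum(sims, 0.0)
    if k is not None and k < len(train_projections):
        order = np.argsort(-sims, kind="stable")[:k]
    else:
        order = np.arange(len(train_projections))
    total = weights[order].sum()
    if total == 0.0:
        return 0.0
    hit = sum(weights[i] for i in order
              if diagnosis_token in train_projections[i][1])
    return float(hit / total)


# ----------------------------------------------------------------- mixins

class _TargetedScorer(BaseEstimator):
    """Shared fit plumbing: resolve targets and remember the label sets."""

    def _resolve_targets(self, X: Sequence[PatientSequence]) -> list[str]:
        if self.targets is not None:
            return list(self.targets)
        from .sequences import select_target_diagnoses
        return select_target_diagnoses(X, k=getattr(self, "target_k", 80))

    def predict(self, X: Sequence[PatientSequence]) -> np.ndarray:
        """Binary calls at per-target thresholds (0.5 unless set by the
        evaluation harness via ``thresholds_``)."""
        scores = self.decision_function(X)
        thr = getattr(self, "thresholds_", np.full(scores.shape[1], 0.5))
        return (scores >= thr).astype(int)


class PDPSClassifier(_TargetedScorer):
    """Patient-diagnosis projection similarity scorer.

    Scores are cosines in [-1, 1]; ranking, not calibration, is the point.
    """

    def __init__(self, embedding: EventEmbedding | None = None,
                 lam: float = 0.0, targets: Sequence[str] | None = None,
                 target_k: int = 80):
        self.embedding = embedding
        self.lam = lam
        self.targets = targets
        self.target_k = target_k

    def fit(self, X: Sequence[PatientSequence], y=None) -> "PDPSClassifier":
        if self.embedding is None or not hasattr(self.embedding, "vectors_"):
            raise ValueError("PDPSClassifier requires a fitted EventEmbedding")
        targets = self._resolve_targets(X)
        self.targets_ = [t for t in targets if t in self.embedding.index_]
        if len(self.targets_) < len(targets):
            logger.warning("dropped %d target diagnoses missing from vocabulary",
                           len(targets) - len(self.targets_))
        cols = [self.embedding.index_[d] for d in self.targets_]
        D = self.embedding.vectors_[cols]
        norms = np.linalg.norm(D, axis=1)
        norms[norms == 0] = 1.0
        self._target_unit = D / norms[:, None]
        return self

    def decision_function(self, X: Sequence[PatientSequence]) -> np.ndarray:
        out = np.full((len(X), len(self.targets_)), np.nan)
        for i, s in enumerate(X):
            try:
                proj = project_patient(s, self.embedding, self.lam)
            except ValueError:
                continue
            nv = np.linalg.norm(proj.vector)
            if nv == 0:
                continue
            out[i] = self._target_unit @ (proj.vector / nv)
        return out


class PDESClassifier(_TargetedScorer):
    """Patient-diagnosis event similarity scorer (similarity-matrix based)."""

    def __init__(self, embedding: EventEmbedding | None = None,
                 lam: float = 0.0, targets: Sequence[str] | None = None,
                 target_k: int = 80, clip_negative: bool = True,
                 clip_score: bool = False):
        self.embedding = embedding
        self.lam = lam
        self.targets = targets
        self.target_k = target_k
        self.clip_negative = clip_negative
        self.clip_score = clip_score

    def fit(self, X: Sequence[PatientSequence], y=None) -> "PDESClassifier":
        if self.embedding is None or not hasattr(self.embedding, "vectors_"):
            raise ValueError("PDESClassifier requires a fitted EventEmbedding")
        targets = self._resolve_targets(X)
        self.targets_ = [t for t in targets if t in self.embedding.index_]
        self.similarity_matrix_ = build_similarity_matrix(
            self.embedding, self.targets_, clip_negative=self.clip_negative)
        return self

    def decision_function(self, X: Sequence[PatientSequence]) -> np.ndarray:
        S = self.similarity_matrix_
        out = np.full((len(X), len(self.targets_)), np.nan)
        for i, s in enumerate(X):
            ids, days = [], []
            for tok, d in zip(s.tokens, s.days):
                j = S.token_index.get(tok)
                if j is not None:
                    ids.append(j)
                    days.append(d)
            if not ids:
                continue
            w = temporal_factor(np.asarray(days, dtype=float), self.lam)
            row = (w @ S.values[ids]) / w.sum()
            out[i] = np.maximum(row, 0.0) if self.clip_score else row
        return out


class CFClassifier(_TargetedScorer):
    """Collaborative-filtering weighted vote over projected training patients."""

    def __init__(self, embedding: EventEmbedding | None = None,
                 lam: float = 0.0, targets: Sequence[str] | None = None,
                 target_k: int = 80, k: int | None = None):
        self.embedding = embedding
        self.lam = lam
        self.targets = targets
        self.target_k = target_k
        self.k = k

    def fit(self, X: Sequence[PatientSequence], y=None) -> "CFClassifier":
        if self.embedding is None or not hasattr(self.embedding, "vectors_"):
            raise ValueError("CFClassifier requires a fitted EventEmbedding")
        if len(X) == 0:
            raise ValueError("CFClassifier requires a non-empty training set")
        self.targets_ = self._resolve_targets(X)
        vecs, labels = [], []
        for s in X:
            try:
                proj = project_patient(s, self.embedding, self.lam)
            except ValueError:
                continue
            vecs.append(proj.vector)
            labels.append(s.label_diagnoses)
        self._train_matrix = np.vstack(vecs)
        norms = np.linalg.norm(self._train_matrix, axis=1)
        norms[norms == 0] = 1.0
        self._train_unit = self._train_matrix / norms[:, None]
        self._label_matrix = np.zeros((len(labels), len(self.targets_)))
        tindex = {d: j for j, d in enumerate(self.targets_)}
        for i, labs in enumerate(labels):
            for d in labs:
                j = tindex.get(d)
                if j is not None:
                    self._label_matrix[i, j] = 1.0
        self.train_projections_ = list(zip(self._train_matrix, labels))
        return self

    def decision_function(self, X: Sequence[PatientSequence]) -> np.ndarray:
        out = np.full((len(X), len(self.targets_)), np.nan)
        n_train = self._train_unit.shape[0]
        for i, s in enumerate(X):
            try:
                proj = project_patient(s, self.embedding, self.lam)
            except ValueError:
                continue
            nv = np.linalg.norm(proj.vector)
            if nv == 0:
                continue
            sims = self._train_unit @ (proj.vector / nv)
            w = np.maximum(sims, 0.0)
            if self.k is not None and self.k < n_train:
                sel = np.argsort(-sims, kind="stable")[:self.k]
            else:
                sel = slice(None)
            total = w[sel].sum()
            if total == 0.0:
                out[i] = 0.0
            else:
                out[i] = (w[sel] @ self._label_matrix[sel]) / total
        return out


class DecayedLogisticBaseline(_TargetedScorer):
    """Per-diagnosis L2 logistic regression on decayed one-hot features.

    Feature vector entry c = sum over occurrences of event c of
    e^(-lambda t_c); with lambda=0 these are raw event counts.
    """

    def __init__(self, lam: float = 0.0, targets: Sequence[str] | None = None,
                 target_k: int = 80, C: float = 1.0):
        self.lam = lam
        self.targets = targets
        self.target_k = target_k
        self.C = C

    def _features(self, X: Sequence[PatientSequence]) -> np.ndarray:
        F = np.zeros((len(X), len(self.vocabulary_)))
        for i, s in enumerate(X):
            for tok, d in zip(s.tokens, s.days):
                j = self._feat_index.get(tok)
                if j is not None:
                    F[i, j] += temporal_factor(float(d), self.lam)
        return F

    def fit(self, X: Sequence[PatientSequence], y=None) -> "DecayedLogisticBaseline":
        self.targets_ = self._resolve_targets(X)
        vocab = sorted({t for s in X for t in s.tokens})
        self.vocabulary_ = vocab
        self._feat_index = {t: j for j, t in enumerate(vocab)}
        F = self._features(X)
        self.models_: dict[str, LogisticRegression | float] = {}
        for d in self.targets_:
            yb = np.array([1 if d in s.label_diagnoses else 0 for s in X])
            if yb.min() == yb.max():
                warnings.warn(f"single-class training labels for {d}; "
                              "fitting constant scorer", RuntimeWarning)
                self.models_[d] = float(yb[0])
                continue
            clf = LogisticRegression(C=self.C, solver="liblinear",
                                     random_state=0)
            clf.fit(F, yb)
            self.models_[d] = clf
        return self

    def decision_function(self, X: Sequence[PatientSequence]) -> np.ndarray:
        F = self._features(X)
        out = np.full((len(X), len(self.targets_)), np.nan)
        for j, d in enumerate(self.targets_):
            m = self.models_[d]
            if isinstance(m, float):
                out[:, j] = m
            else:
                out[:, j] = m.predict_proba(F)[:, 1]
        return out


def lr_baseline_fit(train_seqs: Sequence[PatientSequence], diagnosis_token: str,
                    lam: float = 0.0) -> DecayedLogisticBaseline:
    """Fit the decayed logistic baseline for one diagnosis."""
    return DecayedLogisticBaseline(lam=lam, targets=[diagnosis_token]).fit(train_seqs)


def lr_baseline_score(scorer: DecayedLogisticBaseline,
                      seq: PatientSequence) -> float:
    return float(scorer.decision_function([seq])[0, 0])
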