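"""Cross-validated multi-label evaluation of the diagnosis scorers.

The task: each patient sequence may be labeled with several discharge
diagnoses from its final admission; every (sequence, target diagnosis) pair
is an independent binary prediction. Folds are grouped by patient so that a
patient's multiple sequences never straddle the train/test divide. Inside
each fold, everything learnable — the embedding, the target list, the
similarity matrix, balancing duplicates, decision thresholds — is derived
from the training fold alone.

Two scoring modes: ``all`` scores every pair; ``novel`` scores only pairs
whose diagnosis never occurs in the sequence's history — the harder task of
predicting a genuinely new diagnosis, since chronic conditions trivially
recur. AUC uses the Mann-Whitney rank formulation with ties counted half;
decision thresholds maximize F1 on training-fold scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .embedding import EventEmbedding, build_corpus
from .predictors import (CFClassifier, DecayedLogisticBaseline, PDESClassifier,
                         PDPSClassifier, SimilarityMatrix)
from .sequences import DIAGNOSIS_PREFIX, PatientSequence, select_target_diagnoses

logger = logging.getLogger(__name__)

METHODS = ("cf", "pdes", "pdps", "lr")


@dataclass
class EvalConfig:
    """Evaluation-harness parameters.

    ``mode="novel"`` restricts scoring to diagnoses absent from history;
    ``balance`` duplicates training sequences until every target diagnosis
    reaches ``balance_floor`` of the training fold.
    """

    n_folds: int = 10
    target_k: int = 80
    mode: str = "novel"
    balance: bool = False
    balance_floor: float = 0.08
    lam: float = 0.0
    seed: int = 0
    threshold_objective: str = "f1"   # or "youden"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 <= self.balance_floor < 1.0:
            raise ValueError("balance_floor must lie in [0, 1)")
        if self.mode not in {"novel", "all"}:
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass
class EvaluationReport:
    """Per-(diagnosis, method) metrics plus aggregates over targets."""

    table: pd.DataFrame       # diagnosis, method, auc, accuracy, f1, threshold,
                              # n_pos, n_scored
    aggregates: dict
    skipped: list

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    def aggregates_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.aggregates, indent=1, sort_keys=True))


def kfold_split(sequences: Sequence[PatientSequence], n_folds: int,
                seed: int = 0) -> np.ndarray:
    """Patient-grouped fold assignment (one fold index per sequence).

    Patients are shuffled deterministically and dealt into folds whose
    patient counts differ by at most one; every sequence of a patient shares
    that patient's fold.
    """
    patients = sorted({s.patient_id for s in sequences})
    if len(patients) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} patients, "
                         f"have {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    fold_of = {p: i % n_folds for i, p in enumerate(order)}
    return np.array([fold_of[s.patient_id] for s in sequences], dtype=int)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties half.

    Raises on single-class inputs — the caller decides whether to skip.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(s)          # average ranks handle ties as 1/2
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(scores: Sequence[float], labels: Sequence[int],
                     objective: str = "f1") -> tuple[float, float]:
    """Threshold maximizing F1 (or Youden's J) on the given scores.

    Candidates are midpoints between consecutive sorted unique scores plus
    one below the minimum (predict-all-positive); prediction is
    score >= threshold. Ties prefer the lower threshold (higher recall).
    Returns (threshold, achieved objective value).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("threshold undefined for single-class labels")
    uniq = np.unique(s)
    candidates = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        if objective == "f1":
            v = _f1(tp, fp, fn)
        elif objective == "youden":
            tn = n_neg - fp
            v = tp / n_pos + tn / n_neg - 1.0
        else:
            raise ValueError(f"unknown objective: {objective!r}")
        if v > best_v:       # strict: ties keep the earlier (lower) threshold
            best_t, best_v = float(t), float(v)
    return best_t, best_v


def balance_dataset(train_sequences: Sequence[PatientSequence],
                    target_diagnoses: Sequence[str], floor: float = 0.08,
                    seed: int = 0, max_rounds: int = 100000
                    ) -> list[PatientSequence]:
    """Duplicate random sequences until every target reaches ``floor``.

    While some target diagnosis labels fewer than ``floor`` of the current
    total, a uniformly random sequence containing the most deficient target
    (ties lexicographic) is duplicated. Targets absent from the training set
    cannot be balanced and are logged and skipped. Duplicating for one
    target can dilute another, so joint feasibility is not guaranteed;
    ``max_rounds`` bounds the loop and a failure to converge raises.
    Training-fold use only — duplicated test sequences would corrupt metrics.
    """
    out = list(train_sequences)
    holders = {d: [s for s in train_sequences if d in s.label_diagnoses]
               for d in target_diagnoses}
    balanceable = sorted(d for d, h in holders.items() if h)
    for d in sorted(set(target_diagnoses) - set(balanceable)):
        logger.warning("cannot balance %s: absent from training folds", d)
    counts = {d: len(holders[d]) for d in balanceable}
    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        total = len(out)
        deficits = [(counts[d] / total - floor, d) for d in balanceable]
        deficits.sort()
        if not deficits or deficits[0][0] >= 0:
            return out
        _, d = deficits[0]
        pick = holders[d][int(rng.integers(len(holders[d])))]
        out.append(pick)
        for dd in pick.label_diagnoses:
            if dd in counts:
                counts[dd] += 1
    raise RuntimeError(
        f"balance_dataset did not converge in {max_rounds} rounds; "
        f"floor={floor} is jointly infeasible for these targets")


def top_contributing_events(diagnosis: str, S: SimilarityMatrix, n: int
                            ) -> list[tuple[str, float]]:
    """The n non-diagnosis events most similar to ``diagnosis`` in S.

    This is the interpretability view: the events the similarity scorers
    treat as leading indicators of the diagnosis.
    """
    col = S.column(diagnosis)
    cand = [(t, float(col[i])) for i, t in enumerate(S.tokens)
            if not t.startswith(DIAGNOSIS_PREFIX)]
    cand.sort(key=lambda tv: (-tv[1], tv[0]))
    return cand[:n]


def _make_scorer(name: str, embedding: EventEmbedding, targets: list[str],
                 lam: float):
    if name == "pdps":
        return PDPSClassifier(embedding=embedding, lam=lam, targets=targets)
    if name == "pdes":
        return PDESClassifier(embedding=embedding, lam=lam, targets=targets)
    if name == "cf":
        return CFClassifier(embedding=embedding, lam=lam, targets=targets)
    if name == "lr":
        return DecayedLogisticBaseline(lam=lam, targets=targets)
    raise ValueError(f"unknown method: {name!r}")


def _novel_mask(seqs: Sequence[PatientSequence], targets: list[str]) -> np.ndarray:
    """True where target d is absent from the sequence history."""
    mask = np.ones((len(seqs), len(targets)), dtype=bool)
    for i, s in enumerate(seqs):
        hist = set(s.tokens)
        for j, d in enumerate(targets):
            if d in hist:
                mask[i, j] = False
    return mask


def evaluate(sequences: Sequence[PatientSequence],
             methods: Sequence[str] = ("pdps",),
             config: EvalConfig | None = None,
             embed_params: dict | None = None) -> EvaluationReport:
    """Patient-grouped k-fold evaluation of the requested methods.

    Per fold: target diagnoses are selected on the training fold, the
    embedding is trained on training histories + training labels, each
    method is fitted and scored, and F1-optimal thresholds are chosen on the
    training-fold scores. Test scores are pooled across folds per
    (diagnosis, method); AUC is computed on the pooled scores, accuracy and
    F1 from the pooled thresholded predictions.
    """
    config = config or EvalConfig()
    embed_params = dict(embed_params or {})
    embed_params.setdefault("seed", config.seed)

    folds = kfold_split(sequences, config.n_folds, config.seed)
    pooled: dict[tuple[str, str], dict[str, list]] = {}
    skipped: list[dict] = []

    for fold in range(config.n_folds):
        train = [s for s, f in zip(sequences, folds) if f != fold]
        test = [s for s, f in zip(sequences, folds) if f == fold]
        if not train or not test:
            continue
        targets = select_target_diagnoses(train, k=config.target_k)
        if config.balance:
            train = balance_dataset(train, targets, floor=config.balance_floor,
                                    seed=config.seed + fold)
        embedding = EventEmbedding(**embed_params).fit(
            build_corpus(train, include_labels=True))
        embedding.trained_on_fold_ = fold     # provenance: training folds only
        targets = [d for d in targets if d in embedding.index_]

        label_mat_train = _label_matrix(train, targets)
        label_mat_test = _label_matrix(test, targets)
        if config.mode == "novel":
            mask_train = _novel_mask(train, targets)
            mask_test = _novel_mask(test, targets)
        else:
            mask_train = np.ones((len(train), len(targets)), dtype=bool)
            mask_test = np.ones((len(test), len(targets)), dtype=bool)

        for name in methods:
            scorer = _make_scorer(name, embedding, targets, config.lam)
            scorer.fit(train)
            scorer.trained_on_fold_ = fold
            s_train = scorer.decision_function(train)
            s_test = scorer.decision_function(test)
            for j, d in enumerate(targets):
                mtr = mask_train[:, j] & ~np.isnan(s_train[:, j])
                mte = mask_test[:, j] & ~np.isnan(s_test[:, j])
                ytr = label_mat_train[mtr, j]
                yte = label_mat_test[mte, j]
                if mte.sum() == 0:
                    skipped.append({"fold": fold, "diagnosis": d, "method": name,
                                    "reason": "no scorable test pairs"})
                    continue
                if ytr.size == 0 or ytr.min() == ytr.max():
                    skipped.append({"fold": fold, "diagnosis": d, "method": name,
                                    "reason": "single-class training labels"})
                    continue
                thr, _ = select_threshold(s_train[mtr, j], ytr,
                                          objective=config.threshold_objective)
                key = (d, name)
                bucket = pooled.setdefault(key, {"scores": [], "labels": [],
                                                 "preds": [], "thresholds": []})
                bucket["scores"].extend(s_test[mte, j].tolist())
                bucket["labels"].extend(yte.tolist())
                bucket["preds"].extend((s_test[mte, j] >= thr).astype(int).tolist())
                bucket["thresholds"].append(thr)

    rows = []
    for (d, name), b in sorted(pooled.items()):
        y = np.asarray(b["labels"], dtype=int)
        pred = np.asarray(b["preds"], dtype=int)
        n_pos = int(y.sum())
        row = {"diagnosis": d, "method": name,
               "threshold": float(np.mean(b["thresholds"])),
               "n_pos": n_pos, "n_scored": len(y)}
        if 0 < n_pos < len(y):
            row["auc"] = auc(b["scores"], y)
        else:
            row["auc"] = np.nan
            skipped.append({"fold": "pooled", "diagnosis": d, "method": name,
                            "reason": "single-class pooled labels"})
        row["accuracy"] = float((pred == y).mean())
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        row["f1"] = _f1(tp, fp, fn)
        rows.append(row)

    table = pd.DataFrame(rows, columns=["diagnosis", "method", "auc", "accuracy",
                                        "f1", "threshold", "n_pos", "n_scored"])
    aggregates = {}
    for name in methods:
        sub = table[table["method"] == name]["auc"].dropna()
        aggregates[name] = {
            "mean_auc": float(sub.mean()) if len(sub) else float("nan"),
            "median_auc": float(sub.median()) if len(sub) else float("nan"),
            "n_targets": int(len(sub)),
        }
    if skipped:
        logger.info("evaluation skipped %d (fold, diagnosis, method) cells",
                    len(skipped))
    return EvaluationReport(table=table, aggregates=aggregates, skipped=skipped)


def _label_matrix(seqs: Sequence[PatientSequence], targets: list[str]) -> np.ndarray:
    M = np.zeros((len(seqs), len(targets)), dtype=int)
    tindex = {d: j for j, d in enumerate(targets)}
    for i, s in enumerate(seqs):
        for d in s.label_diagnoses:
            j = tindex.get(d)
            if j is not None:
                M[i, j] = 1
    return M


def sweep_lambda(sequences: Sequence[PatientSequence],
                 lambdas: Sequence[float] = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1),
                 method: str = "pdps", config: EvalConfig | None = None,
                 embed_params: dict | None = None) -> pd.DataFrame:
    """Per-target AUC as a function of the decay rate.

    The embedding does not depend on lambda, so a single train/test split is
    trained once per fold and only the scoring is repeated per lambda.
    Returns a long DataFrame (lambda, diagnosis, auc).
    """
    config = config or EvalConfig()
    embed_params = dict(embed_params or {})
    embed_params.setdefault("seed", config.seed)
    folds = kfold_split(sequences, config.n_folds, config.seed)

    pooled: dict[tuple[float, str], dict[str, list]] = {}
    for fold in range(config.n_folds):
        train = [s for s, f in zip(sequences, folds) if f != fold]
        test = [s for s, f in zip(sequences, folds) if f == fold]
        if not train or not test:
            continue
        targets = select_target_diagnoses(train, k=config.target_k)
        embedding = EventEmbedding(**embed_params).fit(
            build_corpus(train, include_labels=True))
        targets = [d for d in targets if d in embedding.index_]
        label_mat = _label_matrix(test, targets)
        mask = (_novel_mask(test, targets) if config.mode == "novel"
                else np.ones((len(test), len(targets)), dtype=bool))
        for lam in lambdas:
            scorer = _make_scorer(method, embedding, targets, float(lam))
            scorer.fit(train)
            s_test = scorer.decision_function(test)
            for j, d in enumerate(targets):
                m = mask[:, j] & ~np.isnan(s_test[:, j])
                bucket = pooled.setdefault((float(lam), d),
                                           {"scores": [], "labels": []})
                bucket["scores"].extend(s_test[m, j].tolist())
                bucket["labels"].extend(label_mat[m, j].tolist())

    rows = []
    for (lam, d), b in sorted(pooled.items()):
        y = np.asarray(b["labels"], dtype=int)
        value = auc(b["scores"], y) if 0 < y.sum() < len(y) else np.nan
        rows.append({"lam": lam, "diagnosis": d, "auc": value})
    return pd.DataFrame(rows, columns=["lam", "diagnosis", "auc"])
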