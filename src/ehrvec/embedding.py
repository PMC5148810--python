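"""Contextual embeddings of medical event tokens.

Tokens are embedded with a two-layer shallow network trained by stochastic
gradient descent with negative sampling — the word2vec family — over patient
event sequences, in three modes:

``skipgram``
    the center token predicts each context token within ``window`` positions;
``cbow``
    the mean of the context vectors predicts the center token;
``dynamic``
    skip-gram pair generation with an extra *time* constraint: a context
    token must lie within ``window`` positions AND within
    ``dynamic_horizon_days`` of the center token's timestamp (preceding and
    succeeding sides filtered independently). This respects the irregular
    sampling of clinical events: two adjacent tokens can be years apart.

The trainer is deterministic for a fixed seed (single worker, pre-drawn
negatives, no random window shrinking) — reproducibility is part of the
contract, so the usual word2vec reduced-window subsampling is deliberately
omitted. Noise distribution is the unigram frequency raised to 3/4.

The analytic gradients used by the SGD kernels are also exposed in plain
NumPy (:func:`sg_loss_and_grads`, :func:`cbow_loss_and_grads`) so they can be
verified against numerical differentiation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .sequences import PatientSequence

__all__ = [
    "EventEmbedding", "train_embeddings", "cosine", "nearest_tokens",
    "project_2d", "generate_pairs", "build_corpus",
    "sg_loss_and_grads", "cbow_loss_and_grads",
]

_NOISE_EXPONENT = 0.75
_NOISE_TABLE_SIZE = 1 << 20
_MIN_ALPHA_FRACTION = 1e-4


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity dot(a,b)/(|a||b|); raises on a zero-norm input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(a, b) / (na * nb))


# ----------------------------------------------------------------- pair gen

def generate_pairs(indices: np.ndarray, days: np.ndarray | None,
                   window: int, mode: str = "skipgram",
                   horizon_days: float | None = None,
                   anchor: str = "center") -> tuple[np.ndarray, np.ndarray]:
    """(center, context) training pairs for one sentence.

    In ``dynamic`` mode a pair additionally requires the two tokens'
    timestamps to differ by at most ``horizon_days`` (``anchor="center"``),
    or — with ``anchor="end"`` — both tokens to lie within ``horizon_days``
    of the sequence end, which amounts to discarding older events entirely.
    Pair order: for each positional offset, preceding-context pairs then
    succeeding-context pairs.
    """
    idx = np.asarray(indices, dtype=np.int32)
    n = idx.shape[0]
    if n < 2:
        return (np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32))
    use_time = mode == "dynamic" and horizon_days is not None and np.isfinite(horizon_days)
    if mode == "dynamic" and days is None:
        raise ValueError("dynamic mode requires per-token day offsets")
    if use_time and anchor == "end":
        keep = np.asarray(days, dtype=float) <= horizon_days
        idx = idx[keep]
        days = np.asarray(days, dtype=float)[keep]
        n = idx.shape[0]
        use_time = False  # prefilter is the whole constraint
        if n < 2:
            return (np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32))

    centers, contexts = [], []
    for off in range(1, min(window, n - 1) + 1):
        a, b = idx[:-off], idx[off:]  # token a precedes token b by `off`
        if use_time:
            d = np.asarray(days, dtype=float)
            ok = np.abs(d[:-off] - d[off:]) <= horizon_days
            a, b = a[ok], b[ok]
        centers.append(b)   # preceding context
        contexts.append(a)
        centers.append(a)   # succeeding context
        contexts.append(b)
    return (np.concatenate(centers).astype(np.int32),
            np.concatenate(contexts).astype(np.int32))


# ------------------------------------------------------- reference gradients

def sg_loss_and_grads(v_c: np.ndarray, u_o: np.ndarray, U_neg: np.ndarray):
    """Skip-gram negative-sampling loss and analytic gradients.

    L = -log s(u_o.v_c) - sum_k log s(-u_k.v_c), s the logistic function.
    Returns (loss, grad_v_c, grad_u_o, grad_U_neg).
    """
    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    f_pos = float(np.dot(u_o, v_c))
    f_neg = U_neg @ v_c
    loss = -np.log(sig(f_pos)) - np.sum(np.log(sig(-f_neg)))
    g_pos = sig(f_pos) - 1.0
    g_neg = sig(f_neg)                      # shape (k,)
    grad_v = g_pos * u_o + U_neg.T @ g_neg
    grad_uo = g_pos * v_c
    grad_Uneg = np.outer(g_neg, v_c)
    return float(loss), grad_v, grad_uo, grad_Uneg


def cbow_loss_and_grads(V_ctx: np.ndarray, u_o: np.ndarray, U_neg: np.ndarray):
    """CBOW negative-sampling loss with mean-of-context hidden layer.

    h = mean(V_ctx); L = -log s(u_o.h) - sum_k log s(-u_k.h).
    Returns (loss, grad_V_ctx, grad_u_o, grad_U_neg); the context gradient is
    shared (each row receives grad_h / n_ctx).
    """
    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    n_ctx = V_ctx.shape[0]
    h = V_ctx.mean(axis=0)
    f_pos = float(np.dot(u_o, h))
    f_neg = U_neg @ h
    loss = -np.log(sig(f_pos)) - np.sum(np.log(sig(-f_neg)))
    g_pos = sig(f_pos) - 1.0
    g_neg = sig(f_neg)
    grad_h = g_pos * u_o + U_neg.T @ g_neg
    grad_V = np.tile(grad_h / n_ctx, (n_ctx, 1))
    grad_uo = g_pos * h
    grad_Uneg = np.outer(g_neg, h)
    return float(loss), grad_V, grad_uo, grad_Uneg


# ------------------------------------------------------------- numba kernels

@njit(cache=True)
def _train_sg(W, C, centers, contexts, negs, alphas):
    n_pairs = centers.shape[0]
    k = negs.shape[1]
    dim = W.shape[1]
    for i in range(n_pairs):
        c = centers[i]
        o = contexts[i]
        a = alphas[i]
        gv = np.zeros(dim)
        f = 0.0
        for j in range(dim):
            f += W[c, j] * C[o, j]
        g = (1.0 / (1.0 + np.exp(-f)) - 1.0) * a
        for j in range(dim):
            gv[j] += g * C[o, j]
            C[o, j] -= g * W[c, j]
        for t in range(k):
            nneg = negs[i, t]
            if nneg == o:
                continue
            f = 0.0
            for j in range(dim):
                f += W[c, j] * C[nneg, j]
            g = (1.0 / (1.0 + np.exp(-f))) * a
            for j in range(dim):
                gv[j] += g * C[nneg, j]
                C[nneg, j] -= g * W[c, j]
        for j in range(dim):
            W[c, j] -= gv[j]


@njit(cache=True)
def _train_cbow(W, C, centers, ctx_flat, ctx_starts, negs, alphas):
    n_upd = centers.shape[0]
    k = negs.shape[1]
    dim = W.shape[1]
    for i in range(n_upd):
        o = centers[i]           # predicted (output) token
        a = alphas[i]
        lo, hi = ctx_starts[i], ctx_starts[i + 1]
        n_ctx = hi - lo
        h = np.zeros(dim)
        for p in range(lo, hi):
            c = ctx_flat[p]
            for j in range(dim):
                h[j] += W[c, j]
        for j in range(dim):
            h[j] /= n_ctx
        gh = np.zeros(dim)
        f = 0.0
        for j in range(dim):
            f += h[j] * C[o, j]
        g = (1.0 / (1.0 + np.exp(-f)) - 1.0) * a
        for j in range(dim):
            gh[j] += g * C[o, j]
            C[o, j] -= g * h[j]
        for t in range(k):
            nneg = negs[i, t]
            if nneg == o:
                continue
            f = 0.0
            for j in range(dim):
                f += h[j] * C[nneg, j]
            g = (1.0 / (1.0 + np.exp(-f))) * a
            for j in range(dim):
                gh[j] += g * C[nneg, j]
                C[nneg, j] -= g * h[j]
        for p in range(lo, hi):
            c = ctx_flat[p]
            for j in range(dim):
                W[c, j] -= gh[j] / n_ctx


# ---------------------------------------------------------------- estimator

class EventEmbedding(BaseEstimator):
    """Dense vector representations of event tokens, word2vec style.

    Parameters
    ----------
    size : int
        Vector dimensionality.
    window : int
        Maximum positional distance between a center token and a context
        token.
    mode : {"skipgram", "cbow", "dynamic"}
        Training mode; ``dynamic`` adds the time-horizon constraint to
        skip-gram pair generation.
    dynamic_horizon_days : float
        Time horizon in days for dynamic mode (default 365); ``inf`` reduces
        dynamic mode to plain skip-gram.
    horizon_anchor : {"center", "end"}
        Whether the horizon is measured from the center token or from the
        sequence end (the latter discards old events outright).
    negative_samples : int
        Noise tokens per positive pair.
    epochs : int
        Passes over the corpus; the learning rate decays linearly to ~0
        across all updates.
    learning_rate : float
        Initial SGD step size.
    min_count : int
        Minimum corpus frequency for a token to enter the vocabulary
        (default 1: rare-event filtering happens upstream).
    seed : int
        RNG seed; fixed seed gives bit-identical vectors.

    Attributes
    ----------
    vocab_ : list of str
        Tokens in frequency order (ties lexicographic).
    vectors_ : ndarray of shape (n_tokens, size)
        Input (center) vectors — the embedding used everywhere downstream.
    counts_ : ndarray
        Corpus frequency per vocabulary token.
    """

    def __init__(self, size: int = 100, window: int = 10,
                 mode: str = "skipgram", dynamic_horizon_days: float = 365.0,
                 horizon_anchor: str = "center", negative_samples: int = 5,
                 epochs: int = 10, learning_rate: float = 0.025,
                 min_count: int = 1, seed: int = 0):
        self.size = size
        self.window = window
        self.mode = mode
        self.dynamic_horizon_days = dynamic_horizon_days
        self.horizon_anchor = horizon_anchor
        self.negative_samples = negative_samples
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.min_count = min_count
        self.seed = seed

    # corpus: iterable of token lists, (tokens, days) tuples, or sequences
    def fit(self, X: Iterable, y=None) -> "EventEmbedding":
        if self.size < 1 or self.window < 1:
            raise ValueError("size and window must be >= 1")
        if self.negative_samples < 1 or self.epochs < 1:
            raise ValueError("negative_samples and epochs must be >= 1")
        if self.mode not in {"skipgram", "cbow", "dynamic"}:
            raise ValueError(f"unknown mode: {self.mode!r}")

        sentences: list[tuple[list[str], np.ndarray | None]] = []
        for item in X:
            if isinstance(item, PatientSequence):
                sentences.append((item.tokens, item.days))
            elif isinstance(item, tuple):
                toks, days = item
                sentences.append((list(toks),
                                  None if days is None else np.asarray(days, float)))
            else:
                sentences.append((list(item), None))
        if self.mode == "dynamic" and any(d is None for _, d in sentences):
            raise ValueError("dynamic mode requires (tokens, day_offsets) input")

        freq: dict[str, int] = {}
        for toks, _ in sentences:
            for t in toks:
                freq[t] = freq.get(t, 0) + 1
        vocab = sorted((t for t, c in freq.items() if c >= self.min_count),
                       key=lambda t: (-freq[t], t))
        if not vocab:
            raise ValueError("empty vocabulary after min_count pruning")
        index = {t: i for i, t in enumerate(vocab)}
        counts = np.array([freq[t] for t in vocab], dtype=np.int64)

        rng = np.random.default_rng(self.seed)
        V = len(vocab)
        W = (rng.random((V, self.size)) - 0.5) / self.size
        C = np.zeros((V, self.size))

        # unigram^0.75 noise table
        p = counts.astype(float) ** _NOISE_EXPONENT
        p /= p.sum()
        noise_table = rng.choice(V, size=_NOISE_TABLE_SIZE, p=p).astype(np.int32)

        horizon = self.dynamic_horizon_days if self.mode == "dynamic" else None
        all_centers, all_contexts = [], []
        cbow_centers, cbow_flat, cbow_lens = [], [], []
        for toks, days in sentences:
            idx = np.array([index[t] for t in toks if t in index], dtype=np.int32)
            if days is not None:
                d = np.asarray(days, float)[[t in index for t in toks]]
            else:
                d = None
            if idx.shape[0] < 2:
                continue
            if self.mode == "cbow":
                # one update per center position, contexts gathered by window
                for pos in range(idx.shape[0]):
                    lo = max(0, pos - self.window)
                    hi = min(idx.shape[0], pos + self.window + 1)
                    ctx_pos = [idx[q] for q in range(lo, hi) if q != pos]
                    if not ctx_pos:
                        continue
                    cbow_centers.append(idx[pos])
                    cbow_flat.extend(ctx_pos)
                    cbow_lens.append(len(ctx_pos))
            else:
                cen, ctx = generate_pairs(idx, d, self.window, self.mode,
                                          horizon, self.horizon_anchor)
                if cen.shape[0] == 0:
                    continue
                all_centers.append(cen)
                all_contexts.append(ctx)

        if self.mode == "cbow":
            if not cbow_centers:
                raise ValueError("no training examples generated")
            centers = np.array(cbow_centers, dtype=np.int32)
            ctx_flat = np.array(cbow_flat, dtype=np.int32)
            lens = np.array(cbow_lens, dtype=np.int64)
            n_updates_per_epoch = centers.shape[0]
        else:
            if not all_centers:
                raise ValueError("no training pairs generated")
            centers = np.concatenate(all_centers)
            contexts = np.concatenate(all_contexts)
            n_updates_per_epoch = centers.shape[0]

        total = n_updates_per_epoch * self.epochs
        done = 0
        for _ in range(self.epochs):
            perm = rng.permutation(n_updates_per_epoch)
            negs = noise_table[rng.integers(0, _NOISE_TABLE_SIZE,
                                            size=(n_updates_per_epoch,
                                                  self.negative_samples))]
            frac = 1.0 - np.arange(done, done + n_updates_per_epoch) / total
            alphas = self.learning_rate * np.maximum(frac, _MIN_ALPHA_FRACTION)
            if self.mode == "cbow":
                starts = np.zeros(n_updates_per_epoch + 1, dtype=np.int64)
                np.cumsum(lens, out=starts[1:])
                # permute update order while keeping ragged groups intact
                p_centers = centers[perm]
                p_lens = lens[perm]
                p_flat = np.concatenate([
                    ctx_flat[starts[i]:starts[i] + lens[i]] for i in perm
                ]) if n_updates_per_epoch else ctx_flat
                p_starts = np.zeros(n_updates_per_epoch + 1, dtype=np.int64)
                np.cumsum(p_lens, out=p_starts[1:])
                _train_cbow(W, C, p_centers, p_flat, p_starts, negs, alphas)
            else:
                _train_sg(W, C, centers[perm], contexts[perm], negs, alphas)
            done += n_updates_per_epoch

        self.vocab_ = vocab
        self.index_ = index
        self.counts_ = counts
        self.vectors_ = W
        self.context_vectors_ = C
        self.n_training_updates_ = total
        return self

    # ------------------------------------------------------------- queries

    def __contains__(self, token: str) -> bool:
        return token in self.index_

    def get_vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors_[self.index_[token]]
        except KeyError:
            raise KeyError(f"token not in vocabulary: {token!r}") from None

    def similarity(self, a: str, b: str) -> float:
        return cosine(self.get_vector(a), self.get_vector(b))

    def most_similar(self, token: str, n: int = 10,
                     category_prefix: str | None = None
                     ) -> list[tuple[str, float]]:
        """Top-n vocabulary tokens by cosine to ``token`` (query excluded)."""
        if n <= 0:
            return []
        v = self.get_vector(token)
        norms = np.linalg.norm(self.vectors_, axis=1)
        nv = np.linalg.norm(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = (self.vectors_ @ v) / (norms * nv)
        sims = np.nan_to_num(sims, nan=-np.inf)
        cand = [(t, float(sims[i])) for i, t in enumerate(self.vocab_)
                if t != token and (category_prefix is None
                                   or t.startswith(category_prefix))]
        cand.sort(key=lambda ts: (-ts[1], ts[0]))
        return cand[:n]

    def transform(self, X: Iterable) -> np.ndarray:
        """Unweighted vector sum per token list (for pipeline composition)."""
        rows = []
        for item in X:
            toks = item.tokens if isinstance(item, PatientSequence) else list(item)
            ids = [self.index_[t] for t in toks if t in self.index_]
            if not ids:
                rows.append(np.zeros(self.size))
            else:
                rows.append(self.vectors_[ids].sum(axis=0))
        return np.vstack(rows)

    # --------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Text vector format: header "vocab_size dim", then one token+vector
        per line; params in a JSON sidecar."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab_)} {self.size}\n")
            for i, t in enumerate(self.vocab_):
                vec = " ".join(f"{x:.17g}" for x in self.vectors_[i])
                fh.write(f"{t} {vec}\n")
        Path(str(path) + ".params.json").write_text(
            json.dumps({"params": self.get_params(),
                        "counts": self.counts_.tolist()}))

    @classmethod
    def load(cls, path: str | Path) -> "EventEmbedding":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".params.json").read_text())
        model = cls(**sidecar["params"])
        lines = path.read_text(encoding="utf-8").splitlines()
        n, dim = (int(x) for x in lines[0].split())
        vocab, vecs = [], np.empty((n, dim))
        for i, line in enumerate(lines[1:1 + n]):
            parts = line.split(" ")
            vocab.append(parts[0])
            vecs[i] = [float(x) for x in parts[1:]]
        model.vocab_ = vocab
        model.index_ = {t: i for i, t in enumerate(vocab)}
        model.vectors_ = vecs
        model.counts_ = np.asarray(sidecar["counts"], dtype=np.int64)
        model.context_vectors_ = np.zeros_like(vecs)
        return model


# ----------------------------------------------------------------- wrappers

def build_corpus(sequences: Sequence[PatientSequence],
                 include_labels: bool = True
                 ) -> list[tuple[list[str], np.ndarray]]:
    """Training sentences from patient sequences.

    Each sentence is the history oldest-to-latest; with ``include_labels``
    the final-admission diagnosis tokens are appended (sorted, at day offset
    0) so that diagnosis tokens acquire vectors near their antecedent events.
    Only call this on training-fold sequences — test labels must never reach
    the embedding.
    """
    out = []
    for s in sequences:
        toks = list(s.tokens)
        days = list(s.days)
        if include_labels:
            for d in sorted(s.label_diagnoses):
                toks.append(d)
                days.append(0.0)
        out.append((toks, np.asarray(days, dtype=float)))
    return out


def train_embeddings(corpus: Iterable, **params) -> EventEmbedding:
    """Thin functional wrapper: fit an :class:`EventEmbedding` on a corpus."""
    return EventEmbedding(**params).fit(corpus)


def nearest_tokens(model: EventEmbedding, token: str, n: int,
                   category_filter: str | None = None) -> list[tuple[str, float]]:
    return model.most_similar(token, n=n, category_prefix=category_filter)


def project_2d(model: EventEmbedding) -> dict[str, np.ndarray]:
    """Two-coordinate layout per token (identity for size-2 models, else PCA)."""
    if model.size == 2:
        coords = model.vectors_
    else:
        from sklearn.decomposition import PCA
        coords = PCA(n_components=2, random_state=0).fit_transform(model.vectors_)
    return {t: coords[i] for i, t in enumerate(model.vocab_)}
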