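"""Sequence encoding: positioned k-mer GloVe vectors + sinusoidal positions.

A 60 nt target is scanned with a sliding window (k=2, step 1) into 59
overlapping dinucleotide tokens.  Each token is keyed by (k-mer, position),
giving a closed vocabulary of 16 x 59 = 944 positioned tokens.  GloVe
vectors are fit by weighted least squares to the log of the token
co-occurrence counts, and a fixed sinusoidal positional vector is added to
each token's embedding, so a sequence becomes a 59 x d input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .labels import LabelError

__all__ = [
    "TokenSequence",
    "PositionedVocab",
    "GloveModel",
    "tokenize",
    "build_cooccurrence",
    "glove_weight",
    "glove_fit",
    "glove_objective_and_grads",
    "positional_vector",
    "positional_table",
    "embed_sequence",
    "GloveEmbedder",
]

TokenSequence = list  # list of (kmer, 1-based position) pairs


def tokenize(seq: str, k: int = 2, step: int = 1) -> list[tuple[str, int]]:
    """Slide a window of width k and stride ``step`` over the sequence.

    Returns [(kmer, position)] with 1-based positions; the token count is
    (len(seq) - k) / step + 1, and the stride must divide len(seq) - k
    exactly so no 3' bases are silently dropped.
    """
    s = seq.strip().upper()
    if len(s) < k:
        raise LabelError(f"sequence of length {len(s)} shorter than k={k}")
    if (len(s) - k) % step != 0:
        raise LabelError(
            f"(len(seq)-k) = {len(s) - k} is not divisible by step={step} (k={k})"
        )
    return [(s[i : i + k], i // step + 1) for i in range(0, len(s) - k + 1, step)]


@dataclass(frozen=True)
class PositionedVocab:
    """Closed vocabulary of (k-mer, position) tokens.

    With ``positioned=False`` the position is ignored and the vocabulary
    collapses to the 4^k bare k-mers.
    """

    k: int
    n_positions: int
    positioned: bool = True
    _index: dict = field(repr=False, hash=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        kmers = ["".join(p) for p in product("ACGT", repeat=self.k)]
        if self.positioned:
            entries = [
                (km, pos) for pos in range(1, self.n_positions + 1) for km in kmers
            ]
        else:
            entries = [(km, 0) for km in kmers]
        object.__setattr__(self, "entries", tuple(entries))
        self._index.update({e: i for i, e in enumerate(entries)})

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, kmer: str, position: int) -> int:
        key = (kmer, position if self.positioned else 0)
        try:
            return self._index[key]
        except KeyError:
            raise LabelError(f"token {kmer!r}@{position} not in vocabulary") from None

    def encode(self, tokens: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.array([self.index(km, pos) for km, pos in tokens], dtype=np.intp)


def build_cooccurrence(
    corpus: Sequence[Sequence[tuple[str, int]]],
    vocab: PositionedVocab,
    window_diameter: int = 5,
) -> np.ndarray:
    """Symmetric token co-occurrence matrix with 1/distance weighting.

    Token pairs at distance 1..window_diameter within a sequence
    contribute 1/distance to both (i, j) and (j, i).
    """
    if len(corpus) == 0:
        raise LabelError("empty corpus")
    V = len(vocab)
    X = np.zeros((V, V))
    for tokens in corpus:
        idx = vocab.encode(tokens)
        for off in range(1, min(window_diameter, len(idx) - 1) + 1):
            a, b = idx[:-off], idx[off:]
            w = 1.0 / off
            np.add.at(X, (a, b), w)
            np.add.at(X, (b, a), w)
    return X


def glove_weight(x, x_max: float, alpha: float = 0.75):
    """GloVe weighting function: (x/x_max)^alpha below x_max, else 1."""
    x = np.asarray(x, dtype=float)
    if x_max <= 0:
        raise LabelError("x_max must be positive")
    out = np.where(x < x_max, np.power(np.clip(x / x_max, 0.0, None), alpha), 1.0)
    return out if out.ndim else float(out)


@dataclass
class GloveModel:
    """Fitted GloVe factors: main/context vectors and biases."""

    w: np.ndarray
    w_tilde: np.ndarray
    b: np.ndarray
    b_tilde: np.ndarray
    x_max: float
    alpha: float
    objective_history: list[float] = field(default_factory=list)

    @property
    def vectors(self) -> np.ndarray:
        """Final word vectors, the sum of main and context factors."""
        return self.w + self.w_tilde


def _nonzero_triplets(X: np.ndarray):
    i, j = np.nonzero(X)
    return i, j, X[i, j]


def glove_objective_and_grads(
    params: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    i: np.ndarray,
    j: np.ndarray,
    f: np.ndarray,
    logx: np.ndarray,
    shape: tuple[int, int],
):
    """Weighted-least-squares GloVe objective and its analytic gradients.

    J = sum_{ij in nz} f_ij (w_i . w~_j + b_i + b~_j - ln X_ij)^2
    """
    w, wt, b, bt = params
    e = np.einsum("nd,nd->n", w[i], wt[j]) + b[i] + bt[j] - logx
    J = float(np.sum(f * e * e))
    g = 2.0 * f * e
    G = sp.coo_matrix((g, (i, j)), shape=shape).tocsr()
    grad_w = G @ wt
    grad_wt = G.T @ w
    grad_b = np.asarray(G.sum(axis=1)).ravel()
    grad_bt = np.asarray(G.sum(axis=0)).ravel()
    return J, (grad_w, grad_wt, grad_b, grad_bt)


def glove_fit(
    X: np.ndarray,
    d: int = 150,
    max_iter: int = 20000,
    x_max: float | str = 10000.0,
    alpha: float = 0.75,
    learning_rate: float = 0.05,
    optimizer: str = "gd",
    seed: int | None = 0,
    log_every: int = 10,
) -> GloveModel:
    """Fit GloVe factors to a co-occurrence matrix.

    Only nonzero entries enter the objective.  The default optimizer is
    full-batch gradient descent with a fixed step; a step that would
    increase the objective is rejected and the step halved, so the logged
    objective trace is non-increasing.  ``x_max='auto'`` uses the mean of
    the nonzero co-occurrence entries as the truncation value.
    """
    i, j, x = _nonzero_triplets(np.asarray(X, dtype=float))
    if len(x) == 0:
        raise LabelError("co-occurrence matrix has no nonzero entries")
    if x_max == "auto":
        x_max = float(x.mean())
    f = glove_weight(x, float(x_max), alpha)
    logx = np.log(x)
    V = X.shape[0]
    rng = np.random.default_rng(seed)
    scale = 0.5 / max(d, 1)
    params = [
        rng.uniform(-scale, scale, size=(V, d)),
        rng.uniform(-scale, scale, size=(V, d)),
        rng.uniform(-scale, scale, size=V),
        rng.uniform(-scale, scale, size=V),
    ]
    history: list[float] = []
    lr = learning_rate
    accum = [np.zeros_like(p) for p in params] if optimizer == "adagrad" else None
    prev_J = np.inf
    backup = None
    it = 0
    while it < max_iter:
        J, grads = glove_objective_and_grads(tuple(params), i, j, f, logx, (V, V))
        if optimizer == "gd" and J > prev_J and backup is not None:
            # overshoot: revert the last step and retry with half the step
            params = [p.copy() for p in backup]
            lr *= 0.5
            if lr < 1e-14:
                break
            continue
        history.append(J)
        prev_J = J
        backup = [p.copy() for p in params]
        if optimizer == "adagrad":
            for p, g, a in zip(params, grads, accum):
                a += g * g
                p -= lr * g / np.sqrt(a + 1e-8)
        elif optimizer == "gd":
            for p, g in zip(params, grads):
                p -= lr * g
        else:
            raise LabelError(f"unknown optimizer {optimizer!r}")
        it += 1
    logged = history[:: max(log_every, 1)]
    if history and (not logged or logged[-1] != history[-1]):
        logged.append(history[-1])
    return GloveModel(
        w=params[0],
        w_tilde=params[1],
        b=params[2],
        b_tilde=params[3],
        x_max=float(x_max),
        alpha=alpha,
        objective_history=logged,
    )


# ---------------------------------------------------------------------------
# Positional encoding


def positional_vector(t: int, d: int) -> np.ndarray:
    """Sinusoidal position vector: entry 2k = sin(w_k t), 2k+1 = cos(w_k t),
    with frequency w_k = 10000^(-2k/d).  For odd d the last entry falls on
    the sine branch."""
    if d <= 0:
        raise LabelError("dimension must be positive")
    idx = np.arange(d)
    k = idx // 2
    omega = np.power(10000.0, -2.0 * k / d)
    out = np.where(idx % 2 == 0, np.sin(omega * t), np.cos(omega * t))
    return out


def positional_table(n_positions: int, d: int) -> np.ndarray:
    """Table of position vectors for 1-based token positions 1..n."""
    return np.stack([positional_vector(t, d) for t in range(1, n_positions + 1)])


def embed_sequence(
    tokens: Sequence[tuple[str, int]],
    vectors: np.ndarray,
    vocab: PositionedVocab,
    positional: np.ndarray,
) -> np.ndarray:
    """L x d input matrix: GloVe vector of each positioned token plus the
    positional vector of its position (no scaling)."""
    idx = vocab.encode(tokens)
    pos = np.array([p for _, p in tokens], dtype=np.intp)
    if pos.max(initial=0) > positional.shape[0]:
        raise LabelError("token position exceeds the positional table")
    return vectors[idx] + positional[pos - 1]


# ---------------------------------------------------------------------------
# Estimator


class GloveEmbedder(TransformerMixin, BaseEstimator):
    """Transformer: DNA sequences -> (n, L, dim) embedded input matrices.

    Fits a GloVe model on the positioned-token co-occurrence statistics of
    the training corpus and adds fixed sinusoidal positional encodings.
    All training sequences must share one length (60 nt canonically, so
    L = 59 tokens and a 944-token vocabulary at k=2, step 1).

    Parameters mirror the published configuration: ``dim=150``, window
    diameter 5, truncation ``x_max=10000`` (or ``'auto'`` for the mean of
    the nonzero co-occurrence entries), up to 20000 iterations.  Positional
    dropout is 0 and is therefore not implemented as a layer.
    """

    def __init__(
        self,
        k: int = 2,
        step: int = 1,
        dim: int = 150,
        window_diameter: int = 5,
        x_max: float | str = 10000.0,
        alpha: float = 0.75,
        max_iter: int = 20000,
        learning_rate: float = 0.05,
        optimizer: str = "gd",
        positioned: bool = True,
        random_state: int = 0,
    ):
        self.k = k
        self.step = step
        self.dim = dim
        self.window_diameter = window_diameter
        self.x_max = x_max
        self.alpha = alpha
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.positioned = positioned
        self.random_state = random_state

    def _tokenize_corpus(self, X) -> list[list[tuple[str, int]]]:
        corpus = [tokenize(s, self.k, self.step) for s in X]
        lengths = {len(t) for t in corpus}
        if len(lengths) > 1:
            raise LabelError(f"sequences tokenize to differing lengths {sorted(lengths)}")
        return corpus

    def fit(self, X, y=None):
        """Fit on an iterable of equal-length DNA sequences."""
        corpus = self._tokenize_corpus(list(X))
        if not corpus:
            raise LabelError("empty corpus")
        self.n_positions_ = len(corpus[0])
        self.vocab_ = PositionedVocab(
            k=self.k, n_positions=self.n_positions_, positioned=self.positioned
        )
        self.cooccurrence_ = build_cooccurrence(
            corpus, self.vocab_, self.window_diameter
        )
        self.glove_ = glove_fit(
            self.cooccurrence_,
            d=self.dim,
            max_iter=self.max_iter,
            x_max=self.x_max,
            alpha=self.alpha,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
            seed=self.random_state,
        )
        self.vectors_ = self.glove_.vectors
        self.positional_ = positional_table(self.n_positions_, self.dim)
        self.objective_history_ = self.glove_.objective_history
        return self

    def transform(self, X) -> np.ndarray:
        """Embed sequences into a (n, L, dim) array."""
        if not hasattr(self, "vectors_"):
            raise LabelError("GloveEmbedder is not fitted")
        out = [
            embed_sequence(
                tokenize(s, self.k, self.step),
                self.vectors_,
                self.vocab_,
                self.positional_,
            )
            for s in X
        ]
        return np.stack(out)
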