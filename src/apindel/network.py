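"""BiLSTM-attention predictor over the 557-class outcome taxonomy.

Architecture: an embedded 59 x d input matrix is passed through a
bidirectional LSTM (units per direction -> feature dim C = 2*units), an
additive attention layer a_i = softmax_i(w2^T tanh(W1 h_i)) that pools the
feature matrix into a context vector c = sum_i a_i h_i, batch
normalization, a one-hidden-layer MLP (ReLU), dropout, and a softmax over
the outcome classes.  Training minimizes categorical cross-entropy against
soft labels (per-target outcome distributions) with L1 penalties on the
BiLSTM and attention kernels, using Adam with reduce-on-plateau learning
rate decay and early stopping on validation mean squared error.

Everything here is plain NumPy: forward passes, full backpropagation
through time, and the optimizer are implemented directly, which keeps the
model dependency-light and bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .labels import LabelError

__all__ = [
    "NetworkConfig",
    "scaled_test_config",
    "ApindelNetwork",
    "IndelOutcomePredictor",
    "bilstm_features",
    "attention_scores",
    "predict",
    "train",
    "attention_profile",
]


@dataclass
class NetworkConfig:
    """Published model configuration (defaults) for the full-size network."""

    lstm_units: int = 50
    attention_T: int = 64
    mlp_hidden: int = 128
    d: int = 150
    l1_lambda: float = 1e-4
    dropout_p: float = 0.5
    activation: str = "relu"
    batch_size: int = 64
    learning_rate: float = 1e-4
    max_epochs: int = 100
    lr_decay_factor: float = 0.2
    lr_patience: int = 1
    stop_patience: int = 3
    init_output_bias: bool = True
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return 2 * self.lstm_units


def scaled_test_config(seed: int = 0) -> NetworkConfig:
    """Small-profile configuration: trains in minutes on one CPU.

    Uses d=32 embeddings, 16 LSTM units per direction, a 64-wide MLP, a
    larger step size, lighter dropout, and patience values scaled to the
    much smaller number of optimizer steps per epoch (tens rather than
    hundreds), keeping the architecture itself identical.
    """
    return NetworkConfig(
        lstm_units=16,
        attention_T=16,
        mlp_hidden=64,
        d=32,
        dropout_p=0.2,
        learning_rate=3e-3,
        max_epochs=120,
        lr_patience=25,
        stop_patience=45,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Primitive layers


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _act(x, name):
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh(x)
    raise LabelError(f"unknown activation {name!r}")


def _act_grad_from_pre(x, name):
    if name == "relu":
        return (x > 0).astype(x.dtype)
    return 1.0 - np.tanh(x) ** 2


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _lstm_forward(X, W, R, b, activation):
    """One-direction LSTM. X: (B,L,d) -> H: (B,L,U) plus BPTT cache.

    Gate order [i, f, g, o]; sigmoid gates, candidate and cell-output
    activation selectable (the published model uses ReLU)."""
    B, L, _ = X.shape
    U = R.shape[0]
    h = np.zeros((B, U))
    c = np.zeros((B, U))
    H = np.empty((B, L, U))
    cache = []
    for t in range(L):
        z = X[:, t] @ W + h @ R + b
        zi, zf, zg, zo = np.split(z, 4, axis=1)
        i = _sigmoid(zi)
        f = _sigmoid(zf)
        g = _act(zg, activation)
        o = _sigmoid(zo)
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        ac = _act(c, activation)
        h = o * ac
        H[:, t] = h
        cache.append((i, f, g, o, zg, c, c_prev, h_prev, ac))
    return H, cache


def _lstm_backward(dH, X, W, R, cache, activation):
    B, L, d = X.shape
    U = R.shape[0]
    dW = np.zeros_like(W)
    dR = np.zeros_like(R)
    db = np.zeros(4 * U)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, U))
    dc_next = np.zeros((B, U))
    for t in range(L - 1, -1, -1):
        i, f, g, o, zg, c, c_prev, h_prev, ac = cache[t]
        dh = dH[:, t] + dh_next
        do = dh * ac
        dc = dh * o * _act_grad_from_pre(c, activation) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1 - i),
                df * f * (1 - f),
                dg * _act_grad_from_pre(zg, activation),
                do * o * (1 - o),
            ],
            axis=1,
        )
        dW += X[:, t].T @ dz
        dR += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ W.T
        dh_next = dz @ R.T
        dc_next = dc * f
    return dX, dW, dR, db


def attention_scores(H: np.ndarray, W1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Additive attention weights a_i = softmax_i(w2^T tanh(W1 h_i)).

    H may be (L, C) or (B, L, C); W1 is (T, C) and w2 is (T,).  The
    returned weights sum to 1 along the position axis.
    """
    H = np.asarray(H, dtype=float)
    single = H.ndim == 2
    if single:
        H = H[None]
    if W1.ndim != 2 or w2.shape != (W1.shape[0],) or H.shape[2] != W1.shape[1]:
        raise LabelError(
            f"attention shape mismatch: H {H.shape}, W1 {W1.shape}, w2 {w2.shape}"
        )
    u = np.tanh(H @ W1.T) @ w2
    a = _softmax(u, axis=1)
    return a[0] if single else a


# ---------------------------------------------------------------------------
# The network


class ApindelNetwork:
    """Raw NumPy network: parameters, forward, backward, prediction.

    ``input_dim``/``seq_len``/``n_classes`` are fixed at construction;
    the sklearn-style :class:`IndelOutcomePredictor` wraps this with
    embedding and the training protocol.
    """

    def __init__(
        self,
        input_dim: int,
        seq_len: int,
        n_classes: int,
        units: int = 50,
        attention_T: int = 64,
        mlp_hidden: int = 128,
        dropout_p: float = 0.5,
        l1_lambda: float = 1e-4,
        activation: str = "relu",
        seed: int = 0,
    ):
        self.input_dim = input_dim
        self.seq_len = seq_len
        self.n_classes = n_classes
        self.units = units
        self.attention_T = attention_T
        self.mlp_hidden = mlp_hidden
        self.dropout_p = dropout_p
        self.l1_lambda = l1_lambda
        self.activation = activation
        self.seed = seed
        rng = np.random.default_rng(seed)
        C = 2 * units

        def glorot(fan_in, fan_out, shape=None):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))

        d, U, T, M = input_dim, units, attention_T, mlp_hidden
        self.params = {
            "Wf": glorot(d, 4 * U),
            "Rf": glorot(U, 4 * U),
            "bf": np.zeros(4 * U),
            "Wb": glorot(d, 4 * U),
            "Rb": glorot(U, 4 * U),
            "bb": np.zeros(4 * U),
            "W1": glorot(C, T, shape=(T, C)),
            "w2": glorot(T, 1, shape=(T,)),
            "gamma": np.ones(C),
            "beta": np.zeros(C),
            "Wh": glorot(C, M),
            "bh": np.zeros(M),
            "Wo": glorot(M, n_classes),
            "bo": np.zeros(n_classes),
        }
        # forget-gate bias 1: standard LSTM initialization
        for key in ("bf", "bb"):
            self.params[key][U : 2 * U] = 1.0
        self.running_mean = np.zeros(C)
        self.running_var = np.ones(C)
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5
        #: kernels carrying the L1 penalty (biases exempt)
        self.l1_keys = ("Wf", "Rf", "Wb", "Rb", "W1", "w2")

    # -- forward ------------------------------------------------------------

    def features(self, X: np.ndarray, with_cache: bool = False):
        """BiLSTM feature matrix H: (B, L, 2*units)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if not np.all(np.isfinite(X)):
            raise LabelError("non-finite values in network input")
        if X.shape[1:] != (self.seq_len, self.input_dim):
            raise LabelError(
                f"input shape {X.shape[1:]} != ({self.seq_len}, {self.input_dim})"
            )
        p = self.params
        Hf, cf = _lstm_forward(X, p["Wf"], p["Rf"], p["bf"], self.activation)
        Hb_rev, cb = _lstm_forward(
            X[:, ::-1], p["Wb"], p["Rb"], p["bb"], self.activation
        )
        H = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
        if with_cache:
            return H, (X, cf, cb)
        return H

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None):
        p = self.params
        H, feat_cache = self.features(X, with_cache=True)
        Xa = feat_cache[0]
        B, L, C = H.shape
        S = np.tanh(H @ p["W1"].T)
        u = S @ p["w2"]
        a = _softmax(u, axis=1)
        ctx = np.einsum("bl,blc->bc", a, H)
        # batch normalization on the context vector
        if training:
            mu = ctx.mean(axis=0)
            var = ctx.var(axis=0)
            self.running_mean = self.bn_momentum * self.running_mean + (1 - self.bn_momentum) * mu
            self.running_var = self.bn_momentum * self.running_var + (1 - self.bn_momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.bn_eps)
        xn = (ctx - mu) / std
        y_bn = p["gamma"] * xn + p["beta"]
        zh = y_bn @ p["Wh"] + p["bh"]
        hid = np.maximum(zh, 0.0)
        if training and self.dropout_p > 0:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            mask = (rng.random(hid.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
        else:
            mask = np.ones_like(hid)
        hid_d = hid * mask
        logits = hid_d @ p["Wo"] + p["bo"]
        probs = _softmax(logits, axis=1)
        cache = {
            "X": Xa, "feat": feat_cache, "H": H, "S": S, "a": a, "ctx": ctx,
            "mu": mu, "std": std, "xn": xn, "zh": zh, "hid": hid,
            "mask": mask, "hid_d": hid_d, "probs": probs, "training": training,
        }
        return probs, a, cache

    # -- loss / gradients ---------------------------------------------------

    def loss_and_grads(self, X, Y, rng=None):
        """Soft-label cross-entropy + L1 penalty; full analytic gradients."""
        p = self.params
        probs, a, cache = self.forward(X, training=True, rng=rng)
        B = probs.shape[0]
        eps = 1e-12
        ce = -np.sum(Y * np.log(probs + eps)) / B
        l1 = self.l1_lambda * sum(np.abs(p[k]).sum() for k in self.l1_keys)
        loss = ce + l1
        grads = {}
        dlogits = (probs - Y) / B
        grads["Wo"] = cache["hid_d"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dhid_d = dlogits @ p["Wo"].T
        dhid = dhid_d * cache["mask"]
        dzh = dhid * (cache["zh"] > 0)
        y_bn = p["gamma"] * cache["xn"] + p["beta"]
        grads["Wh"] = y_bn.T @ dzh
        grads["bh"] = dzh.sum(axis=0)
        dy_bn = dzh @ p["Wh"].T
        grads["gamma"] = (dy_bn * cache["xn"]).sum(axis=0)
        grads["beta"] = dy_bn.sum(axis=0)
        # batch-norm backward (training statistics)
        xn, std = cache["xn"], cache["std"]
        dxn = dy_bn * p["gamma"]
        dctx = (dxn - dxn.mean(axis=0) - xn * (dxn * xn).mean(axis=0)) / std
        # attention backward
        H, S, a_ = cache["H"], cache["S"], cache["a"]
        dH = a_[:, :, None] * dctx[:, None, :]
        da = np.einsum("bc,blc->bl", dctx, H)
        du = a_ * (da - (a_ * da).sum(axis=1, keepdims=True))
        grads["w2"] = np.einsum("blt,bl->t", S, du)
        dS = du[:, :, None] * p["w2"][None, None, :]
        dZ1 = dS * (1.0 - S**2)
        grads["W1"] = np.einsum("blt,blc->tc", dZ1, H)
        dH += np.einsum("blt,tc->blc", dZ1, p["W1"])
        # BiLSTM backward
        Xa, cf, cb = cache["feat"]
        U = self.units
        _, dWf, dRf, dbf = _lstm_backward(
            dH[:, :, :U], Xa, p["Wf"], p["Rf"], cf, self.activation
        )
        _, dWb, dRb, dbb = _lstm_backward(
            dH[:, ::-1, U:], Xa[:, ::-1], p["Wb"], p["Rb"], cb, self.activation
        )
        grads.update(Wf=dWf, Rf=dRf, bf=dbf, Wb=dWb, Rb=dRb, bb=dbb)
        for k in self.l1_keys:
            grads[k] = grads[k] + self.l1_lambda * np.sign(p[k])
        return loss, grads, probs

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = []
        for s in range(0, X.shape[0], batch_size):
            probs, _, _ = self.forward(X[s : s + batch_size], training=False)
            out.append(probs)
        return np.concatenate(out)

    def attention(self, X, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = []
        for s in range(0, X.shape[0], batch_size):
            _, a, _ = self.forward(X[s : s + batch_size], training=False)
            out.append(a)
        return np.concatenate(out)

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running_mean": self.running_mean.copy(),
            "running_var": self.running_var.copy(),
        }

    def load_state_dict(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k] = v.copy()
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


def bilstm_features(inputs: np.ndarray, network: ApindelNetwork) -> np.ndarray:
    """Feature matrix H = (h_1..h_L) of the network's BiLSTM layer."""
    return network.features(inputs)


# ---------------------------------------------------------------------------
# Training


def _adam_step(params, grads, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for k, g in grads.items():
        if g is None:
            continue
        m[k] = beta1 * m[k] + (1 - beta1) * g
        v[k] = beta2 * v[k] + (1 - beta2) * g * g
        mhat = m[k] / (1 - beta1**t)
        vhat = v[k] / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_network(
    net: ApindelNetwork,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: NetworkConfig,
) -> pd.DataFrame:
    """Soft-label training loop.

    Adam at the configured learning rate; per-epoch validation MSE drives
    reduce-on-plateau decay (factor ``lr_decay_factor`` after
    ``lr_patience`` stale epochs) and early stopping (after
    ``stop_patience`` stale epochs).  The network is left holding the
    weights of the best-validation epoch.  Returns the per-epoch history
    (train loss, validation MSE, learning rate).
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise LabelError("training and validation splits must be nonempty")
    if config.init_output_bias:
        # start the softmax at the class priors so optimization spends its
        # budget on sequence dependence rather than the marginal
        net.params["bo"] = np.log(Y_train.mean(axis=0) + 1e-8)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    m = {k: np.zeros_like(p) for k, p in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    lr = config.learning_rate
    best_val = np.inf
    best_state = net.state_dict()
    lr_wait = 0
    stop_wait = 0
    adam_t = 0
    rows = []
    n = len(X_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, grads, _ = net.loss_and_grads(X_train[idx], Y_train[idx], rng=drop_rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}; "
                    "reduce the learning rate or check the inputs"
                )
            adam_t += 1
            _adam_step(net.params, grads, m, v, adam_t, lr)
            losses.append(loss)
        val_pred = net.predict_proba(X_val)
        val_mse = float(np.mean((val_pred - Y_val) ** 2))
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_mse": val_mse, "lr": lr}
        )
        if val_mse < best_val:
            best_val = val_mse
            best_state = net.state_dict()
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= config.lr_patience:
                lr *= config.lr_decay_factor
                lr_wait = 0
            if stop_wait >= config.stop_patience:
                break
    net.load_state_dict(best_state)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimator


class IndelOutcomePredictor(BaseEstimator):
    """Sklearn-style estimator: 60 nt sequences -> 557-class distributions.

    ``fit(X, y)`` takes sequences (or pre-embedded (n, L, d) arrays) and
    soft-label target distributions; ``predict`` returns distributions on
    the simplex.  An unfitted :class:`~apindel.embedding.GloveEmbedder`
    may be supplied and is cloned and fitted on the training sequences.
    """

    def __init__(
        self,
        embedder=None,
        units: int = 50,
        attention_T: int = 64,
        mlp_hidden: int = 128,
        dropout_p: float = 0.5,
        l1_lambda: float = 1e-4,
        activation: str = "relu",
        batch_size: int = 64,
        learning_rate: float = 1e-4,
        max_epochs: int = 100,
        lr_decay_factor: float = 0.2,
        lr_patience: int = 1,
        stop_patience: int = 3,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.embedder = embedder
        self.units = units
        self.attention_T = attention_T
        self.mlp_hidden = mlp_hidden
        self.dropout_p = dropout_p
        self.l1_lambda = l1_lambda
        self.activation = activation
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.lr_decay_factor = lr_decay_factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self, d: int) -> NetworkConfig:
        return NetworkConfig(
            lstm_units=self.units,
            attention_T=self.attention_T,
            mlp_hidden=self.mlp_hidden,
            d=d,
            l1_lambda=self.l1_lambda,
            dropout_p=self.dropout_p,
            activation=self.activation,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            lr_decay_factor=self.lr_decay_factor,
            lr_patience=self.lr_patience,
            stop_patience=self.stop_patience,
            seed=self.random_state,
        )

    def _embed(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return X
        seqs = list(X)
        bad = [s for s in seqs if len(s) != 60]
        if bad:
            raise LabelError(
                f"model inputs must be 60 nt cut-centered windows; got length "
                f"{len(bad[0])} (window the sequence first)"
            )
        return self.embedder_.transform(seqs)

    def fit(self, X, y, validation_data=None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise LabelError("y must be (n_samples, n_classes) soft labels")
        if self.embedder is not None:
            # a pre-fitted embedder is reused as-is; an unfitted one is cloned
            if hasattr(self.embedder, "vectors_"):
                self.embedder_ = self.embedder
            else:
                self.embedder_ = clone(self.embedder)
        else:
            from .embedding import GloveEmbedder

            self.embedder_ = GloveEmbedder(random_state=self.random_state)
        is_seqs = not (isinstance(X, np.ndarray) and X.ndim == 3)
        if is_seqs and not hasattr(self.embedder_, "vectors_"):
            self.embedder_.fit(list(X))
        E = self._embed(X)
        if validation_data is not None:
            Xv, yv = validation_data
            Ev = self._embed(Xv)
            yv = np.asarray(yv, dtype=float)
            Et, yt = E, y
        else:
            rng = np.random.default_rng(self.random_state)
            n = len(E)
            n_val = max(1, int(round(self.validation_fraction * n)))
            if n - n_val < 1:
                raise LabelError("not enough samples to hold out a validation split")
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            Et, yt = E[tr_idx], y[tr_idx]
            Ev, yv = E[val_idx], y[val_idx]
        cfg = self._config(d=E.shape[2])
        self.network_ = ApindelNetwork(
            input_dim=E.shape[2],
            seq_len=E.shape[1],
            n_classes=y.shape[1],
            units=self.units,
            attention_T=self.attention_T,
            mlp_hidden=self.mlp_hidden,
            dropout_p=self.dropout_p,
            l1_lambda=self.l1_lambda,
            activation=self.activation,
            seed=self.random_state,
        )
        self.history_ = train_network(self.network_, Et, yt, Ev, yv, cfg)
        self.best_val_mse_ = float(self.history_["val_mse"].min())
        self.n_classes_ = y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted outcome distributions (rows on the simplex)."""
        return self.network_.predict_proba(self._embed(X))

    def attention(self, X) -> np.ndarray:
        """Per-record attention vectors over token positions."""
        return self.network_.attention(self._embed(X))

    def attention_profile(self, X) -> np.ndarray:
        """Mean attention vector over the given records (sums to 1)."""
        a = self.attention(X)
        if a.shape[0] == 0:
            raise LabelError("attention profile of an empty record list")
        return a.mean(axis=0)


# ---------------------------------------------------------------------------
# Thin functional wrappers


def predict(model: IndelOutcomePredictor, record) -> np.ndarray:
    """Predict the outcome distribution of one target record or sequence."""
    seq = record.sequence if hasattr(record, "sequence") else record
    return model.predict([seq])[0]


def train(config: NetworkConfig, train_set, validation_set, embedder=None):
    """Train an :class:`IndelOutcomePredictor` from two record lists.

    Records need ``sequence`` and ``distribution`` attributes; returns the
    fitted estimator.
    """
    model = IndelOutcomePredictor(
        embedder=embedder,
        units=config.lstm_units,
        attention_T=config.attention_T,
        mlp_hidden=config.mlp_hidden,
        dropout_p=config.dropout_p,
        l1_lambda=config.l1_lambda,
        activation=config.activation,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        lr_decay_factor=config.lr_decay_factor,
        lr_patience=config.lr_patience,
        stop_patience=config.stop_patience,
        random_state=config.seed,
    )
    Xt = [r.sequence for r in train_set]
    yt = np.stack([r.distribution for r in train_set])
    Xv = [r.sequence for r in validation_set]
    yv = np.stack([r.distribution for r in validation_set])
    return model.fit(Xt, yt, validation_data=(Xv, yv))


def attention_profile(model: IndelOutcomePredictor, records) -> np.ndarray:
    """Elementwise mean of per-record attention vectors."""
    seqs = [r.sequence if hasattr(r, "sequence") else r for r in records]
    if not seqs:
        raise LabelError("attention profile of an empty record list")
    return model.attention_profile(seqs)
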