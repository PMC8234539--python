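"""Deep survival network producing a scalar per-patient risk score.

Architecture: the input feeds a "dense box" of three 48-unit layers with
DenseNet-style wiring (each layer sees the raw input concatenated with
every earlier layer's output); the concatenated representation then
passes through an "auto-coding box" (48 -> 48 -> 24 bottleneck, with an
optional L1 activity penalty on the 24-unit code to encourage sparse
codes) and a linear 1-unit risk head.  Training is full-batch Adam on
the negative log Cox partial likelihood (Breslow ties) with dropout and
early stopping on a validation split; the best-validation weights are
restored.

Implemented directly on numpy with hand-derived gradients (verified
against finite differences in the test suite) — the cohorts are a few
hundred rows, so there is nothing for a GPU framework to do here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "DSNNConfig",
    "DSNNModel",
    "TrainingLog",
    "cox_partial_nll",
    "cox_partial_nll_grad",
    "build_network",
    "train",
    "predict_risk",
]

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@dataclass
class DSNNConfig:
    dense_layers: tuple = (48, 48, 48)
    autocode_layers: tuple = (48, 48, 24)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.2
    l1_activity_weight: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.l1_activity_weight < 0:
            raise ValueError("l1_activity_weight must be >= 0")


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow), stabilized
# ---------------------------------------------------------------------------


def _risk_set_logsumexp(risk, time):
    """Per-event log sum over the risk set, with tie-aware risk sets.

    Returns (event_idx, log_denominators) for the ordering sorted by
    descending time.
    """
    order = np.argsort(-time, kind="stable")
    r = risk[order]
    t = time[order]
    m = r.max()
    csum = np.cumsum(np.exp(r - m))
    last = np.searchsorted(-t, -t, side="right") - 1
    return order, m + np.log(csum[last])


def cox_partial_nll(risk, time, event) -> float:
    """Negative log Cox partial likelihood (sum over events, Breslow ties)."""
    risk = np.asarray(risk, dtype=float).ravel()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("partial likelihood needs at least one event")
    order, log_denom = _risk_set_logsumexp(risk, time)
    es = event[order]
    rs = risk[order]
    return float(-(rs[es == 1] - log_denom[es == 1]).sum())


def cox_partial_nll_grad(risk, time, event) -> np.ndarray:
    """Analytic gradient of ``cox_partial_nll`` with respect to the risks."""
    risk = np.asarray(risk, dtype=float).ravel()
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("partial likelihood needs at least one event")

    order = np.argsort(-time, kind="stable")
    r = risk[order]
    t = time[order]
    e = event[order]
    m = r.max()
    expr = np.exp(r - m)
    csum = np.cumsum(expr)
    last = np.searchsorted(-t, -t, side="right") - 1
    denom = csum[last]  # scaled by exp(-m), cancels below

    # dL/dr_j = -e_j + exp(r_j) * sum_{events i with t_i <= t_j} 1 / denom_i
    inv = np.where(e == 1, 1.0 / denom, 0.0)
    # events with t_i <= t_j are, in descending-time order, positions >= first
    # index of t_j's tie block... accumulate reverse cumulative sum of inv over
    # positions, then index at the FIRST position of each tie block.
    rev_csum = np.cumsum(inv[::-1])[::-1]
    first = np.searchsorted(-t, -t, side="left")
    grad_sorted = -e + expr * rev_csum[first]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return grad


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _selu(z):
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(z) - 1.0))


def _selu_grad(z):
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


@dataclass
class DSNNModel:
    config: DSNNConfig
    n_features: int
    weights: list = dc_field(default_factory=list)   # [(W, b), ...]
    feature_names: list | None = None

    def copy_weights(self):
        return [(W.copy(), b.copy()) for W, b in self.weights]

    def set_weights(self, weights):
        self.weights = [(W.copy(), b.copy()) for W, b in weights]

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in self.weights)


def _layer_dims(config: DSNNConfig, n_features: int):
    """Input/output sizes of every layer in order (dense, autocode, head)."""
    dims = []
    width = n_features
    for h in config.dense_layers:
        dims.append((width, h))
        width += h  # DenseNet concatenation grows the running input
    for h in config.autocode_layers:
        dims.append((width, h))
        width = h
    dims.append((width, 1))
    return dims


def build_network(config: DSNNConfig, n_features: int,
                  feature_names=None) -> DSNNModel:
    """Initialize the model (LeCun-normal init, suited to SELU)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(config.seed)
    weights = []
    for fan_in, fan_out in _layer_dims(config, n_features):
        W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return DSNNModel(config, n_features, weights,
                     list(feature_names) if feature_names is not None else None)


def _forward(model: DSNNModel, X: np.ndarray, rng=None):
    """Forward pass; dropout active only when an rng is supplied.

    Returns (risk, cache) where cache holds everything backward needs.
    """
    cfg = model.config
    nd = len(cfg.dense_layers)
    na = len(cfg.autocode_layers)
    p = cfg.dropout_rate if rng is not None else 0.0

    cache = {"inputs": [], "zs": [], "drops": [], "X": X}
    cur = X
    dense_outs = []
    for li in range(nd):
        W, b = model.weights[li]
        z = cur @ W + b
        a = _selu(z)
        if p > 0:
            keep = (rng.uniform(size=a.shape) >= p) / (1.0 - p)
            a = a * keep
        else:
            keep = None
        cache["inputs"].append(cur)
        cache["zs"].append(z)
        cache["drops"].append(keep)
        dense_outs.append(a)
        cur = np.concatenate([X] + dense_outs, axis=1)

    for ai in range(na):
        W, b = model.weights[nd + ai]
        z = cur @ W + b
        a = _selu(z)
        last_hidden = ai == na - 1
        if p > 0 and not last_hidden:  # keep the code layer deterministic-ish
            keep = (rng.uniform(size=a.shape) >= p) / (1.0 - p)
            a = a * keep
        else:
            keep = None
        cache["inputs"].append(cur)
        cache["zs"].append(z)
        cache["drops"].append(keep)
        cur = a
    cache["code"] = cur

    W, b = model.weights[nd + na]
    risk = (cur @ W + b).ravel()
    cache["inputs"].append(cur)
    return risk, cache


def _backward(model: DSNNModel, cache, d_risk: np.ndarray,
              l1_weight: float):
    """Gradients of loss wrt every (W, b), given dLoss/dRisk."""
    cfg = model.config
    nd = len(cfg.dense_layers)
    na = len(cfg.autocode_layers)
    X = cache["X"]
    n_feat = X.shape[1]

    grads = [None] * len(model.weights)

    # head
    W_head, _ = model.weights[nd + na]
    code_in = cache["inputs"][nd + na]
    d_out = d_risk[:, None]
    grads[nd + na] = (code_in.T @ d_out, d_out.sum(axis=0))
    d_a = d_out @ W_head.T

    # L1 activity penalty on the code
    if l1_weight > 0:
        d_a = d_a + l1_weight * np.sign(cache["code"])

    # autocode box (plain chain)
    for ai in range(na - 1, -1, -1):
        li = nd + ai
        keep = cache["drops"][li]
        if keep is not None:
            d_a = d_a * keep
        d_z = d_a * _selu_grad(cache["zs"][li])
        W, _ = model.weights[li]
        grads[li] = (cache["inputs"][li].T @ d_z, d_z.sum(axis=0))
        d_a = d_z @ W.T  # gradient wrt this layer's (concatenated) input

    # d_a is now the gradient wrt concat(X, h_0 .. h_{nd-1});
    # peel dense layers from the last to the first, accumulating the
    # gradient each hidden output receives from every later consumer.
    widths = list(cfg.dense_layers)
    d_h = []  # gradient wrt each dense output
    offset = n_feat
    for w in widths:
        d_h.append(d_a[:, offset:offset + w].copy())
        offset += w

    for li in range(nd - 1, -1, -1):
        d_al = d_h[li]
        keep = cache["drops"][li]
        if keep is not None:
            d_al = d_al * keep
        d_z = d_al * _selu_grad(cache["zs"][li])
        W, _ = model.weights[li]
        grads[li] = (cache["inputs"][li].T @ d_z, d_z.sum(axis=0))
        d_in = d_z @ W.T  # wrt concat(X, h_0 .. h_{li-1})
        off = n_feat
        for j in range(li):
            d_h[j] += d_in[:, off:off + widths[j]]
            off += widths[j]
    return grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainingLog:
    epochs: list
    train_loss: list
    val_loss: list
    best_epoch: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "train_loss":
                             self.train_loss, "val_loss": self.val_loss})


def _as_matrix(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    return np.asarray(features, dtype=float), None


def train(features, time, event, config: DSNNConfig):
    """Fit the network full-batch with Adam and early stopping.

    Features are z-standardized with training-split statistics (stored on
    the model for prediction).  Returns ``(model, TrainingLog)``.
    """
    X, names = _as_matrix(features)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(X)
    rng = np.random.default_rng(config.seed)

    idx = rng.permutation(n)
    n_val = max(int(round(config.val_fraction * n)), 1)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    if event[tr_idx].sum() < 2:
        raise ValueError("training split needs at least 2 events")
    if event[val_idx].sum() < 1:
        # move one event into validation to keep the early-stop signal defined
        ev = tr_idx[event[tr_idx] == 1]
        val_idx = np.append(val_idx, ev[-1])
        tr_idx = tr_idx[tr_idx != ev[-1]]

    mu = X[tr_idx].mean(axis=0)
    sd = X[tr_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    Xtr, Xval = Xs[tr_idx], Xs[val_idx]

    model = build_network(config, X.shape[1], names)
    model.norm_mu, model.norm_sd = mu, sd

    # Adam state
    m_t = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    v_t = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_val = np.inf
    best_weights = model.copy_weights()
    best_epoch = 0
    wait = 0
    log_e, log_tr, log_val = [], [], []
    drop_rng = np.random.default_rng(config.seed + 1)

    n_ev = event[tr_idx].sum()
    for epoch in range(1, config.max_epochs + 1):
        risk, cache = _forward(model, Xtr,
                               rng=drop_rng if config.dropout_rate > 0
                               else None)
        loss = cox_partial_nll(risk, time[tr_idx], event[tr_idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (non-finite loss) at epoch {epoch}; "
                f"last finite epoch {epoch - 1}"
            )
        d_risk = cox_partial_nll_grad(risk, time[tr_idx], event[tr_idx]) / n_ev
        grads = _backward(model, cache, d_risk, config.l1_activity_weight)

        new_weights = []
        for li, ((W, b), (gW, gb)) in enumerate(zip(model.weights, grads)):
            mW, mb = m_t[li]
            vW, vb = v_t[li]
            mW = beta1 * mW + (1 - beta1) * gW
            mb = beta1 * mb + (1 - beta1) * gb
            vW = beta2 * vW + (1 - beta2) * gW**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            m_t[li] = (mW, mb)
            v_t[li] = (vW, vb)
            bc1 = 1 - beta1**epoch
            bc2 = 1 - beta2**epoch
            W = W - config.learning_rate * (mW / bc1) / (
                np.sqrt(vW / bc2) + eps)
            b = b - config.learning_rate * (mb / bc1) / (
                np.sqrt(vb / bc2) + eps)
            new_weights.append((W, b))
        model.weights = new_weights

        val_risk, _ = _forward(model, Xval)
        try:
            val_loss = cox_partial_nll(val_risk, time[val_idx],
                                       event[val_idx])
        except ValueError:
            val_loss = np.inf
        log_e.append(epoch)
        log_tr.append(loss)
        log_val.append(float(val_loss))

        if val_loss < best_val - 1e-10:
            best_val = val_loss
            best_weights = model.copy_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break

    model.set_weights(best_weights)
    return model, TrainingLog(log_e, log_tr, log_val, best_epoch)


def predict_risk(model: DSNNModel, features) -> np.ndarray:
    """Deterministic per-patient risk scores (dropout disabled).

    DataFrame inputs are aligned to the training feature names; missing or
    extra columns raise with the offending names.
    """
    if isinstance(features, pd.DataFrame):
        if model.feature_names is not None:
            missing = [c for c in model.feature_names
                       if c not in features.columns]
            extra = [c for c in features.columns
                     if c not in model.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature columns mismatch: missing={missing}, "
                    f"extra={extra}"
                )
            features = features[model.feature_names]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if hasattr(model, "norm_mu"):
        X = (X - model.norm_mu) / model.norm_sd
    risk, _ = _forward(model, X)
    return risk
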