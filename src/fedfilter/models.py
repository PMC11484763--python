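"""Prediction models consuming K-dimensional filtered representations.

Three families cover the three data modalities:

* ``feedforward`` — single-hidden-layer MLP (default 128 ReLU units) with a
  per-label logistic head, for tabular data;
* ``recurrent``   — a GRU with 128 hidden units read over the T x K filtered
  sequence, logistic head on the final hidden state, for time series;
* ``graphconv``   — a two-layer GCN (K -> 128 -> labels) with symmetric
  degree-normalised adjacency and self-loops, predicting per node.

All parameters live in a :class:`~fedfilter.params.ParamDict`; every family
implements an explicit forward (with cache) and reverse pass so that exact
analytic gradients of loss(model(filter(x))) are available to the federated
optimiser without an autodiff dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .filtering import sigmoid
from .params import ParamDict

__all__ = ["ModelSpec", "build_model", "predict", "loss", "loss_grad_logits"]

_KINDS = ("feedforward", "recurrent", "graphconv")
_TASKS = ("binary", "multilabel")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract shared by server and clients."""

    kind: str
    input_dim: int            # K, the knowledge-vector length
    hidden_dim: int = 128
    output_dim: int = 1       # number of target labels
    task: str = "binary"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {_KINDS}")
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {_TASKS}")
        if self.input_dim < 1 or self.hidden_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim, hidden_dim and output_dim must be positive")
        if self.task == "binary" and self.output_dim != 1:
            raise ValueError("binary task requires output_dim == 1")


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    s = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-s, s, size=shape)


def build_model(spec: ModelSpec, seed: int) -> ParamDict:
    """Deterministically initialise parameters for ``spec``.

    Weights are uniform in [-1/sqrt(fan_in), 1/sqrt(fan_in)]; biases zero.
    """
    rng = np.random.default_rng(seed)
    K, H, O = spec.input_dim, spec.hidden_dim, spec.output_dim
    if spec.kind == "feedforward":
        return ParamDict({
            "W1": _uniform(rng, K, (K, H)),
            "b1": np.zeros(H),
            "W2": _uniform(rng, H, (H, O)),
            "b2": np.zeros(O),
        })
    if spec.kind == "recurrent":
        p = {}
        for gate in ("z", "r", "n"):
            p[f"W{gate}"] = _uniform(rng, K, (K, H))
            p[f"U{gate}"] = _uniform(rng, H, (H, H))
            p[f"b{gate}"] = np.zeros(H)
        p["Wo"] = _uniform(rng, H, (H, O))
        p["bo"] = np.zeros(O)
        return ParamDict(p)
    if spec.kind == "graphconv":
        return ParamDict({
            "Wg1": _uniform(rng, K, (K, H)),
            "bg1": np.zeros(H),
            "Wg2": _uniform(rng, H, (H, O)),
            "bg2": np.zeros(O),
        })
    raise ValueError(spec.kind)  # unreachable; __post_init__ guards


# ---------------------------------------------------------------------------
# adjacency normalisation for graphconv
# ---------------------------------------------------------------------------

def normalized_adjacency(n_nodes: int, edges: np.ndarray) -> sp.csr_matrix:
    """Symmetric GCN propagation matrix D^{-1/2} (A + I) D^{-1/2}.

    ``edges`` is an (E, 2) integer array; both directions may or may not be
    present — the matrix is symmetrised, self-loops are added once.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    data = np.ones(len(edges))
    A = sp.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes))
    A = A.maximum(A.T)          # symmetrise, collapse duplicates
    A = A.tolil()
    A.setdiag(1.0)              # self-loops
    A = A.tocsr()
    A.data[:] = 1.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    Dinv = sp.diags(dinv)
    return (Dinv @ A @ Dinv).tocsr()


# ---------------------------------------------------------------------------
# forward passes with caches
# ---------------------------------------------------------------------------

def _ff_forward(p: ParamDict, X: np.ndarray):
    Z_pre = X @ p["W1"] + p["b1"]
    Z = np.maximum(Z_pre, 0.0)
    logits = Z @ p["W2"] + p["b2"]
    return logits, {"X": X, "Z_pre": Z_pre, "Z": Z}


def _ff_backward(p: ParamDict, cache, dlogits: np.ndarray):
    Z, Z_pre, X = cache["Z"], cache["Z_pre"], cache["X"]
    grads = {
        "W2": Z.T @ dlogits,
        "b2": dlogits.sum(axis=0),
    }
    dZ = dlogits @ p["W2"].T
    dZ_pre = dZ * (Z_pre > 0.0)
    grads["W1"] = X.T @ dZ_pre
    grads["b1"] = dZ_pre.sum(axis=0)
    dX = dZ_pre @ p["W1"].T
    ordered = ParamDict({k: grads[k] for k in ("W1", "b1", "W2", "b2")})
    return ordered, dX


def _gru_forward(p: ParamDict, X: np.ndarray):
    """X: (B, T, K) -> logits (B, O) from the final hidden state."""
    B, T, _ = X.shape
    Hdim = p["Uz"].shape[0]
    h = np.zeros((B, Hdim))
    steps = []
    for t in range(T):
        x = X[:, t, :]
        z = sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        n = np.tanh(x @ p["Wn"] + (r * h) @ p["Un"] + p["bn"])
        h_new = (1.0 - z) * n + z * h
        steps.append({"x": x, "h_prev": h, "z": z, "r": r, "n": n})
        h = h_new
    logits = h @ p["Wo"] + p["bo"]
    return logits, {"steps": steps, "h_final": h, "shape": X.shape}


def _gru_backward(p: ParamDict, cache, dlogits: np.ndarray):
    B, T, K = cache["shape"]
    grads = {k: np.zeros_like(p[k]) for k in p}
    grads["Wo"] = cache["h_final"].T @ dlogits
    grads["bo"] = dlogits.sum(axis=0)
    dh = dlogits @ p["Wo"].T
    dX = np.zeros((B, T, K))
    for t in range(T - 1, -1, -1):
        st = cache["steps"][t]
        x, h_prev, z, r, n = st["x"], st["h_prev"], st["z"], st["r"], st["n"]
        # h = (1-z)*n + z*h_prev
        dz_pre = dh * (h_prev - n) * z * (1.0 - z)
        dn_pre = dh * (1.0 - z) * (1.0 - n * n)
        dh_prev = dh * z
        # n = tanh(x Wn + (r*h_prev) Un + bn)
        grads["Wn"] += x.T @ dn_pre
        grads["Un"] += (r * h_prev).T @ dn_pre
        grads["bn"] += dn_pre.sum(axis=0)
        drh = dn_pre @ p["Un"].T
        dr_pre = drh * h_prev * r * (1.0 - r)
        dh_prev += drh * r
        # r = sigmoid(x Wr + h_prev Ur + br)
        grads["Wr"] += x.T @ dr_pre
        grads["Ur"] += h_prev.T @ dr_pre
        grads["br"] += dr_pre.sum(axis=0)
        dh_prev += dr_pre @ p["Ur"].T
        # z = sigmoid(x Wz + h_prev Uz + bz)
        grads["Wz"] += x.T @ dz_pre
        grads["Uz"] += h_prev.T @ dz_pre
        grads["bz"] += dz_pre.sum(axis=0)
        dh_prev += dz_pre @ p["Uz"].T
        dX[:, t, :] = dn_pre @ p["Wn"].T + dr_pre @ p["Wr"].T + dz_pre @ p["Wz"].T
        dh = dh_prev
    ordered = ParamDict({k: grads[k] for k in p})
    return ordered, dX


def _gcn_forward(p: ParamDict, X: np.ndarray, A: sp.csr_matrix):
    AX = A @ X
    Z_pre = AX @ p["Wg1"] + p["bg1"]
    Z = np.maximum(Z_pre, 0.0)
    AZ = A @ Z
    logits = AZ @ p["Wg2"] + p["bg2"]
    return logits, {"AX": AX, "Z_pre": Z_pre, "AZ": AZ, "A": A}


def _gcn_backward(p: ParamDict, cache, dlogits: np.ndarray):
    A = cache["A"]
    grads = {
        "Wg2": cache["AZ"].T @ dlogits,
        "bg2": dlogits.sum(axis=0),
    }
    dAZ = dlogits @ p["Wg2"].T
    dZ = A.T @ dAZ              # A symmetric, but keep the transpose explicit
    dZ_pre = dZ * (cache["Z_pre"] > 0.0)
    grads["Wg1"] = cache["AX"].T @ dZ_pre
    grads["bg1"] = dZ_pre.sum(axis=0)
    dAX = dZ_pre @ p["Wg1"].T
    dX = A.T @ dAX
    ordered = ParamDict({k: grads[k] for k in ("Wg1", "bg1", "Wg2", "bg2")})
    return ordered, dX


def model_forward(params: ParamDict, spec: ModelSpec, rep, adjacency: sp.csr_matrix | None = None):
    """Forward pass to logits with cache; ``rep`` is batched.

    feedforward: rep (B, K); recurrent: rep (B, T, K); graphconv: rep (N, K)
    with ``adjacency`` the normalised propagation matrix.
    """
    rep = np.asarray(rep, dtype=np.float64)
    if spec.kind == "feedforward":
        if rep.ndim != 2 or rep.shape[1] != spec.input_dim:
            raise ValueError(f"feedforward expects (B, {spec.input_dim}), got {rep.shape}")
        return _ff_forward(params, rep)
    if spec.kind == "recurrent":
        if rep.ndim != 3 or rep.shape[2] != spec.input_dim:
            raise ValueError(f"recurrent expects (B, T, {spec.input_dim}), got {rep.shape}")
        return _gru_forward(params, rep)
    if spec.kind == "graphconv":
        if rep.ndim != 2 or rep.shape[1] != spec.input_dim:
            raise ValueError(f"graphconv expects (N, {spec.input_dim}), got {rep.shape}")
        if adjacency is None:
            raise ValueError("graphconv requires the normalised adjacency matrix")
        return _gcn_forward(params, rep, adjacency)
    raise ValueError(spec.kind)


def model_backward(params: ParamDict, spec: ModelSpec, cache, dlogits: np.ndarray):
    """Reverse pass: returns (dparams, drep)."""
    if spec.kind == "feedforward":
        return _ff_backward(params, cache, dlogits)
    if spec.kind == "recurrent":
        return _gru_backward(params, cache, dlogits)
    if spec.kind == "graphconv":
        return _gcn_backward(params, cache, dlogits)
    raise ValueError(spec.kind)


def predict(params: ParamDict, spec: ModelSpec, rep, adjacency: sp.csr_matrix | None = None) -> np.ndarray:
    """Per-label probabilities for a batched filtered input.

    Single samples may be passed un-batched (a (K,) vector or (T, K) series);
    the batch axis is then added and squeezed transparently.
    """
    rep = np.asarray(rep, dtype=np.float64)
    squeeze = False
    if spec.kind == "feedforward" and rep.ndim == 1:
        rep, squeeze = rep[None, :], True
    if spec.kind == "recurrent" and rep.ndim == 2:
        rep, squeeze = rep[None, :, :], True
    logits, _ = model_forward(params, spec, rep, adjacency=adjacency)
    probs = sigmoid(logits)
    if squeeze:
        probs = probs[0]
    return probs


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

_EPS = 1e-12


def loss(pred: np.ndarray, y: np.ndarray, task: str = "binary") -> float:
    """Mean binary cross-entropy over samples and labels.

    Multilabel targets are treated as independent per-label Bernoulli
    outcomes (macro mean over all entries).  Predictions are clipped at
    1e-12 from the boundary before taking logs.
    """
    if task not in _TASKS:
        raise ValueError(f"unknown task {task!r}")
    pred = np.asarray(pred, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError(f"pred shape {pred.shape} != label shape {y.shape}")
    if np.any((pred < 0.0) | (pred > 1.0)) or not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("labels must be binary 0/1")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def loss_grad_logits(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) = (p - y) / n_entries  — used by training."""
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return (probs - y) / probs.size
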