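"""Knowledge abstraction and filtering.

The filtering module maps a client's D-dimensional sample onto the shared
K-dimensional latent space spanned by the global knowledge vector ``h``.
Two dense layers (no internal nonlinearity) embed the sample and the
knowledge vector respectively; the averaged embedding passes through a
sigmoid to yield a mask ``M`` in (0,1)^K which gates ``h``::

    e1 = W1^T x + b1          (W1: D x K)
    e2 = W2^T h + b2          (W2: K x K)
    M  = sigmoid((e1 + e2) / 2)
    x' = M * h                (element-wise)

Because the mask is strictly inside (0,1), the filtered representation is
an element-wise attenuation of the knowledge vector: |x'_i| <= |h_i|.

Filtering can be applied recursively: stage r receives the previous
stage's output as its knowledge vector while the original sample is reused
at every stage.  Time-series and graphs are handled by applying one shared
filter stack to every time step / node independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParamDict

__all__ = [
    "FilterParams",
    "FilterStack",
    "FilteredRepresentation",
    "init_filter_params",
    "init_filter_stack",
    "filter_forward",
    "recursive_filter",
    "filter_timeseries",
    "filter_graph",
]


# the filter mask must stay strictly inside (0,1) even where the sigmoid
# saturates in float64 (|pre-activation| > ~37)
_MASK_LO = np.nextafter(0.0, 1.0)
_MASK_HI = np.nextafter(1.0, 0.0)


def _mask_sigmoid(z: np.ndarray) -> np.ndarray:
    return np.clip(sigmoid(z), _MASK_LO, _MASK_HI)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FilterParams:
    """One filtering stage: two dense layers (D->K and K->K)."""

    W1: np.ndarray  # (D, K)
    b1: np.ndarray  # (K,)
    W2: np.ndarray  # (K, K)
    b2: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        D, K = self.W1.shape
        if self.b1.shape != (K,):
            raise ValueError(f"b1 shape {self.b1.shape} inconsistent with W1 {self.W1.shape}")
        if self.W2.shape != (K, K):
            raise ValueError(f"W2 shape {self.W2.shape} must be ({K}, {K})")
        if self.b2.shape != (K,):
            raise ValueError(f"b2 shape {self.b2.shape} inconsistent with K={K}")
        for name in ("W1", "b1", "W2", "b2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in filter parameter {name}")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def knowledge_dim(self) -> int:
        return self.W1.shape[1]


@dataclass
class FilterStack:
    """R >= 1 filtering stages sharing the same D and K.

    Every stage's first layer consumes the *original* sample (W1 is D x K at
    each stage); only the knowledge-vector input changes between stages.
    """

    stages: list[FilterParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("a FilterStack needs at least one stage")
        D, K = self.stages[0].input_dim, self.stages[0].knowledge_dim
        for i, st in enumerate(self.stages):
            if st.input_dim != D or st.knowledge_dim != K:
                raise ValueError(
                    f"stage {i} has (D,K)=({st.input_dim},{st.knowledge_dim}), "
                    f"expected ({D},{K})"
                )

    @property
    def depth(self) -> int:
        return len(self.stages)

    @property
    def input_dim(self) -> int:
        return self.stages[0].input_dim

    @property
    def knowledge_dim(self) -> int:
        return self.stages[0].knowledge_dim

    # federation needs flat named parameters for checkpoints / optimisers
    def to_paramdict(self) -> ParamDict:
        out = {}
        for r, st in enumerate(self.stages):
            out[f"stage{r}.W1"] = st.W1
            out[f"stage{r}.b1"] = st.b1
            out[f"stage{r}.W2"] = st.W2
            out[f"stage{r}.b2"] = st.b2
        return ParamDict(out)

    @staticmethod
    def from_paramdict(p: ParamDict) -> "FilterStack":
        stages = []
        r = 0
        while f"stage{r}.W1" in p:
            stages.append(
                FilterParams(
                    W1=p[f"stage{r}.W1"], b1=p[f"stage{r}.b1"],
                    W2=p[f"stage{r}.W2"], b2=p[f"stage{r}.b2"],
                )
            )
            r += 1
        return FilterStack(stages)


@dataclass
class FilteredRepresentation:
    """Final-stage output: gated knowledge vector and the gate itself."""

    values: np.ndarray  # (K,)
    mask: np.ndarray    # (K,), entries strictly in (0, 1)


def init_filter_params(D: int, K: int, rng: np.random.Generator) -> FilterParams:
    """Fan-in-scaled uniform init: W1 ~ U[-1/sqrt(D), 1/sqrt(D)], W2 ~ U[-1/sqrt(K), 1/sqrt(K)], zero biases."""
    if D < 1:
        raise ValueError("input dimension D must be >= 1")
    if K < 1:
        raise ValueError("knowledge dimension K must be >= 1")
    s1, s2 = 1.0 / np.sqrt(D), 1.0 / np.sqrt(K)
    return FilterParams(
        W1=rng.uniform(-s1, s1, size=(D, K)),
        b1=np.zeros(K),
        W2=rng.uniform(-s2, s2, size=(K, K)),
        b2=np.zeros(K),
    )


def init_filter_stack(D: int, K: int, depth: int, rng: np.random.Generator) -> FilterStack:
    if depth < 1:
        raise ValueError("recursion depth must be >= 1")
    return FilterStack([init_filter_params(D, K, rng) for _ in range(depth)])


def _validate_sample(x: np.ndarray, D: int, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a 1-d feature vector, got shape {x.shape}")
    if x.shape[0] != D:
        raise ValueError(f"{name} has {x.shape[0]} features, filter expects D={D}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite entries in {name}")
    return x


def _validate_h(h: np.ndarray, K: int) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 1 or h.shape[0] != K:
        raise ValueError(f"knowledge vector has shape {h.shape}, filter expects length K={K}")
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite entries in knowledge vector h")
    return h


# ---------------------------------------------------------------------------
# forward passes (public, single-sample API)
# ---------------------------------------------------------------------------

def filter_forward(x: np.ndarray, h: np.ndarray, p: FilterParams) -> FilteredRepresentation:
    """Apply one filtering stage to one sample.

    Parameters
    ----------
    x : (D,) sample in the client's native view.
    h : (K,) knowledge vector.
    p : the stage's parameters.

    Returns
    -------
    FilteredRepresentation with ``values = M * h`` and ``mask = M``.
    """
    x = _validate_sample(x, p.input_dim)
    h = _validate_h(h, p.knowledge_dim)
    e1 = p.W1.T @ x + p.b1
    e2 = p.W2.T @ h + p.b2
    M = _mask_sigmoid((e1 + e2) / 2.0)
    return FilteredRepresentation(values=M * h, mask=M)


def recursive_filter(x: np.ndarray, h: np.ndarray, stack: FilterStack) -> FilteredRepresentation:
    """Apply the stack: stage r consumes (x, h_{r-1}) with h_0 = h."""
    rep = None
    h_cur = h
    for st in stack.stages:
        rep = filter_forward(x, h_cur, st)
        h_cur = rep.values
    assert rep is not None
    return rep


def filter_timeseries(series: np.ndarray, h: np.ndarray, stack: FilterStack) -> np.ndarray:
    """Filter every time step of a (T, D) series with one shared stack -> (T, K)."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError(f"series must be a (T, D) matrix, got shape {series.shape}")
    return batch_filter(series, h, stack)[0]


def filter_graph(node_features: np.ndarray, h: np.ndarray, stack: FilterStack) -> np.ndarray:
    """Filter every node's feature vector with one shared stack -> (N, K).

    Edges are untouched: filtering is a per-node map, so any graph structure
    carried alongside the node table passes through unchanged.
    """
    node_features = np.asarray(node_features, dtype=np.float64)
    if node_features.ndim != 2:
        raise ValueError(
            f"node_features must be an (N, D) matrix, got shape {node_features.shape}"
        )
    return batch_filter(node_features, h, stack)[0]


# ---------------------------------------------------------------------------
# batched forward/backward used by training (rows are independent samples)
# ---------------------------------------------------------------------------

def batch_filter(X: np.ndarray, h: np.ndarray, stack: FilterStack):
    """Vectorised recursive filtering of a (B, D) batch.

    Returns ``(values, cache)`` where values is (B, K) and cache holds the
    per-stage intermediates needed by :func:`batch_filter_backward`.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected a (B, D) batch, got shape {X.shape}")
    if X.shape[1] != stack.input_dim:
        raise ValueError(
            f"batch has D={X.shape[1]} features, filter stack expects D={stack.input_dim}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in input batch")
    h = _validate_h(h, stack.knowledge_dim)

    B = X.shape[0]
    H = np.broadcast_to(h, (B, h.shape[0])).copy()  # stage-0 knowledge input
    caches = []
    for st in stack.stages:
        E1 = X @ st.W1 + st.b1              # (B, K)
        E2 = H @ st.W2 + st.b2              # (B, K)
        M = _mask_sigmoid((E1 + E2) / 2.0)
        values = M * H
        caches.append({"H_in": H, "M": M})
        H = values
    return H, {"X": X, "stages": caches}


def batch_filter_backward(dvalues: np.ndarray, stack: FilterStack, cache):
    """Backprop through :func:`batch_filter`.

    Parameters
    ----------
    dvalues : (B, K) gradient w.r.t. the final filtered representations.

    Returns
    -------
    (dphi, dh, dX) where dphi is a ParamDict matching ``stack.to_paramdict()``,
    dh is the (K,) gradient w.r.t. the shared knowledge vector (summed over
    the batch), and dX is the (B, D) gradient w.r.t. the inputs.
    """
    X = cache["X"]
    dX = np.zeros_like(X)
    grads = {}
    dH = np.asarray(dvalues, dtype=np.float64)
    for r in range(stack.depth - 1, -1, -1):
        st = stack.stages[r]
        c = cache["stages"][r]
        H_in, M = c["H_in"], c["M"]
        dM = dH * H_in
        dH_in = dH * M
        dA = dM * M * (1.0 - M) * 0.5       # d/dpre of sigmoid((E1+E2)/2)
        # E1 = X @ W1 + b1
        grads[f"stage{r}.W1"] = X.T @ dA
        grads[f"stage{r}.b1"] = dA.sum(axis=0)
        dX += dA @ st.W1.T
        # E2 = H_in @ W2 + b2
        grads[f"stage{r}.W2"] = H_in.T @ dA
        grads[f"stage{r}.b2"] = dA.sum(axis=0)
        dH_in += dA @ st.W2.T
        dH = dH_in
    dh = dH.sum(axis=0)  # stage-0 H_in is h broadcast over the batch
    # order the ParamDict exactly like to_paramdict()
    ordered = {}
    for r in range(stack.depth):
        for part in ("W1", "b1", "W2", "b2"):
            ordered[f"stage{r}.{part}"] = grads[f"stage{r}.{part}"]
    return ParamDict(ordered), dh, dX
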