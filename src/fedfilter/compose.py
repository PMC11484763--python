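"""Forward and reverse passes of loss ∘ model ∘ filter.

One code path serves all three modalities.  The filter is optional: plain
baselines (FedAvg, standalone without filtering) feed raw views straight
into a model whose input dimension equals the view dimension.

Shapes by modality
------------------
tabular      X (B, D)      -> filtered (B, K)      -> feedforward
time series  X (B, T, D)   -> filtered (B, T, K)   -> recurrent
graph        X (N, D)+adj  -> filtered (N, K)      -> graphconv (per node)

For graphs the loss can be restricted to a subset of nodes (semi-supervised
node classification: the forward pass sees the whole graph, gradients flow
only from the masked nodes).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .filtering import FilterStack, batch_filter, batch_filter_backward, sigmoid
from .models import (ModelSpec, loss, loss_grad_logits, model_backward,
                     model_forward)
from .params import ParamDict

__all__ = ["forward_probs", "composed_loss_grads", "input_gradients"]


def _filter_input(X: np.ndarray, h: np.ndarray, stack: FilterStack):
    """Apply the stack row-wise; (B,T,D) series are flattened per step."""
    if X.ndim == 3:
        B, T, D = X.shape
        flat, cache = batch_filter(X.reshape(B * T, D), h, stack)
        return flat.reshape(B, T, -1), cache
    return batch_filter(X, h, stack)


def forward_probs(theta: ParamDict, spec: ModelSpec, X: np.ndarray,
                  h: np.ndarray | None = None, stack: FilterStack | None = None,
                  adjacency: sp.csr_matrix | None = None) -> np.ndarray:
    """Predicted probabilities for a batch, optionally through the filter."""
    X = np.asarray(X, dtype=np.float64)
    if stack is not None:
        if h is None:
            raise ValueError("filtering requires the knowledge vector h")
        rep, _ = _filter_input(X, h, stack)
    else:
        rep = X
    logits, _ = model_forward(theta, spec, rep, adjacency=adjacency)
    return sigmoid(logits)


def _align_labels(y: np.ndarray, logits_shape) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape != tuple(logits_shape):
        raise ValueError(f"labels shape {y.shape} incompatible with outputs {logits_shape}")
    return y


def composed_loss_grads(theta: ParamDict, spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                        h: np.ndarray | None = None, stack: FilterStack | None = None,
                        adjacency: sp.csr_matrix | None = None,
                        loss_mask: np.ndarray | None = None):
    """Loss and exact gradients w.r.t. (theta, h, phi) for one batch.

    Returns ``(loss_value, d_theta, d_h, d_phi)``; the latter two are None
    when no filter is in play.  ``loss_mask`` (graphs) selects the rows that
    contribute to the loss.
    """
    X = np.asarray(X, dtype=np.float64)
    use_filter = stack is not None
    if use_filter:
        if h is None:
            raise ValueError("filtering requires the knowledge vector h")
        rep, fcache = _filter_input(X, h, stack)
    else:
        rep = X
    logits, mcache = model_forward(theta, spec, rep, adjacency=adjacency)
    probs = sigmoid(logits)
    y2 = _align_labels(y, logits.shape)
    if loss_mask is not None:
        lvalue = loss(probs[loss_mask], y2[loss_mask], spec.task)
        dlogits = np.zeros_like(probs)
        dlogits[loss_mask] = loss_grad_logits(probs[loss_mask], y2[loss_mask])
    else:
        lvalue = loss(probs, y2, spec.task)
        dlogits = loss_grad_logits(probs, y2)
    d_theta, drep = model_backward(theta, spec, mcache, dlogits)
    if not use_filter:
        return lvalue, d_theta, None, None
    if drep.ndim == 3:
        B, T, K = drep.shape
        d_phi, d_h, _ = batch_filter_backward(drep.reshape(B * T, K), stack, fcache)
    else:
        d_phi, d_h, _ = batch_filter_backward(drep, stack, fcache)
    return lvalue, d_theta, d_h, d_phi


def input_gradients(theta: ParamDict, spec: ModelSpec, X: np.ndarray,
                    h: np.ndarray | None = None, stack: FilterStack | None = None,
                    adjacency: sp.csr_matrix | None = None,
                    label: int = 0) -> np.ndarray:
    """d(output probability for one label)/d(input features), per sample.

    For feedforward and recurrent models rows are independent, so the
    returned array holds each sample's own gradient.  For graph models the
    convolution couples nodes and the gradient of the summed output is
    returned per node instead.
    """
    X = np.asarray(X, dtype=np.float64)
    use_filter = stack is not None
    if use_filter:
        rep, fcache = _filter_input(X, h, stack)
    else:
        rep = X
    logits, mcache = model_forward(theta, spec, rep, adjacency=adjacency)
    probs = sigmoid(logits)
    dlogits = np.zeros_like(probs)
    dlogits[:, label] = probs[:, label] * (1.0 - probs[:, label])  # dp/dlogit
    _, drep = model_backward(theta, spec, mcache, dlogits)
    if not use_filter:
        return drep
    if drep.ndim == 3:
        B, T, K = drep.shape
        _, _, dX = batch_filter_backward(drep.reshape(B * T, K), stack, fcache)
        return dX.reshape(X.shape)
    _, _, dX = batch_filter_backward(drep, stack, fcache)
    return dX
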