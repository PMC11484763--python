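"""Client–server federated protocol with knowledge-vector filtering.

Each round the server broadcasts the global model parameters θ and the
knowledge vector h.  Every participating client copies them, trains
(θ_c, h_c) together with its private filter parameters φ on its local data
(Adam, β, J local epochs, mini-batches), keeps φ, and reports the
pseudo-gradients ∇θ = θ − θ_c and ∇h = h − h_c.  The server updates

    θ ← θ − η · mean_c ∇θ^c,      h ← h − η · mean_c ∇h^c.

Baselines: plain FedAvg (no h, no filter; requires identical views),
standalone local training (with or without a locally-trained filter), and
post-hoc personalisation of the global model at each client.

Determinism: every random stream is derived from (seed, round, client id),
never from list position or call order, and the server sorts incoming
deltas by client id before averaging — client execution order cannot
change any result.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .compose import composed_loss_grads, forward_probs
from .filtering import FilterStack, init_filter_stack
from .models import ModelSpec, build_model, normalized_adjacency
from .optim import Adam
from .params import ParamDict, mean_paramdicts
from .synthetic import ClientDataset

__all__ = [
    "ProtocolError",
    "DivergenceError",
    "GlobalState",
    "GradientDelta",
    "ClientState",
    "LocalModel",
    "init_global_state",
    "client_update",
    "aggregate",
    "run_federated",
    "run_fedavg",
    "standalone_train",
    "personalize",
    "personalize_plain",
]


class ProtocolError(RuntimeError):
    """Violation of the federation contract (empty data, missing deltas, ...)."""


class DivergenceError(RuntimeError):
    """Non-finite loss during a client's local training."""


@dataclass
class GlobalState:
    theta: ParamDict
    h: np.ndarray
    round_index: int = 0

    def copy(self) -> "GlobalState":
        return GlobalState(self.theta.copy(), self.h.copy(), self.round_index)


@dataclass
class GradientDelta:
    """Client message: pseudo-gradients θ−θ_c and h−h_c."""

    d_theta: ParamDict
    d_h: np.ndarray
    client_id: str
    n_samples: int = 0
    train_loss: float = float("nan")


@dataclass
class ClientState:
    """A client: its dataset, private filter and local hyperparameters."""

    client_id: str
    data: ClientDataset
    beta: float = 1e-3          # local Adam learning rate
    local_epochs: int = 1       # J
    batch_size: int = 64
    filter_depth: int = 2       # recursion depth R
    filter_stack: FilterStack | None = None
    _adjacency: object = field(default=None, repr=False)

    def train_indices(self) -> np.ndarray:
        if self.data.splits is None:
            return np.arange(self.data.n_samples)
        return self.data.split_indices("train")

    def adjacency(self):
        """Normalised propagation matrix (graph clients only), cached."""
        if self.data.edges is None:
            return None
        if self._adjacency is None:
            self._adjacency = normalized_adjacency(self.data.n_samples, self.data.edges)
        return self._adjacency


@dataclass
class LocalModel:
    """A locally-held model: parameters plus, if filtered, (h, φ)."""

    theta: ParamDict
    h: np.ndarray | None = None
    stack: FilterStack | None = None

    def predict(self, spec: ModelSpec, X: np.ndarray, adjacency=None) -> np.ndarray:
        return forward_probs(self.theta, spec, X, h=self.h, stack=self.stack,
                             adjacency=adjacency)


# ---------------------------------------------------------------------------
# seeding — stable per (seed, round, client id), independent of call order
# ---------------------------------------------------------------------------

def _client_key(client_id: str) -> int:
    digest = hashlib.sha256(client_id.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _rng(seed: int, round_index: int, client_id: str = "", salt: int = 0) -> np.random.Generator:
    keys = [int(seed) % (2 ** 31), round_index, salt]
    if client_id:
        keys.append(_client_key(client_id))
    return np.random.default_rng(np.random.SeedSequence(keys))


_MODEL_SALT = 101
_H_SALT = 102
_PARTICIPATION_SALT = 103
_FILTER_SALT = 104
_PERSONALIZE_SALT = 105


def init_global_state(spec: ModelSpec, seed: int) -> GlobalState:
    """Server initialisation: model parameters and the knowledge vector.

    h entries are uniform in [-1/sqrt(K), 1/sqrt(K)], the same fan-in
    convention used for layer weights.
    """
    K = spec.input_dim
    theta = build_model(spec, seed=int(_rng(seed, 0, salt=_MODEL_SALT).integers(2 ** 31)))
    h = _rng(seed, 0, salt=_H_SALT).uniform(-1.0 / np.sqrt(K), 1.0 / np.sqrt(K), size=K)
    return GlobalState(theta=theta, h=h, round_index=0)


def _ensure_filter(client: ClientState, K: int, seed: int) -> FilterStack:
    if client.filter_stack is None:
        D = client.data.n_features
        rng = _rng(seed, 0, client.client_id, salt=_FILTER_SALT)
        client.filter_stack = init_filter_stack(D, K, client.filter_depth, rng)
    stack = client.filter_stack
    if stack.knowledge_dim != K:
        raise ProtocolError(
            f"client {client.client_id}: filter K={stack.knowledge_dim} does not match "
            f"global knowledge dimension {K}"
        )
    if stack.input_dim != client.data.n_features:
        raise ProtocolError(
            f"client {client.client_id}: filter D={stack.input_dim} does not match "
            f"its data view ({client.data.n_features} features)"
        )
    return stack


# ---------------------------------------------------------------------------
# the local training engine shared by clients, baselines and personalisation
# ---------------------------------------------------------------------------

@dataclass
class _LocalResult:
    acc_theta: ParamDict
    theta: ParamDict
    acc_h: np.ndarray | None
    h: np.ndarray | None
    stack: FilterStack | None
    losses: list[float]


def _local_train(theta0: ParamDict, spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                 train_idx: np.ndarray, epochs: int, beta: float, batch_size: int,
                 rng: np.random.Generator, client_id: str,
                 h0: np.ndarray | None = None, stack: FilterStack | None = None,
                 adjacency=None, opt: Adam | None = None) -> _LocalResult:
    use_filter = stack is not None
    acc_theta = theta0.zeros_like()
    theta_cur = theta0
    if use_filter:
        phi0 = stack.to_paramdict()
        acc_phi = phi0.zeros_like()
        stack_cur = stack
        h0 = np.asarray(h0, dtype=np.float64)
        acc_h = np.zeros_like(h0)
        h_cur = h0
    else:
        acc_h = h_cur = None
        stack_cur = None
    if opt is None:
        opt = Adam(beta)
    is_graph = spec.kind == "graphconv"
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            if is_graph:
                lvalue, d_theta, d_h, d_phi = composed_loss_grads(
                    theta_cur, spec, X, y, h=h_cur, stack=stack_cur,
                    adjacency=adjacency, loss_mask=idx)
            else:
                lvalue, d_theta, d_h, d_phi = composed_loss_grads(
                    theta_cur, spec, X[idx], y[idx], h=h_cur, stack=stack_cur)
            if not np.isfinite(lvalue):
                raise DivergenceError(
                    f"non-finite training loss at client {client_id!r}")
            losses.append(lvalue)
            acc_theta = acc_theta + opt.direction(d_theta, "theta")
            theta_cur = theta0 - acc_theta
            if use_filter:
                step_h = opt.direction(ParamDict({"h": d_h}), "h")["h"]
                acc_h = acc_h + step_h
                h_cur = h0 - acc_h
                acc_phi = acc_phi + opt.direction(d_phi, "phi")
                stack_cur = FilterStack.from_paramdict(phi0 - acc_phi)
    return _LocalResult(acc_theta=acc_theta, theta=theta_cur, acc_h=acc_h,
                        h=h_cur, stack=stack_cur, losses=losses)


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def client_update(global_state: GlobalState, client: ClientState, spec: ModelSpec,
                  seed: int = 0) -> GradientDelta:
    """One client's local round: train (θ_c, h_c, φ), return pseudo-gradients.

    φ is persisted inside ``client``; ``global_state`` is never mutated.
    """
    train_idx = client.train_indices()
    if len(train_idx) == 0:
        raise ProtocolError(f"client {client.client_id} has an empty training split")
    stack = _ensure_filter(client, spec.input_dim, seed)
    rng = _rng(seed, global_state.round_index, client.client_id)
    res = _local_train(
        global_state.theta, spec, client.data.X, client.data.y, train_idx,
        epochs=client.local_epochs, beta=client.beta, batch_size=client.batch_size,
        rng=rng, client_id=client.client_id, h0=global_state.h, stack=stack,
        adjacency=client.adjacency())
    client.filter_stack = res.stack
    mean_loss = float(np.mean(res.losses)) if res.losses else float("nan")
    return GradientDelta(d_theta=res.acc_theta, d_h=res.acc_h,
                         client_id=client.client_id, n_samples=len(train_idx),
                         train_loss=mean_loss)


def aggregate(global_state: GlobalState, deltas: Sequence[GradientDelta],
              eta: float, weighted: bool = False) -> GlobalState:
    """Server update: subtract η times the (unweighted) mean pseudo-gradient.

    ``weighted=True`` switches to a sample-count-weighted mean.  Deltas are
    sorted by client id first, so the result is independent of arrival order.
    """
    if len(deltas) == 0:
        raise ProtocolError("aggregate called with no client deltas")
    ds = sorted(deltas, key=lambda d: d.client_id)
    if weighted:
        w = np.array([d.n_samples for d in ds], dtype=np.float64)
        if w.sum() <= 0:
            raise ProtocolError("weighted aggregation needs positive sample counts")
        w = w / w.sum()
        mean_theta = ds[0].d_theta.scale(w[0])
        mean_h = ds[0].d_h * w[0]
        for wi, d in zip(w[1:], ds[1:]):
            mean_theta = mean_theta + d.d_theta.scale(wi)
            mean_h = mean_h + d.d_h * wi
    else:
        mean_theta = mean_paramdicts([d.d_theta for d in ds])
        mean_h = np.mean([d.d_h for d in ds], axis=0)
    theta_new = global_state.theta - mean_theta.scale(eta)
    h_new = global_state.h - eta * mean_h
    return GlobalState(theta=theta_new, h=h_new,
                       round_index=global_state.round_index + 1)


def run_federated(clients: Sequence[ClientState], spec: ModelSpec, rounds: int,
                  eta: float = 1e-3, seed: int = 0, participation: float = 1.0,
                  weighted: bool = False,
                  initial_state: GlobalState | None = None,
                  track_validation: int = 0,
                  keep_best_val_state: bool = False
                  ) -> tuple[GlobalState, list[dict]]:
    """The full protocol: N rounds of broadcast → local train → aggregate.

    Returns the final global state and a per-round history (round index,
    per-client mean training loss, and — every ``track_validation`` rounds,
    if nonzero — the macro validation AUROC).  With ``keep_best_val_state``
    the state returned is the tracked round with the best validation AUROC
    instead of the last one (round-level early stopping).  Fully
    deterministic given ``seed``; resuming from a checkpointed state
    reproduces the uninterrupted run.
    """
    if len(clients) == 0:
        raise ProtocolError("no clients")
    state = initial_state.copy() if initial_state is not None else init_global_state(spec, seed)
    history: list[dict] = []
    best: tuple[float, GlobalState] | None = None
    if keep_best_val_state and not track_validation:
        track_validation = 1
    for _ in range(rounds):
        participants = _select_clients(clients, participation, seed, state.round_index)
        deltas = []
        for c in participants:
            try:
                deltas.append(client_update(state, c, spec, seed=seed))
            except (ProtocolError, DivergenceError):
                raise
            except Exception as exc:  # attribute any client failure
                raise ProtocolError(f"client {c.client_id} failed: {exc}") from exc
        record = {
            "round": state.round_index,
            "client_losses": {d.client_id: d.train_loss for d in deltas},
            "mean_train_loss": float(np.mean([d.train_loss for d in deltas])),
        }
        state = aggregate(state, deltas, eta, weighted=weighted)
        if track_validation and state.round_index % track_validation == 0:
            score = _macro_val_auroc(state, clients, spec)
            record["val_macro_auroc"] = score
            if score is not None and (best is None or score > best[0]):
                best = (score, state.copy())
        history.append(record)
    if keep_best_val_state and best is not None:
        return best[1], history
    return state, history


def _macro_val_auroc(state: GlobalState, clients: Sequence[ClientState],
                     spec: ModelSpec) -> float | None:
    """Unweighted mean validation AUROC over clients under the global model
    (each client applies its own current filter)."""
    scores = []
    for c in clients:
        if c.data.splits is None or c.filter_stack is None:
            continue
        model = LocalModel(theta=state.theta, h=state.h, stack=c.filter_stack)
        s = _val_auroc(model, spec, c)
        if s is not None:
            scores.append(s)
    return float(np.mean(scores)) if scores else None


def _select_clients(clients: Sequence[ClientState], participation: float,
                    seed: int, round_index: int) -> list[ClientState]:
    ordered = sorted(clients, key=lambda c: c.client_id)
    if participation >= 1.0:
        return ordered
    k = max(1, int(round(participation * len(ordered))))
    rng = _rng(seed, round_index, salt=_PARTICIPATION_SALT)
    chosen = rng.choice(len(ordered), size=k, replace=False)
    return [ordered[i] for i in sorted(chosen)]


def run_fedavg(clients: Sequence[ClientState], spec: ModelSpec, rounds: int,
               eta: float = 1e-3, seed: int = 0, participation: float = 1.0,
               weighted: bool = False, track_validation: int = 0,
               keep_best_val_state: bool = False) -> tuple[ParamDict, list[dict]]:
    """Plain federated averaging: no knowledge vector, no filtering.

    All client views must have identical dimension and feature ordering;
    under feature disparity run harmonize_common_subset first.
    """
    if len(clients) == 0:
        raise ProtocolError("no clients")
    dims = {c.client_id: c.data.n_features for c in clients}
    if len(set(dims.values())) != 1:
        raise ProtocolError(
            f"FedAvg requires identical client views but dimensions differ: {dims}; "
            "harmonise the views first (harmonize_common_subset)")
    D = next(iter(dims.values()))
    if spec.input_dim != D:
        raise ProtocolError(
            f"model input dimension {spec.input_dim} must equal the shared view "
            f"dimension {D} for FedAvg")
    theta = build_model(spec, seed=int(_rng(seed, 0, salt=_MODEL_SALT).integers(2 ** 31)))
    round_index = 0
    history: list[dict] = []
    best: tuple[float, ParamDict] | None = None
    if keep_best_val_state and not track_validation:
        track_validation = 1
    for _ in range(rounds):
        participants = _select_clients(clients, participation, seed, round_index)
        deltas = []
        for c in participants:
            train_idx = c.train_indices()
            if len(train_idx) == 0:
                raise ProtocolError(f"client {c.client_id} has an empty training split")
            rng = _rng(seed, round_index, c.client_id)
            res = _local_train(theta, spec, c.data.X, c.data.y, train_idx,
                               epochs=c.local_epochs, beta=c.beta,
                               batch_size=c.batch_size, rng=rng,
                               client_id=c.client_id, adjacency=c.adjacency())
            mean_loss = float(np.mean(res.losses)) if res.losses else float("nan")
            deltas.append(GradientDelta(d_theta=res.acc_theta,
                                        d_h=np.zeros(0), client_id=c.client_id,
                                        n_samples=len(train_idx), train_loss=mean_loss))
        ds = sorted(deltas, key=lambda d: d.client_id)
        if weighted:
            w = np.array([d.n_samples for d in ds], dtype=np.float64)
            w = w / w.sum()
            mean_theta = ds[0].d_theta.scale(w[0])
            for wi, d in zip(w[1:], ds[1:]):
                mean_theta = mean_theta + d.d_theta.scale(wi)
        else:
            mean_theta = mean_paramdicts([d.d_theta for d in ds])
        record = {
            "round": round_index,
            "client_losses": {d.client_id: d.train_loss for d in deltas},
            "mean_train_loss": float(np.mean([d.train_loss for d in deltas])),
        }
        theta = theta - mean_theta.scale(eta)
        round_index += 1
        if track_validation and round_index % track_validation == 0:
            vals = [s for c in clients if c.data.splits is not None
                    and (s := _val_auroc(LocalModel(theta=theta), spec, c)) is not None]
            score = float(np.mean(vals)) if vals else None
            record["val_macro_auroc"] = score
            if score is not None and (best is None or score > best[0]):
                best = (score, theta.copy())
        history.append(record)
    if keep_best_val_state and best is not None:
        return best[1], history
    return theta, history


def standalone_train(client: ClientState, spec: ModelSpec, epochs: int,
                     with_filtering: bool = False, seed: int = 0,
                     early_stopping: bool = False) -> LocalModel:
    """Train a model at one client only.

    ``with_filtering=False``: a plain model on the client's native view
    (spec.input_dim must equal D).  ``with_filtering=True``: the client
    trains its own knowledge vector and filter jointly with the model
    (spec.input_dim = K), i.e. the single-site variant of the framework.
    ``early_stopping`` returns the epoch snapshot with the best validation
    AUROC; the training trajectory itself is unchanged.
    """
    train_idx = client.train_indices()
    if len(train_idx) == 0:
        raise ProtocolError(f"client {client.client_id} has an empty training split")
    rng = _rng(seed, 0, client.client_id)
    has_val = (early_stopping and client.data.splits is not None
               and len(client.data.split_indices("val")) > 0)
    if with_filtering:
        init = init_global_state(spec, seed)
        stack = _ensure_filter(client, spec.input_dim, seed)
        theta_cur, h_cur, stack_cur = init.theta, init.h, stack
    else:
        if spec.input_dim != client.data.n_features:
            raise ProtocolError(
                f"standalone model input dim {spec.input_dim} must equal the client's "
                f"view dimension {client.data.n_features}")
        theta_cur = build_model(
            spec, seed=int(_rng(seed, 0, salt=_MODEL_SALT).integers(2 ** 31)))
        h_cur = stack_cur = None
    if not has_val:
        # one uninterrupted call: the trajectory then re-evaluates exactly the
        # same floating-point expressions as a federated client's local round,
        # making the single-client protocol reduction bit-exact
        res = _local_train(theta_cur, spec, client.data.X, client.data.y, train_idx,
                           epochs=epochs, beta=client.beta,
                           batch_size=client.batch_size, rng=rng,
                           client_id=client.client_id, h0=h_cur, stack=stack_cur,
                           adjacency=client.adjacency())
        if with_filtering:
            client.filter_stack = res.stack
        return LocalModel(theta=res.theta, h=res.h, stack=res.stack)
    opt = Adam(client.beta)
    best: tuple[float, LocalModel] | None = None
    cur = LocalModel(theta=theta_cur, h=h_cur, stack=stack_cur)
    for _ in range(epochs):
        res = _local_train(theta_cur, spec, client.data.X, client.data.y, train_idx,
                           epochs=1, beta=client.beta, batch_size=client.batch_size,
                           rng=rng, client_id=client.client_id, h0=h_cur,
                           stack=stack_cur, adjacency=client.adjacency(), opt=opt)
        theta_cur, h_cur, stack_cur = res.theta, res.h, res.stack
        cur = LocalModel(theta=theta_cur, h=h_cur, stack=stack_cur)
        score = _val_auroc(cur, spec, client)
        if score is not None and (best is None or score > best[0]):
            best = (score, cur)
    if with_filtering:
        client.filter_stack = stack_cur
    if best is not None:
        return best[1]
    return cur


def personalize(global_state: GlobalState, client: ClientState, spec: ModelSpec,
                epochs: int = 5, beta: float = 1e-3, seed: int = 0,
                early_stopping: bool = True) -> LocalModel:
    """Local fine-tuning of the final global model at one client.

    Continues client-style training of (θ_c, h_c, φ) on the client's train
    split; with ``early_stopping`` the epoch with the best validation AUROC
    is returned.  Neither the global state nor any other client is touched;
    the client's stored φ is left as-is (the fine-tuned copy is returned).
    """
    stack = _ensure_filter(client, spec.input_dim, seed)
    if epochs == 0:
        return LocalModel(theta=global_state.theta.copy(), h=global_state.h.copy(),
                          stack=stack)
    train_idx = client.train_indices()
    if len(train_idx) == 0:
        raise ProtocolError(f"client {client.client_id} has an empty training split")
    has_val = client.data.splits is not None and len(client.data.split_indices("val")) > 0
    opt = Adam(beta)
    rng = _rng(seed, 0, client.client_id, salt=_PERSONALIZE_SALT)
    theta_cur, h_cur, stack_cur = global_state.theta.copy(), global_state.h.copy(), stack
    best: tuple[float, LocalModel] | None = None
    cur = LocalModel(theta=theta_cur, h=h_cur, stack=stack_cur)
    for _ in range(epochs):
        res = _local_train(theta_cur, spec, client.data.X, client.data.y,
                           train_idx, epochs=1, beta=beta,
                           batch_size=client.batch_size, rng=rng,
                           client_id=client.client_id, h0=h_cur,
                           stack=stack_cur, adjacency=client.adjacency(), opt=opt)
        theta_cur, h_cur, stack_cur = res.theta, res.h, res.stack
        cur = LocalModel(theta=theta_cur, h=h_cur, stack=stack_cur)
        if early_stopping and has_val:
            score = _val_auroc(cur, spec, client)
            if score is not None and (best is None or score > best[0]):
                best = (score, cur)
    if early_stopping and best is not None:
        return best[1]
    return cur


def personalize_plain(theta: ParamDict, client: ClientState, spec: ModelSpec,
                      epochs: int = 5, beta: float = 1e-3, seed: int = 0,
                      early_stopping: bool = True) -> LocalModel:
    """Local fine-tuning of a plain (unfiltered) global model at one client."""
    if epochs == 0:
        return LocalModel(theta=theta.copy())
    train_idx = client.train_indices()
    if len(train_idx) == 0:
        raise ProtocolError(f"client {client.client_id} has an empty training split")
    has_val = client.data.splits is not None and len(client.data.split_indices("val")) > 0
    opt = Adam(beta)
    rng = _rng(seed, 0, client.client_id, salt=_PERSONALIZE_SALT)
    theta_cur = theta.copy()
    best: tuple[float, LocalModel] | None = None
    cur = LocalModel(theta=theta_cur)
    for _ in range(epochs):
        res = _local_train(theta_cur, spec, client.data.X, client.data.y, train_idx,
                           epochs=1, beta=beta, batch_size=client.batch_size,
                           rng=rng, client_id=client.client_id,
                           adjacency=client.adjacency(), opt=opt)
        theta_cur = res.theta
        cur = LocalModel(theta=theta_cur)
        if early_stopping and has_val:
            score = _val_auroc(cur, spec, client)
            if score is not None and (best is None or score > best[0]):
                best = (score, cur)
    if early_stopping and best is not None:
        return best[1]
    return cur


def _val_auroc(model: LocalModel, spec: ModelSpec, client: ClientState) -> float | None:
    idx = client.data.split_indices("val")
    y = client.data.y[idx]
    yflat = y if y.ndim == 1 else y[:, 0]
    if len(np.unique(yflat)) < 2:
        return None
    if spec.kind == "graphconv":
        probs = model.predict(spec, client.data.X, adjacency=client.adjacency())[idx]
    else:
        probs = model.predict(spec, client.data.X[idx])
    p = probs[:, 0] if probs.ndim == 2 else probs
    if y.ndim == 1:
        return float(roc_auc_score(y, p))
    scores = []
    for j in range(y.shape[1]):
        if len(np.unique(y[:, j])) == 2:
            scores.append(roc_auc_score(y[:, j], probs[:, j]))
    return float(np.mean(scores)) if scores else None
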