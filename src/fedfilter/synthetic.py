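"""Synthetic multi-client clinical data and data-view heterogeneity.

Real multi-site EHR cohorts (the setting this package simulates) share a
latent disease signal but differ in case mix, measurement conventions and
which features each site records.  The generator emulates exactly that:

* a latent factor model shared by all clients drives both the informative
  features and a logistic label model (the common signal);
* each client gets its own covariate mean shift (site case-mix drift), its
  own class prevalence, and optionally a much smaller sample count (a
  data-scarce site);
* three *view* operators then heterogenise the clients' ML-ready tables the
  way hospitals do — dropping features (feature disparity), reordering
  columns (shuffled views) and changing measurement units (scaled views).

Every operator records its transform so it can be audited or inverted; none
of them ever touches labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SyntheticSpec",
    "ViewTransform",
    "ClientDataset",
    "generate_base_population",
    "apply_feature_disparity",
    "apply_shuffle",
    "apply_scaling",
    "harmonize_common_subset",
    "build_patient_graph",
    "split_dataset",
    "save_client_dataset",
    "load_client_dataset",
]

SPLIT_FRACTIONS = (0.65, 0.15, 0.20)
SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic federation.

    Defaults describe a four-site binary risk-prediction task: three sites
    with ~2000 encounters and one data-scarce site with 200, 28 recorded
    features of which 20 carry the latent signal, and a 15% event
    prevalence at every site (imbalanced, as clinical outcomes are).
    """

    n_clients: int = 4
    samples_per_client: int | tuple[int, ...] = (2000, 2000, 2000, 200)
    n_features: int = 28
    n_informative: int = 20
    latent_dim: int = 16
    class_prevalence: float | tuple[float, ...] = 0.15
    noise_sd: float = 0.5
    shift_sd: float = 0.5
    signal_strength: float = 3.0
    interaction_strength: float = 0.0
    task: str = "binary"          # "binary" | "multilabel"
    n_labels: int = 1             # labels per sample when multilabel
    modality: str = "tabular"     # "tabular" | "timeseries" | "graph"
    n_timesteps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ValueError("need at least one client")
        if not (0 < self.n_informative <= self.n_features) and self.n_informative != 0:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        for p in self.prevalences():
            if not (0.0 < p < 1.0):
                raise ValueError("class prevalence must lie strictly in (0, 1)")
        if self.task not in ("binary", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.modality not in ("tabular", "timeseries", "graph"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.task == "multilabel" and self.n_labels < 2:
            raise ValueError("multilabel task needs n_labels >= 2")
        if len(self.sample_counts()) != self.n_clients:
            raise ValueError("samples_per_client length must equal n_clients")

    def sample_counts(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_client, int):
            return (self.samples_per_client,) * self.n_clients
        return tuple(self.samples_per_client)

    def prevalences(self) -> tuple[float, ...]:
        if isinstance(self.class_prevalence, float):
            return (self.class_prevalence,) * self.n_clients
        return tuple(self.class_prevalence)


@dataclass
class ViewTransform:
    """Audit record of how a client's view was derived from the base table.

    View column ``j`` holds base feature ``kept_indices[permutation[j]]``
    multiplied by ``scales[j]``.
    """

    kept_indices: np.ndarray      # sorted base-feature indices that survive
    permutation: np.ndarray       # bijection over range(len(kept_indices))
    scales: np.ndarray            # positive per-view-column factors

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=np.int64)
        self.permutation = np.asarray(self.permutation, dtype=np.int64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        m = len(self.kept_indices)
        if sorted(self.permutation.tolist()) != list(range(m)):
            raise ValueError("permutation must be a bijection over the kept features")
        if len(self.scales) != m or np.any(self.scales <= 0):
            raise ValueError("scales must be positive, one per kept feature")
        if len(np.unique(self.kept_indices)) != m:
            raise ValueError("kept_indices must not repeat")

    @staticmethod
    def identity(n_features: int) -> "ViewTransform":
        return ViewTransform(
            kept_indices=np.arange(n_features),
            permutation=np.arange(n_features),
            scales=np.ones(n_features),
        )

    def base_index_of_column(self, j: int) -> int:
        return int(self.kept_indices[self.permutation[j]])

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Transform a (..., D_base) array into the client's view."""
        Xv = X[..., self.kept_indices][..., self.permutation] * self.scales
        return Xv

    def compose(self, other: "ViewTransform") -> "ViewTransform":
        """Transform resulting from applying ``self`` then ``other``."""
        kept_seq = self.kept_indices[self.permutation]       # base idx per view col
        scale_seq = self.scales
        new_seq = kept_seq[other.kept_indices][other.permutation]
        new_scale = scale_seq[other.kept_indices][other.permutation] * other.scales
        order = np.argsort(new_seq)
        kept_sorted = new_seq[order]
        # permutation p with kept_sorted[p[j]] == new_seq[j]
        perm = np.argsort(order)
        return ViewTransform(kept_indices=kept_sorted, permutation=perm, scales=new_scale)

    def to_json(self) -> str:
        return json.dumps({
            "kept_indices": self.kept_indices.tolist(),
            "permutation": self.permutation.tolist(),
            "scales": self.scales.tolist(),
        })

    @staticmethod
    def from_json(s: str) -> "ViewTransform":
        d = json.loads(s)
        return ViewTransform(
            kept_indices=np.array(d["kept_indices"]),
            permutation=np.array(d["permutation"]),
            scales=np.array(d["scales"]),
        )


@dataclass
class ClientDataset:
    """One client's ML-ready data: features, labels, names and split masks.

    ``X`` is (n, D) for tabular/graph or (n, T, D) for time series; ``y`` is
    (n,) binary or (n, L) multilabel.  ``edges`` (graph modality only) is an
    (E, 2) integer array over sample indices, closed under reversal.
    """

    client_id: str
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    splits: dict[str, np.ndarray] | None = None
    edges: np.ndarray | None = None
    transform: ViewTransform | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[-1]

    def split_indices(self, name: str) -> np.ndarray:
        if self.splits is None:
            raise ValueError(f"dataset {self.client_id} has no splits; call split_dataset first")
        return np.flatnonzero(self.splits[name])

    def subset_X(self, name: str) -> np.ndarray:
        return self.X[self.split_indices(name)]

    def subset_y(self, name: str) -> np.ndarray:
        return self.y[self.split_indices(name)]


# ---------------------------------------------------------------------------
# base population
# ---------------------------------------------------------------------------

def _calibrated_intercept(logits: np.ndarray, prevalence: float) -> float:
    """Intercept b with mean(sigmoid(logits + b)) == prevalence."""
    def f(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(logits + b))))) - prevalence
    return brentq(f, -40.0, 40.0)


def generate_base_population(spec: SyntheticSpec) -> list[ClientDataset]:
    """Draw every client's dataset in the shared base feature space.

    All clients share the latent->feature mixing and the latent->label
    weights (the common signal); each client has its own covariate mean
    shift, prevalence-calibrated intercept and sample count.
    """
    rng = np.random.default_rng(spec.seed)
    D, L, M = spec.n_features, spec.latent_dim, spec.n_informative
    n_lab = spec.n_labels if spec.task == "multilabel" else 1

    mixing = rng.normal(size=(L, M)) / np.sqrt(L) if M > 0 else np.zeros((L, 0))
    w = rng.normal(size=(L, n_lab))
    norms = np.linalg.norm(w, axis=0)
    w = w / norms * spec.signal_strength        # each label's latent weight has fixed norm
    # second-order latent interactions: clinical risk is multi-index, so the
    # label depends on more latent directions than any single projection
    Qs = []
    for _ in range(n_lab):
        Q = rng.normal(size=(L, L))
        Q = (Q + Q.T) / 2.0
        if spec.interaction_strength > 0:
            Q *= spec.interaction_strength / np.sqrt(2.0) / np.linalg.norm(Q)
        else:
            Q[:] = 0.0
        Qs.append(Q)

    names = [f"f{i:02d}" for i in range(D)]
    counts = spec.sample_counts()
    prevs = spec.prevalences()
    clients: list[ClientDataset] = []
    for c in range(spec.n_clients):
        n = counts[c]
        shift = rng.normal(scale=spec.shift_sd, size=D)
        z = rng.normal(size=(n, L))
        logits = z @ w                                       # (n, n_lab)
        for j in range(n_lab):
            logits[:, j] += np.einsum("ni,ij,nj->n", z, Qs[j], z) - np.trace(Qs[j])
        ys = np.empty((n, n_lab))
        for j in range(n_lab):
            b = _calibrated_intercept(logits[:, j], prevs[c])
            ys[:, j] = rng.binomial(1, 1.0 / (1.0 + np.exp(-(logits[:, j] + b))))
        y = ys[:, 0] if spec.task == "binary" else ys

        base = np.zeros((n, D))
        if M > 0:
            base[:, :M] = z @ mixing
        base += shift
        if spec.modality == "timeseries":
            T = spec.n_timesteps
            X = np.empty((n, T, D))
            ar = np.zeros((n, D))
            for t in range(T):
                ar = 0.5 * ar + rng.normal(scale=spec.noise_sd, size=(n, D))
                X[:, t, :] = base + ar
        else:
            X = base + rng.normal(scale=spec.noise_sd, size=(n, D))

        ds = ClientDataset(
            client_id=f"client{c}",
            X=X,
            y=y,
            feature_names=list(names),
            transform=ViewTransform.identity(D),
        )
        if spec.modality == "graph":
            ds = build_patient_graph(ds, k=min(10, max(1, n - 1)))
        clients.append(ds)
    return clients


# ---------------------------------------------------------------------------
# heterogeneity operators
# ---------------------------------------------------------------------------

def _with_view(ds: ClientDataset, step: ViewTransform) -> tuple[ClientDataset, ViewTransform]:
    Xv = step.apply(ds.X)
    names = [ds.feature_names[int(step.kept_indices[step.permutation[j]])]
             for j in range(len(step.kept_indices))]
    total = step if ds.transform is None else ds.transform.compose(step)
    new = replace(ds, X=Xv, feature_names=names, transform=total)
    return new, step


def apply_feature_disparity(ds: ClientDataset, keep_fraction: float | None = None,
                            seed: int = 0, n_keep: int | None = None
                            ) -> tuple[ClientDataset, ViewTransform]:
    """Drop a seeded random subset of features (site records fewer variables).

    Exactly one of ``keep_fraction`` / ``n_keep`` selects how many columns
    survive; kept columns stay in their original relative order.
    """
    D = ds.n_features
    if n_keep is None:
        if keep_fraction is None:
            raise ValueError("provide keep_fraction or n_keep")
        n_keep = int(round(keep_fraction * D))
    if not (1 <= n_keep <= D):
        raise ValueError(f"n_keep={n_keep} out of range for D={D}")
    rng = np.random.default_rng(seed)
    kept = np.sort(rng.choice(D, size=n_keep, replace=False))
    step = ViewTransform(kept_indices=kept, permutation=np.arange(n_keep),
                         scales=np.ones(n_keep))
    return _with_view(ds, step)


def apply_shuffle(ds: ClientDataset, seed: int = 0) -> tuple[ClientDataset, ViewTransform]:
    """Seeded permutation of feature columns (and their names); labels untouched."""
    D = ds.n_features
    rng = np.random.default_rng(seed)
    perm = rng.permutation(D)
    step = ViewTransform(kept_indices=np.arange(D), permutation=perm, scales=np.ones(D))
    return _with_view(ds, step)


def apply_scaling(ds: ClientDataset, seed: int = 0,
                  scale_range: tuple[float, float] = (0.01, 100.0)
                  ) -> tuple[ClientDataset, ViewTransform]:
    """Per-feature unit change: factors drawn log-uniformly from ``scale_range``."""
    lo, hi = scale_range
    if lo <= 0 or hi < lo:
        raise ValueError("scale_range must satisfy 0 < lo <= hi")
    D = ds.n_features
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=D))
    step = ViewTransform(kept_indices=np.arange(D), permutation=np.arange(D),
                         scales=factors)
    return _with_view(ds, step)


def harmonize_common_subset(views: Sequence[tuple[ClientDataset, ViewTransform]]
                            ) -> list[ClientDataset]:
    """Reduce every client to the features all clients share, canonically ordered.

    This is the lossy manual preprocessing plain federated averaging needs
    under feature disparity: features outside the intersection are dropped
    at every client.  Column order follows the base feature index.
    """
    datasets = [v[0] for v in views]
    common: set[str] | None = None
    for ds in datasets:
        s = set(ds.feature_names)
        common = s if common is None else (common & s)
    if not common:
        raise ValueError("harmonisation failed: clients share no common features")
    order = sorted(common)  # names encode base index, so lexicographic == base order
    out = []
    for ds in datasets:
        cols = [ds.feature_names.index(name) for name in order]
        Xh = ds.X[..., cols]
        tr = None
        if ds.transform is not None:
            # selecting named view columns == kept subset in the listed order
            seq = np.array(cols)
            sel = ViewTransform(kept_indices=np.sort(seq),
                                permutation=np.argsort(np.argsort(seq)),
                                scales=np.ones(len(seq)))
            tr = ds.transform.compose(sel)
        out.append(replace(ds, X=Xh, feature_names=list(order), transform=tr))
    return out


def build_patient_graph(ds: ClientDataset, k: int = 10) -> ClientDataset:
    """Connect each sample (patient) to its k nearest neighbours.

    Cosine similarity on z-scored features, union-symmetrised (an edge
    survives if either endpoint selected the other), self-loops added.  The
    edge list is stored closed under reversal.
    """
    n = ds.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples n={n}")
    if ds.X.ndim != 2:
        raise ValueError("patient graphs are built from tabular (n, D) data")
    mu = ds.X.mean(axis=0)
    sd = ds.X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (ds.X - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(Z)
    _, idx = nn.kneighbors(Z)
    pairs = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            pairs.add((i, j))
            pairs.add((j, i))
    for i in range(n):
        pairs.add((i, i))
    edges = np.array(sorted(pairs), dtype=np.int64)
    return replace(ds, edges=edges)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    rem = [q - b for q, b in zip(quotas, base)]
    short = n - sum(base)
    # distribute leftover units to the largest remainders (ties: earlier split)
    order = sorted(range(len(fractions)), key=lambda i: (-rem[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(ds: ClientDataset, seed: int = 0,
                  fractions: Sequence[float] = SPLIT_FRACTIONS) -> ClientDataset:
    """Label-stratified train/val/test split with largest-remainder rounding.

    Global split sizes are exact by largest remainder (100 samples at the
    default 65/15/20 give exactly 65/15/20); strata are apportioned the same
    way and then repaired minimally so the global sizes hold.
    """
    n = ds.n_samples
    totals = _largest_remainder(n, fractions)
    y = ds.y if ds.y.ndim == 1 else ds.y[:, 0]   # stratify on the first label
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    # per-class largest-remainder allocation
    alloc = {}
    for cls in classes:
        alloc[cls] = _largest_remainder(int(np.sum(y == cls)), fractions)
    # repair: adjust class cells until per-split column sums match the totals
    for s in range(len(fractions)):
        col = sum(alloc[c][s] for c in classes)
        while col != totals[s]:
            step = 1 if col < totals[s] else -1
            # move a unit between this split and the most mismatched other split
            donors = [(t, c) for t in range(len(fractions)) if t != s
                      for c in classes
                      if (alloc[c][t] - (0 if step > 0 else -1)) > 0]
            # choose the (other split, class) whose column is most over/under target
            def surplus(tc):
                t, _ = tc
                return (sum(alloc[cc][t] for cc in classes) - totals[t]) * step
            t, c = max(donors, key=surplus)
            alloc[c][t] -= step
            alloc[c][s] += step
            col = sum(alloc[cc][s] for cc in classes)
    masks = {name: np.zeros(n, dtype=bool) for name in SPLIT_NAMES}
    for cls in classes:
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        start = 0
        for s, name in enumerate(SPLIT_NAMES):
            take = alloc[cls][s]
            masks[name][members[start:start + take]] = True
            start += take
    return replace(ds, splits=masks)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def save_client_dataset(ds: ClientDataset, out_dir: str | Path) -> None:
    """Write a client dataset as delimited text plus JSON metadata.

    Tabular/graph: ``features.csv`` (one row per sample).  Time series:
    ``series.csv`` in long format (sample_id, time, features).  Graph edges:
    ``edges.csv`` (two columns).  Labels and split masks ride along in the
    feature table; the view transform goes to ``transform.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = ds.n_samples
    lab = ds.y if ds.y.ndim == 2 else ds.y[:, None]
    lab_cols = {f"label{j}" if lab.shape[1] > 1 else "label": lab[:, j]
                for j in range(lab.shape[1])}
    split_col = np.full(n, "", dtype=object)
    if ds.splits is not None:
        for name in SPLIT_NAMES:
            split_col[ds.splits[name]] = name
    if ds.X.ndim == 3:
        T = ds.X.shape[1]
        rows = []
        for i in range(n):
            for t in range(T):
                rows.append([i, t] + list(ds.X[i, t]))
        df = pd.DataFrame(rows, columns=["sample_id", "time"] + ds.feature_names)
        df.to_csv(out / "series.csv", index=False)
        meta_df = pd.DataFrame({"sample_id": np.arange(n), **lab_cols, "split": split_col})
        meta_df.to_csv(out / "labels.csv", index=False)
    else:
        df = pd.DataFrame(ds.X, columns=ds.feature_names)
        for cname, col in lab_cols.items():
            df[cname] = col
        df["split"] = split_col
        df.to_csv(out / "features.csv", index=False)
    if ds.edges is not None:
        pd.DataFrame(ds.edges, columns=["src", "dst"]).to_csv(out / "edges.csv", index=False)
    meta = {"client_id": ds.client_id, "feature_names": ds.feature_names}
    if ds.transform is not None:
        meta["transform"] = json.loads(ds.transform.to_json())
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_client_dataset(in_dir: str | Path) -> ClientDataset:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    names = meta["feature_names"]
    transform = None
    if "transform" in meta:
        transform = ViewTransform.from_json(json.dumps(meta["transform"]))
    edges = None
    if (src / "edges.csv").exists():
        edges = pd.read_csv(src / "edges.csv").to_numpy(dtype=np.int64)
    if (src / "series.csv").exists():
        df = pd.read_csv(src / "series.csv")
        labels = pd.read_csv(src / "labels.csv")
        n = labels.shape[0]
        T = df["time"].nunique()
        X = np.empty((n, T, len(names)))
        for (i, t), grp in df.groupby(["sample_id", "time"]):
            X[int(i), int(t)] = grp[names].to_numpy()[0]
        y, split_col = _labels_from_frame(labels)
    else:
        df = pd.read_csv(src / "features.csv")
        X = df[names].to_numpy(dtype=np.float64)
        y, split_col = _labels_from_frame(df)
    splits = None
    if split_col is not None and (split_col != "").any():
        splits = {name: (split_col == name).to_numpy() for name in SPLIT_NAMES}
    return ClientDataset(client_id=meta["client_id"], X=X, y=y,
                         feature_names=list(names), splits=splits,
                         edges=edges, transform=transform)


def _labels_from_frame(df: pd.DataFrame):
    lab_cols = [c for c in df.columns if c == "label" or c.startswith("label")]
    lab_cols = [c for c in lab_cols if c != "labels"]
    y = df[lab_cols].to_numpy(dtype=np.float64)
    if y.shape[1] == 1:
        y = y[:, 0]
    split_col = df["split"].fillna("") if "split" in df.columns else None
    return y, split_col
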