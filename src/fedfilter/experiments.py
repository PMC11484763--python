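"""Scenario experiments: the evaluation harness of the simulation study.

An *experiment* draws a fresh multi-client population per run, heterogenises
each client's view according to the scenario, trains the requested methods,
personalises the federated ones at every client, and scores each client's
held-out test split.  The four scenarios mirror how multi-site EHR views
actually diverge:

* ``standard``  — identical views everywhere;
* ``disparity`` — some clients record fewer features (the classic
  21-vs-28-feature pattern across sites);
* ``shuffled``  — same features, site-specific column order;
* ``scaled``    — same features, site-specific measurement units.

Methods: ``standalone`` (local model per client), ``standalone_filtering``
(the single-site variant of the framework), ``fedavg`` (plain federated
averaging; under disparity the views are first harmonised to the common
feature subset, the lossy manual alignment the framework avoids), and
``proposed`` (knowledge-filtering federation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import (ImportanceReport, METRIC_NAMES, MetricsReport,
                         compute_metrics, feature_importance)
from .federation import (ClientState, personalize, personalize_plain,
                         run_fedavg, run_federated, standalone_train)
from .models import ModelSpec
from .synthetic import (ClientDataset, SyntheticSpec, ViewTransform,
                        apply_feature_disparity, apply_scaling, apply_shuffle,
                        generate_base_population, harmonize_common_subset,
                        split_dataset)

logger = logging.getLogger(__name__)

SCENARIOS = ("standard", "disparity", "shuffled", "scaled")
METHODS = ("standalone", "standalone_filtering", "fedavg", "proposed")

__all__ = [
    "SCENARIOS",
    "METHODS",
    "ExperimentConfig",
    "prepare_clients",
    "run_scenario_experiment",
    "knowledge_size_sweep",
    "run_importance_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Hyperparameters of one experiment (defaults follow the reference setup).

    ``rounds``/``eta`` govern the server, ``beta``/``local_epochs``/
    ``batch_size`` the clients, ``knowledge_dim`` the shared latent space,
    ``filter_depth`` the recursive filtering depth.  Standalone baselines
    train for ``standalone_epochs`` epochs.
    """

    knowledge_dim: int = 64
    hidden_dim: int = 128
    rounds: int = 300
    eta: float = 1.0
    beta: float = 1e-3
    local_epochs: int = 1
    batch_size: int = 64
    filter_depth: int = 2
    participation: float = 1.0
    weighted: bool = False
    personalization_epochs: int = 5
    standalone_epochs: int = 300
    threshold_policy: str = "youden"
    select_by_validation: bool = True   # round/epoch snapshot with best val AUROC
    validation_every: int = 5           # rounds between validation checks
    scale_range: tuple[float, float] = (0.01, 100.0)
    disparity_keep: tuple[int, ...] | None = None


def _model_kind(modality: str) -> str:
    return {"tabular": "feedforward", "timeseries": "recurrent",
            "graph": "graphconv"}[modality]


def _disparity_keep_counts(spec: SyntheticSpec, config: ExperimentConfig) -> list[int]:
    """Default pattern: first half of the clients keep the full view, the
    rest keep 75% of it (28 -> 21 at the default width)."""
    if config.disparity_keep is not None:
        if len(config.disparity_keep) != spec.n_clients:
            raise ValueError("disparity_keep must list one count per client")
        return list(config.disparity_keep)
    D = spec.n_features
    reduced = int(round(0.75 * D))
    half = spec.n_clients // 2
    return [D] * (spec.n_clients - half) + [reduced] * half


def prepare_clients(scenario: str, spec: SyntheticSpec, config: ExperimentConfig,
                    seed: int) -> list[tuple[ClientDataset, ViewTransform]]:
    """Generate one run's population and heterogenise + split every view."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    population = generate_base_population(replace(spec, seed=seed))
    keep = _disparity_keep_counts(spec, config) if scenario == "disparity" else None
    out = []
    for c, ds in enumerate(population):
        if scenario == "standard":
            tr = ViewTransform.identity(ds.n_features)
        elif scenario == "disparity":
            ds, tr = apply_feature_disparity(ds, n_keep=keep[c], seed=seed * 1000 + c)
        elif scenario == "shuffled":
            ds, tr = apply_shuffle(ds, seed=seed * 1000 + c)
        else:
            ds, tr = apply_scaling(ds, seed=seed * 1000 + c,
                                   scale_range=config.scale_range)
        ds = split_dataset(ds, seed=seed * 1000 + 500 + c)
        out.append((ds, tr))
    return out


def _client_states(views: Sequence[tuple[ClientDataset, ViewTransform]],
                   config: ExperimentConfig) -> list[ClientState]:
    return [ClientState(client_id=ds.client_id, data=ds, beta=config.beta,
                        local_epochs=config.local_epochs,
                        batch_size=config.batch_size,
                        filter_depth=config.filter_depth)
            for ds, _ in views]


def _score_client(model, spec: ModelSpec, client: ClientState,
                  config: ExperimentConfig) -> dict:
    data = client.data
    test_idx = data.split_indices("test")
    val_idx = data.split_indices("val")
    if spec.kind == "graphconv":
        probs = model.predict(spec, data.X, adjacency=client.adjacency())
        test_p, val_p = probs[test_idx], probs[val_idx]
    else:
        test_p = model.predict(spec, data.X[test_idx])
        val_p = model.predict(spec, data.X[val_idx])
    y_test, y_val = data.y[test_idx], data.y[val_idx]
    if y_test.ndim == 1:
        test_p, val_p = test_p[:, 0], val_p[:, 0]
    return compute_metrics(test_p, y_test,
                           threshold_policy=config.threshold_policy,
                           val_scores=val_p, val_labels=y_val)


def _output_dim(spec: SyntheticSpec) -> int:
    return spec.n_labels if spec.task == "multilabel" else 1


def _run_method(method: str, views, spec: SyntheticSpec, config: ExperimentConfig,
                seed: int) -> list[dict]:
    """Train one method on one run's prepared views; one metric row per client."""
    kind = _model_kind(spec.modality)
    out_dim = _output_dim(spec)
    rows = []
    if method == "proposed":
        mspec = ModelSpec(kind=kind, input_dim=config.knowledge_dim,
                          hidden_dim=config.hidden_dim, output_dim=out_dim,
                          task=spec.task)
        clients = _client_states(views, config)
        state, _ = run_federated(clients, mspec, rounds=config.rounds,
                                 eta=config.eta, seed=seed,
                                 participation=config.participation,
                                 weighted=config.weighted,
                                 track_validation=(config.validation_every
                                                   if config.select_by_validation else 0),
                                 keep_best_val_state=config.select_by_validation)
        for client in clients:
            model = personalize(state, client, mspec,
                                epochs=config.personalization_epochs,
                                beta=config.beta, seed=seed)
            rows.append({"client": client.client_id,
                         **_score_client(model, mspec, client, config)})
    elif method == "fedavg":
        dims = {ds.n_features for ds, _ in views}
        if len(dims) > 1:
            aligned = harmonize_common_subset(views)
            for (ds, _), h in zip(views, aligned):
                dropped = ds.n_features - h.n_features
                if dropped:
                    logger.info("fedavg harmonisation dropped %d of %d features at %s",
                                dropped, ds.n_features, ds.client_id)
            views = [(h, None) for h in aligned]
        D = views[0][0].n_features
        mspec = ModelSpec(kind=kind, input_dim=D, hidden_dim=config.hidden_dim,
                          output_dim=out_dim, task=spec.task)
        clients = _client_states(views, config)
        theta, _ = run_fedavg(clients, mspec, rounds=config.rounds, eta=config.eta,
                              seed=seed, participation=config.participation,
                              weighted=config.weighted,
                              track_validation=(config.validation_every
                                                if config.select_by_validation else 0),
                              keep_best_val_state=config.select_by_validation)
        for client in clients:
            model = personalize_plain(theta, client, mspec,
                                      epochs=config.personalization_epochs,
                                      beta=config.beta, seed=seed)
            rows.append({"client": client.client_id,
                         **_score_client(model, mspec, client, config)})
    elif method == "standalone":
        for client in _client_states(views, config):
            mspec = ModelSpec(kind=kind, input_dim=client.data.n_features,
                              hidden_dim=config.hidden_dim, output_dim=out_dim,
                              task=spec.task)
            model = standalone_train(client, mspec, epochs=config.standalone_epochs,
                                     with_filtering=False, seed=seed,
                                     early_stopping=config.select_by_validation)
            rows.append({"client": client.client_id,
                         **_score_client(model, mspec, client, config)})
    elif method == "standalone_filtering":
        mspec = ModelSpec(kind=kind, input_dim=config.knowledge_dim,
                          hidden_dim=config.hidden_dim, output_dim=out_dim,
                          task=spec.task)
        for client in _client_states(views, config):
            model = standalone_train(client, mspec, epochs=config.standalone_epochs,
                                     with_filtering=True, seed=seed,
                                     early_stopping=config.select_by_validation)
            rows.append({"client": client.client_id,
                         **_score_client(model, mspec, client, config)})
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return rows


def run_scenario_experiment(scenario: str, methods: Sequence[str],
                            spec: SyntheticSpec, n_runs: int = 10,
                            config: ExperimentConfig = ExperimentConfig(),
                            base_seed: int = 0,
                            seeds: Sequence[int] | None = None
                            ) -> dict[str, MetricsReport]:
    """Run every method over ``n_runs`` independently drawn populations.

    Each run uses its own seed (``base_seed + run`` unless ``seeds`` is
    given) for data generation, view transforms, initialisation and batch
    order, emulating independent initialisations.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected a subset of {METHODS}")
    if seeds is None:
        seeds = [base_seed + r for r in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("seeds length must equal n_runs")
    per_method_rows: dict[str, list[dict]] = {m: [] for m in methods}
    for r, s in enumerate(seeds):
        views = prepare_clients(scenario, spec, config, seed=int(s))
        for m in methods:
            for row in _run_method(m, views, spec, config, seed=int(s)):
                per_method_rows[m].append({"run": r, **row})
    reports = {}
    for m in methods:
        df = pd.DataFrame(per_method_rows[m])
        n_undef = int(df[list(METRIC_NAMES)].isna().sum().sum())
        if n_undef:
            logger.info("%s/%s: %d undefined metric values excluded from macro means",
                        scenario, m, n_undef)
        reports[m] = MetricsReport(scenario=scenario, method=m, per_run=df,
                                   n_runs=n_runs, n_undefined=n_undef)
    return reports


def knowledge_size_sweep(sizes: Sequence[int], scenario: str, spec: SyntheticSpec,
                         n_runs: int = 5,
                         config: ExperimentConfig = ExperimentConfig(),
                         base_seed: int = 0) -> pd.DataFrame:
    """Re-run the framework for each knowledge-vector size K, all else fixed.

    Returns one row per K with the mean and standard deviation (over runs)
    of the macro AUROC and AUPRC.
    """
    rows = []
    for K in sizes:
        cfg = replace(config, knowledge_dim=int(K))
        rep = run_scenario_experiment(scenario, ["proposed"], spec, n_runs=n_runs,
                                      config=cfg, base_seed=base_seed)["proposed"]
        auroc = rep.run_macro("auroc")
        auprc = rep.run_macro("auprc")
        rows.append({"K": int(K),
                     "auroc_mean": float(np.nanmean(auroc)),
                     "auroc_sd": float(np.nanstd(auroc, ddof=0)),
                     "auprc_mean": float(np.nanmean(auprc)),
                     "auprc_sd": float(np.nanstd(auprc, ddof=0))})
    return pd.DataFrame(rows).set_index("K")


def run_importance_experiment(spec: SyntheticSpec,
                              config: ExperimentConfig = ExperimentConfig(),
                              n_runs: int = 10, base_seed: int = 0,
                              planted_feature: int | None = None,
                              planted_strength: float = 1.0) -> pd.DataFrame:
    """Feature-disparity probe: do richer clients use their extra feature?

    One base feature receives a strong planted label signal at every client
    (emulating a highly predictive vital sign); the poorer half of the
    clients then lose exactly that feature in their views while the richer
    half keep the full table.  After federated training + personalisation,
    gradient importance is computed at each richer client and the planted
    feature is compared against the median importance of the pure-noise
    features of the same client.

    Returns one row per (run, rich client) with the planted feature's
    importance, the noise median, and their difference.
    """
    if planted_feature is None:
        planted_feature = spec.n_features - 1   # a column outside the informative block
    if not (spec.n_informative <= planted_feature < spec.n_features):
        raise ValueError("planted_feature should be a noise column index")
    kind = _model_kind(spec.modality)
    if kind != "feedforward":
        raise ValueError("the importance probe is defined for tabular data")
    out_rows = []
    noise_cols = [j for j in range(spec.n_informative, spec.n_features)
                  if j != planted_feature]
    half = spec.n_clients // 2
    for r in range(n_runs):
        s = base_seed + r
        population = generate_base_population(replace(spec, seed=s))
        rng = np.random.default_rng(s + 7_777)
        views = []
        for c, ds in enumerate(population):
            y1 = ds.y if ds.y.ndim == 1 else ds.y[:, 0]
            planted = planted_strength * (2.0 * y1 - 1.0) + rng.normal(size=ds.n_samples)
            ds.X[:, planted_feature] = planted
            if c >= spec.n_clients - half:   # poorer clients lose the planted feature
                keep = np.array([j for j in range(spec.n_features)
                                 if j != planted_feature])
                tr = ViewTransform(kept_indices=keep,
                                   permutation=np.arange(len(keep)),
                                   scales=np.ones(len(keep)))
                ds = replace(ds, X=ds.X[:, keep],
                             feature_names=[ds.feature_names[j] for j in keep],
                             transform=tr)
            ds = split_dataset(ds, seed=s * 1000 + 500 + c)
            views.append((ds, ds.transform))
        mspec = ModelSpec(kind="feedforward", input_dim=config.knowledge_dim,
                          hidden_dim=config.hidden_dim, output_dim=_output_dim(spec),
                          task=spec.task)
        clients = _client_states(views, config)
        state, _ = run_federated(clients, mspec, rounds=config.rounds,
                                 eta=config.eta, seed=s,
                                 participation=config.participation)
        for client in clients[:spec.n_clients - half]:     # the richer clients
            model = personalize(state, client, mspec,
                                epochs=config.personalization_epochs,
                                beta=config.beta, seed=s)
            test_idx = client.data.split_indices("test")
            rep = feature_importance(model.theta, mspec,
                                     client.data.X[test_idx], h=model.h,
                                     stack=model.stack,
                                     feature_names=client.data.feature_names,
                                     client_id=client.client_id)
            imp = dict(zip(rep.feature_names, rep.values))
            planted_name = f"f{planted_feature:02d}"
            noise_median = float(np.median([imp[f"f{j:02d}"] for j in noise_cols]))
            out_rows.append({"run": r, "client": client.client_id,
                             "planted": float(imp[planted_name]),
                             "noise_median": noise_median,
                             "excess": float(imp[planted_name]) - noise_median})
    return pd.DataFrame(out_rows)
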