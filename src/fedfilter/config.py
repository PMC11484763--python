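"""Run configuration schema and checkpoint serialisation.

A run configuration is a YAML/JSON document with sections ``data`` (the
synthetic population), ``model``, ``federation``, ``evaluation``, plus the
scenario, methods, seed and output directory.  Unknown keys are rejected
and the fully-resolved configuration (defaults filled in) is echoed into
every run directory, alongside the package version and seeds, so a run can
be reproduced exactly.

Checkpoints hold the global model parameters, the knowledge vector, every
client's filter parameters and the round index, keyed by a hash of the
resolved configuration; loading against a different configuration fails.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .experiments import ExperimentConfig, METHODS, SCENARIOS
from .federation import GlobalState
from .filtering import FilterStack
from .params import ParamDict
from .synthetic import SyntheticSpec

__all__ = ["RunConfig", "load_config", "config_hash",
           "Checkpoint", "save_checkpoint", "load_checkpoint"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Section):
    n_clients: int = 4
    samples_per_client: int | list[int] = [2000, 2000, 2000, 200]
    n_features: int = 28
    n_informative: int = 20
    latent_dim: int = 16
    interaction_strength: float = 0.0
    class_prevalence: float | list[float] = 0.15
    noise_sd: float = 0.5
    shift_sd: float = 0.5
    signal_strength: float = 3.0
    task: str = "binary"
    n_labels: int = 1
    modality: str = "tabular"
    n_timesteps: int = 4

    def to_spec(self, seed: int) -> SyntheticSpec:
        spc = self.samples_per_client
        prev = self.class_prevalence
        return SyntheticSpec(
            n_clients=self.n_clients,
            samples_per_client=tuple(spc) if isinstance(spc, list) else spc,
            n_features=self.n_features, n_informative=self.n_informative,
            latent_dim=self.latent_dim,
            class_prevalence=tuple(prev) if isinstance(prev, list) else prev,
            noise_sd=self.noise_sd, shift_sd=self.shift_sd,
            signal_strength=self.signal_strength,
            interaction_strength=self.interaction_strength, task=self.task,
            n_labels=self.n_labels, modality=self.modality,
            n_timesteps=self.n_timesteps, seed=seed)


class ModelConfig(_Section):
    hidden_dim: int = 128


class FederationConfig(_Section):
    rounds: int = 300
    eta: float = 1.0
    beta: float = 1e-3
    local_epochs: int = 1
    batch_size: int = 64
    knowledge_dim: int = 64
    filter_depth: int = 2
    participation: float = 1.0
    weighted: bool = False


class EvaluationConfig(_Section):
    threshold_policy: str = "youden"
    personalization_epochs: int = 5
    standalone_epochs: int = 300

    @field_validator("threshold_policy")
    @classmethod
    def _policy(cls, v: str) -> str:
        if v not in ("youden", "fixed"):
            raise ValueError("threshold_policy must be 'youden' or 'fixed'")
        return v


class RunConfig(_Section):
    data: DataConfig = DataConfig()
    model: ModelConfig = ModelConfig()
    federation: FederationConfig = FederationConfig()
    evaluation: EvaluationConfig = EvaluationConfig()
    scenario: str = "standard"
    methods: list[str] = ["proposed"]
    n_runs: int = 1
    seed: int = 0
    sweep_sizes: list[int] = [8, 16, 64]
    out_dir: str = "runs/out"

    @field_validator("scenario")
    @classmethod
    def _scenario(cls, v: str) -> str:
        if v not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        return v

    @field_validator("methods")
    @classmethod
    def _methods(cls, v: list[str]) -> list[str]:
        for m in v:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected a subset of {METHODS}")
        return v

    def to_experiment_config(self) -> ExperimentConfig:
        f, e = self.federation, self.evaluation
        return ExperimentConfig(
            knowledge_dim=f.knowledge_dim, hidden_dim=self.model.hidden_dim,
            rounds=f.rounds, eta=f.eta, beta=f.beta,
            local_epochs=f.local_epochs, batch_size=f.batch_size,
            filter_depth=f.filter_depth, participation=f.participation,
            weighted=f.weighted,
            personalization_epochs=e.personalization_epochs,
            standalone_epochs=e.standalone_epochs,
            threshold_policy=e.threshold_policy)

    def resolved(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for k, v in overrides.items():
        if v is not None:
            raw[k] = v
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Identity hash used to pair checkpoints with configurations.

    The total round count is excluded: it is training progress, not run
    identity, and a checkpoint from an interrupted run must be resumable
    under the same configuration with the full round budget.
    """
    resolved = cfg.resolved()
    resolved["federation"] = {k: v for k, v in resolved["federation"].items()
                              if k != "rounds"}
    blob = json.dumps(resolved, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    state: GlobalState
    client_filters: dict[str, FilterStack]
    cfg_hash: str


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {"h": ckpt.state.h}
    for k, v in ckpt.state.theta.items():
        arrays[f"theta/{k}"] = v
    for cid, stack in ckpt.client_filters.items():
        for k, v in stack.to_paramdict().items():
            arrays[f"phi/{cid}/{k}"] = v
    np.savez(path / "params.npz", **arrays)
    meta = {"round_index": ckpt.state.round_index, "config_hash": ckpt.cfg_hash,
            "clients": sorted(ckpt.client_filters)}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, expected_hash: str | None = None) -> Checkpoint:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if expected_hash is not None and meta["config_hash"] != expected_hash:
        raise ValueError(
            f"checkpoint config hash {meta['config_hash']} does not match the "
            f"current configuration ({expected_hash}); refusing to load")
    with np.load(path / "params.npz") as z:
        theta = ParamDict({k.split("/", 1)[1]: z[k] for k in z.files
                           if k.startswith("theta/")})
        h = z["h"]
        filters: dict[str, FilterStack] = {}
        for cid in meta["clients"]:
            prefix = f"phi/{cid}/"
            pd = ParamDict({k[len(prefix):]: z[k] for k in z.files
                            if k.startswith(prefix)})
            filters[cid] = FilterStack.from_paramdict(pd)
    state = GlobalState(theta=theta, h=h, round_index=int(meta["round_index"]))
    return Checkpoint(state=state, client_filters=filters,
                      cfg_hash=meta["config_hash"])
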