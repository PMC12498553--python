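"""Run configuration: one structured document driving every stage.

A single global seed is split deterministically into per-stage seeds so
any stage can be rerun in isolation and still reproduce the full run.
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

STAGES = ("simulate", "preprocess", "train", "analyze", "validate", "report")


class ConfigError(ValueError):
    pass


@dataclass
class SimBlock:
    n_per_group: int = 10
    noise_cv: float = 0.1
    two_batches: bool = False
    batch_shift: float = 0.0
    batch_scale: float = 1.0


@dataclass
class PrepBlock:
    pseudocount: float = 1.0
    outlier_threshold: float = 3.0


@dataclass
class VAEBlock:
    latent_dim: int = 8
    hidden: tuple[int, int] = (64, 32)
    activation: str = "relu"
    learning_rate: float = 1e-3
    iterations: int = 500
    beta: float = 0.1
    kl_warmup: int = 100
    val_fraction: float = 0.2
    tol: float = 1e-4
    patience: int = 20


@dataclass
class AnalysisBlock:
    n_trees: int = 500
    n_folds: int = 5
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    regularization: float = 0.01
    top_n: int = 10
    top_genes: int = 20
    overlay_metabolite: str = "Lactate"


def _build(cls, payload: dict, context: str):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context} block")
    if "hidden" in payload:
        payload = {**payload, "hidden": tuple(payload["hidden"])}
    return cls(**payload)


@dataclass
class RunConfig:
    seed: int = 42
    sim: SimBlock = field(default_factory=SimBlock)
    prep: PrepBlock = field(default_factory=PrepBlock)
    vae: VAEBlock = field(default_factory=VAEBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return int(state[STAGES.index(stage)] % (2**31))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        blocks = {"sim": SimBlock, "prep": PrepBlock,
                  "vae": VAEBlock, "analysis": AnalysisBlock}
        unknown = set(payload) - set(blocks) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs: dict = {"seed": int(payload.get("seed", 42))}
        for name, bcls in blocks.items():
            kwargs[name] = _build(bcls, payload.get(name, {}) or {}, name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["vae"]["hidden"] = list(d["vae"]["hidden"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
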