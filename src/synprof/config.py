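"""Experiment configuration and deterministic seed fan-out.

A run is reproducible from (config, global seed) alone.  The single
global seed is split into independent per-stage seeds through
``numpy.random.SeedSequence`` in a fixed stage order, so any stage can be
re-run in isolation with the seed it would have received inside the full
pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .model import HyperParams, TrainingSchedule

__all__ = ["ExperimentConfig", "stage_seed", "STAGES"]

#: Pipeline stages in execution order; also the seed fan-out order.
STAGES = (
    "library",
    "screens",
    "cell_lines",
    "synergy_table",
    "target_models",
    "synergy_model",
    "validation",
    "interpretation",
    "ablation",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive the per-stage seed from the global one (documented rule).

    ``SeedSequence(global_seed)`` is spawned once per stage in the fixed
    :data:`STAGES` order; the stage's child generates one 32-bit word,
    reduced below 2**31.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return int(children[STAGES.index(stage)].generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything a full run needs, serializable to YAML or JSON."""

    # geometry
    n_targets: int = 13
    n_genes: int = 7
    n_lines: int = 5
    n_drugs: int = 98
    n_pairs_per_line: int = 4753  # all distinct pairs of 98 drugs
    n_bits: int = 256
    fingerprint_sparsity: float = 0.2
    # screens
    n_screen_compounds: int = 1500
    active_fraction: float = 0.1
    label_noise: float = 0.05
    # generative law
    motifs: list[dict] | None = None  # SynergyMotif dicts; None = defaults
    noise_sd: float = 0.5
    # cross-validation
    k_outer: int = 3
    k_inner: int = 3
    grid: str = "desk"  # "desk" | "full" | "model1"
    hyperparams: dict | None = None  # explicit single combination; overrides grid
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    # interpretation
    n_active_min: int = 2
    n_active_max: int = 4
    top_k: int = 20
    dedup: bool = True
    linkage: str = "average"
    n_interpret_lines: int = 2  # interpret the lines with the best per-line r
    # ablation
    ablation_modes: tuple[str, ...] = ("true_profile", "random_weight", "shuffled")
    n_lodo_drugs: int = 5
    # stages to run, in order; later stages are skipped if a prerequisite
    # stage is absent
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def schedule(self) -> TrainingSchedule:
        return TrainingSchedule(
            max_epochs=self.max_epochs, patience=self.patience, batch_size=self.batch_size
        )

    def hyperparameter_grid(self) -> list[HyperParams]:
        from .model import MODEL1_HYPERPARAMS, desk_grid, full_grid

        if self.hyperparams is not None:
            return [
                HyperParams(
                    nodes=tuple(self.hyperparams["nodes"]),
                    activations=tuple(self.hyperparams["activations"]),
                    dropout_rate=float(self.hyperparams.get("dropout_rate", 0.5)),
                    learning_rate=self.learning_rate,
                )
            ]
        if self.grid == "desk":
            return desk_grid(learning_rate=self.learning_rate)
        if self.grid == "full":
            return full_grid(learning_rate=self.learning_rate)
        if self.grid == "model1":
            return [replace(MODEL1_HYPERPARAMS, learning_rate=self.learning_rate)]
        raise ValueError(f"unknown grid {self.grid!r}; choose desk, full or model1")

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    # ---------------------------------------------------------------- #
    # serialization
    # ---------------------------------------------------------------- #

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["ablation_modes"] = list(self.ablation_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "ablation_modes" in d:
            d["ablation_modes"] = tuple(d["ablation_modes"])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def desk(cls, seed: int = 0) -> "ExperimentConfig":
        """A small configuration that exercises every stage in ~a minute."""
        return cls(
            n_drugs=40,
            n_pairs_per_line=250,
            n_screen_compounds=400,
            n_lines=3,
            hyperparams={"nodes": [128, 128, 128], "activations": ["relu", "relu", "relu"]},
            max_epochs=60,
            n_lodo_drugs=3,
            seed=seed,
        )
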