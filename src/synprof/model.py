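"""The drug-synergy regressor: a 3-hidden-layer network with dropout.

The hyperparameter search space is the published grid — each of the three
hidden layers takes 128, 256 or 512 nodes and a tanh or ReLU activation
(216 combinations), with dropout 0.5 after every hidden layer, a single
linear output node, and Adam at learning rate 1e-5.  Because a drug pair
is unordered, inference always averages the predictions for the A+B and
B+A orderings (:func:`predict_symmetric`), which makes the reported score
an exactly symmetric function of the pair.

A full 216-cell grid is expensive at desk scale, so :func:`desk_grid`
exposes a fixed 8-combination subsample (including the best published
configuration) while :func:`full_grid` retains the complete space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._mlp import FeedForwardRegressor
from .features import ScoreNormalizer, swap_profile_blocks

__all__ = [
    "NODE_CHOICES",
    "ACTIVATION_CHOICES",
    "HyperParams",
    "MODEL1_HYPERPARAMS",
    "TrainingSchedule",
    "SynergyRegressor",
    "full_grid",
    "desk_grid",
    "build_regressor",
    "train_regressor",
    "predict_symmetric",
    "predict_symmetric_matrix",
]

NODE_CHOICES = (128, 256, 512)
ACTIVATION_CHOICES = ("tanh", "relu")


@dataclass(frozen=True)
class HyperParams:
    """One cell of the hyperparameter grid."""

    nodes: tuple[int, int, int] = (512, 256, 512)
    activations: tuple[str, str, str] = ("tanh", "relu", "relu")
    dropout_rate: float = 0.5
    learning_rate: float = 1e-5

    def in_grid(self) -> bool:
        return all(n in NODE_CHOICES for n in self.nodes) and all(
            a in ACTIVATION_CHOICES for a in self.activations
        )

    def label(self) -> str:
        layers = "|".join(f"{a}{n}" for n, a in zip(self.nodes, self.activations))
        return f"{layers},lr={self.learning_rate:g}"


#: The best configuration found by the nested grid search on the published
#: data: tanh 512 | ReLU 256 | ReLU 512.
MODEL1_HYPERPARAMS = HyperParams()


def full_grid(learning_rate: float = 1e-5, dropout_rate: float = 0.5) -> list[HyperParams]:
    """All 3^3 * 2^3 = 216 node/activation combinations."""
    return [
        HyperParams(nodes=n, activations=a, dropout_rate=dropout_rate,
                    learning_rate=learning_rate)
        for n in itertools.product(NODE_CHOICES, repeat=3)
        for a in itertools.product(ACTIVATION_CHOICES, repeat=3)
    ]


def desk_grid(learning_rate: float = 1e-3, dropout_rate: float = 0.5) -> list[HyperParams]:
    """A fixed 8-combination subsample of the grid for desk-scale runs.

    Spans every node size and activation in every layer position and
    includes the best published configuration first.
    """
    combos = [
        ((512, 256, 512), ("tanh", "relu", "relu")),
        ((512, 512, 128), ("tanh", "relu", "relu")),
        ((128, 128, 128), ("relu", "relu", "relu")),
        ((256, 256, 256), ("tanh", "tanh", "tanh")),
        ((128, 256, 512), ("relu", "tanh", "relu")),
        ((512, 128, 256), ("relu", "relu", "tanh")),
        ((256, 512, 128), ("tanh", "relu", "tanh")),
        ((128, 512, 256), ("relu", "tanh", "tanh")),
    ]
    return [
        HyperParams(nodes=n, activations=a, dropout_rate=dropout_rate,
                    learning_rate=learning_rate)
        for n, a in combos
    ]


@dataclass
class TrainingSchedule:
    """Epoch budget and batching — configurable, not part of the grid."""

    max_epochs: int = 500
    patience: int = 20
    batch_size: int = 128
    validation_fraction: float = 0.1


#: Reduced schedule for desk-scale experiments and tests.
DESK_SCHEDULE = TrainingSchedule(max_epochs=200, patience=20, batch_size=128)


@dataclass
class SynergyRegressor:
    """A (possibly trained) synergy network plus its score normalizer."""

    hyperparams: HyperParams
    input_width: int
    net: FeedForwardRegressor
    n_targets: int
    normalizer: ScoreNormalizer | None = None

    @property
    def history(self) -> dict:
        return self.net.history

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw (orientation-sensitive) prediction on the normalized scale."""
        return self.net.predict(X)

    def predict_symmetric_matrix(self, X: np.ndarray) -> np.ndarray:
        return predict_symmetric_matrix(self, X)


def build_regressor(hp: HyperParams, input_width: int, n_targets: int = 13,
                    seed: int = 0) -> SynergyRegressor:
    """Build an untrained 3-hidden-layer regressor for the given width.

    Hyperparameters outside the published grid are accepted with a warning
    — the grid is a search space, not a validity constraint.
    """
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    if not hp.in_grid():
        warnings.warn(
            f"hyperparameters {hp.label()} lie outside the standard grid",
            stacklevel=2,
        )
    net = FeedForwardRegressor(
        input_width=input_width,
        hidden_sizes=hp.nodes,
        activations=hp.activations,
        dropout_rate=hp.dropout_rate,
        seed=seed,
    )
    return SynergyRegressor(
        hyperparams=hp, input_width=input_width, net=net, n_targets=n_targets
    )


def train_regressor(
    model: SynergyRegressor,
    X: np.ndarray,
    y_normalized: np.ndarray,
    schedule: TrainingSchedule = TrainingSchedule(),
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> SynergyRegressor:
    """Fit the network on normalized targets with Adam + MSE.

    Seed-reproducible on a single thread; early stopping (and best-weight
    restore) applies whenever a validation split is supplied.
    """
    model.net.fit(
        X,
        y_normalized,
        learning_rate=model.hyperparams.learning_rate,
        max_epochs=schedule.max_epochs,
        batch_size=schedule.batch_size,
        patience=schedule.patience,
        X_val=X_val,
        y_val=y_val,
        seed=seed,
    )
    return model


def predict_symmetric_matrix(model: SynergyRegressor, X: np.ndarray) -> np.ndarray:
    """Swap-averaged predictions for a batch of AB-oriented feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_width:
        raise ValueError(
            f"input width mismatch: got {X.shape[1]}, model expects {model.input_width}"
        )
    ab = model.net.predict(X)
    ba = model.net.predict(swap_profile_blocks(X, model.n_targets))
    return 0.5 * (ab + ba)


def predict_symmetric(
    model: SynergyRegressor,
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    mutation_codes: np.ndarray,
) -> float:
    """Swap-averaged prediction for one pair: mean of f(A,B) and f(B,A)."""
    from .features import assemble_pair_features

    x = assemble_pair_features(profile_a, profile_b, mutation_codes)
    return float(predict_symmetric_matrix(model, x[None, :])[0])


CHECKPOINT_VERSION = 1


def save_checkpoint(model: SynergyRegressor, path) -> None:
    """Serialize a trained regressor to a portable JSON archive.

    Layout: {"version", "hyperparams": {nodes, activations, dropout_rate,
    learning_rate}, "input_width", "n_targets", "normalizer" (or null),
    "weights"/"biases": nested float lists per layer}.
    """
    import json

    payload = {
        "version": CHECKPOINT_VERSION,
        "hyperparams": {
            "nodes": list(model.hyperparams.nodes),
            "activations": list(model.hyperparams.activations),
            "dropout_rate": model.hyperparams.dropout_rate,
            "learning_rate": model.hyperparams.learning_rate,
        },
        "input_width": model.input_width,
        "n_targets": model.n_targets,
        "normalizer": model.normalizer.to_dict() if model.normalizer else None,
        "weights": [w.tolist() for w in model.net.weights],
        "biases": [b.tolist() for b in model.net.biases],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> SynergyRegressor:
    """Restore a regressor saved by :func:`save_checkpoint`."""
    import json

    from .features import ScoreNormalizer

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('version')!r}")
    hp = HyperParams(
        nodes=tuple(payload["hyperparams"]["nodes"]),
        activations=tuple(payload["hyperparams"]["activations"]),
        dropout_rate=payload["hyperparams"]["dropout_rate"],
        learning_rate=payload["hyperparams"]["learning_rate"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_regressor(hp, payload["input_width"], payload["n_targets"])
    model.net.weights = [np.asarray(w, dtype=np.float32) for w in payload["weights"]]
    model.net.biases = [np.asarray(b, dtype=np.float32) for b in payload["biases"]]
    if payload["normalizer"]:
        model.normalizer = ScoreNormalizer.from_dict(payload["normalizer"])
    return model
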