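"""Pair feature assembly, swap augmentation, and ZIP-score normalization.

The synergy regressor sees a fixed 2T+G layout (33 inputs at default
geometry): positions 0..T-1 hold the first drug's inhibition profile,
T..2T-1 the second drug's, and 2T..2T+G-1 the cell line's raw 0/1/2
mutation codes.  Because a pair is unordered, the training table is
doubled by swapping the two profile blocks, and predictions are averaged
over both orderings downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CellLinePanel

__all__ = [
    "assemble_pair_features",
    "swap_profile_blocks",
    "augment_by_swap",
    "build_pair_design",
    "ScoreNormalizer",
]


def assemble_pair_features(
    profile_a: np.ndarray, profile_b: np.ndarray, mutation_codes: np.ndarray
) -> np.ndarray:
    """Concatenate [profile_a | profile_b | mutation codes] into one vector."""
    profile_a = np.asarray(profile_a, dtype=float)
    profile_b = np.asarray(profile_b, dtype=float)
    mutation_codes = np.asarray(mutation_codes, dtype=float)
    if profile_a.ndim != 1 or profile_b.ndim != 1 or profile_a.shape != profile_b.shape:
        raise ValueError(
            f"profile blocks must be equal-length 1-d vectors; got "
            f"{profile_a.shape} and {profile_b.shape}"
        )
    if mutation_codes.ndim != 1:
        raise ValueError(f"mutation block must be a 1-d vector; got shape {mutation_codes.shape}")
    if not set(np.unique(mutation_codes)).issubset({0.0, 1.0, 2.0}):
        raise ValueError("mutation block must contain only codes 0, 1, 2")
    return np.concatenate([profile_a, profile_b, mutation_codes])


def swap_profile_blocks(X: np.ndarray, n_targets: int) -> np.ndarray:
    """Exchange the two drug-profile blocks, leaving mutations in place."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = n_targets
    if X.shape[1] < 2 * T:
        raise ValueError(f"width {X.shape[1]} too small for two blocks of {T}")
    out = X.copy()
    out[:, :T] = X[:, T : 2 * T]
    out[:, T : 2 * T] = X[:, :T]
    return out


def augment_by_swap(
    X: np.ndarray,
    y: np.ndarray,
    n_targets: int,
    meta: pd.DataFrame | None = None,
):
    """Double a feature table by adding the block-swapped copy of each row.

    The target score is carried over unchanged (synergy is a property of
    the unordered pair).  When ``meta`` is given, the appended rows get
    orientation "BA" and the originals "AB".
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and target count differ")
    X_out = np.vstack([X, swap_profile_blocks(X, n_targets)])
    y_out = np.concatenate([y, y])
    if meta is None:
        return X_out, y_out
    m_ab = meta.copy()
    m_ab["orientation"] = "AB"
    m_ba = meta.copy()
    m_ba["orientation"] = "BA"
    return X_out, y_out, pd.concat([m_ab, m_ba], ignore_index=True)


def build_pair_design(
    pairs: pd.DataFrame, profiles: pd.DataFrame, panel: CellLinePanel
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the design matrix for a pairs table.

    ``pairs`` needs columns drug_a, drug_b, cell_line (zip_score optional);
    ``profiles`` is indexed by compound id with one column per feature.
    Returns ``(X, y)`` with X of width ``2*T + G`` in AB orientation and y
    the raw zip scores (zeros if absent).  Unknown drugs or lines raise.
    """
    for col in ("drug_a", "drug_b", "cell_line"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table lacks required column {col!r}")
    known = set(profiles.index)
    bad_drugs = sorted(
        (set(pairs["drug_a"]) | set(pairs["drug_b"])) - known
    )
    if bad_drugs:
        raise KeyError(f"pairs table references unknown drugs: {bad_drugs[:10]}")
    bad_lines = sorted(set(pairs["cell_line"]) - set(panel.line_ids))
    if bad_lines:
        raise KeyError(f"pairs table references unknown cell lines: {bad_lines}")

    prof = profiles.to_numpy(dtype=float)
    row_of = {cid: i for i, cid in enumerate(profiles.index)}
    line_of = {lid: i for i, lid in enumerate(panel.line_ids)}
    ia = pairs["drug_a"].map(row_of).to_numpy()
    ib = pairs["drug_b"].map(row_of).to_numpy()
    il = pairs["cell_line"].map(line_of).to_numpy()
    X = np.hstack(
        [prof[ia], prof[ib], panel.mutation_codes[il].astype(float)]
    )
    y = (
        pairs["zip_score"].to_numpy(dtype=float)
        if "zip_score" in pairs.columns
        else np.zeros(len(pairs))
    )
    return X, y


@dataclass
class ScoreNormalizer:
    """Affine map taking training ZIP scores to mean 0, variance 1.

    Uses the population variance so the transformed training variance is
    exactly 1.  ``invert`` maps model predictions back to the original ZIP
    scale.
    """

    mean: float
    variance: float

    def __post_init__(self):
        if not self.variance > 0:
            raise ValueError("degenerate variance: scores are constant")

    @classmethod
    def fit(cls, scores) -> "ScoreNormalizer":
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size < 2:
            raise ValueError("need at least 2 scores to fit a normalizer")
        var = float(np.var(scores))  # population variance
        if var <= 0:
            raise ValueError("degenerate variance: scores are constant")
        return cls(mean=float(np.mean(scores)), variance=var)

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / np.sqrt(self.variance)

    def invert(self, z):
        return np.asarray(z, dtype=float) * np.sqrt(self.variance) + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean, "variance": self.variance}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreNormalizer":
        return cls(mean=float(d["mean"]), variance=float(d["variance"]))
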