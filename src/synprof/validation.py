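"""Nested cross-validation, grid search, and generalization protocols.

The evaluation design follows the two-level scheme standard for synergy
regression: a 3x3 nested CV in which outer folds estimate generalization
and inner folds pick hyperparameters by mean validation Pearson r, with
cell-line stratification at both levels; plus leave-one-cell-line-out
(LOCO) and leave-one-drug-out (LODO) splits and a paired four-way
feature-set comparison.  Swap augmentation is applied to training
portions only, the score normalizer is refit on each training portion,
and every reported metric comes from swap-averaged predictions on
indices provably disjoint from anything used in training or selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from .model import (
    HyperParams,
    SynergyRegressor,
    TrainingSchedule,
    build_regressor,
    predict_symmetric_matrix,
    train_regressor,
)
from .synthetic import AblationMode, CellLinePanel, CompoundLibrary, make_ablation_profiles

__all__ = [
    "EvalReport",
    "OuterFoldResult",
    "LeakageError",
    "stratified_kfold",
    "grid_search_inner",
    "nested_cv",
    "evaluate_predictions",
    "leave_one_cell_line_out",
    "leave_one_drug_out",
    "compare_feature_sets",
    "pearson_r",
]


class LeakageError(RuntimeError):
    """Test indices overlapped a training/selection index set."""


def pearson_r(x, y) -> float | None:
    """Pearson correlation; None (not 0) when either side has no variance."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class EvalReport:
    """Overall and per-group Pearson r / MSE for one evaluation."""

    overall_r: float | None
    overall_mse: float
    n: int
    per_group: dict[str, dict] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.overall_r,
            "mse": self.overall_mse,
            "n": self.n,
            "per_group": self.per_group,
            **self.extras,
        }


def evaluate_predictions(predicted, observed, groups=None) -> EvalReport:
    """Pearson r and MSE overall and per group label.

    Groups with fewer than 2 records are skipped with a warning; a group
    with zero variance gets ``pearson_r: None`` rather than a coerced 0.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size < 2:
        raise ValueError("need at least 2 records to evaluate")
    overall_mse = float(np.mean((predicted - observed) ** 2))
    report = EvalReport(
        overall_r=pearson_r(predicted, observed), overall_mse=overall_mse, n=predicted.size
    )
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            mask = groups == g
            if mask.sum() < 2:
                warnings.warn(f"group {g!r} has <2 records; skipped", stacklevel=2)
                continue
            report.per_group[str(g)] = {
                "pearson_r": pearson_r(predicted[mask], observed[mask]),
                "mse": float(np.mean((predicted[mask] - observed[mask]) ** 2)),
                "n": int(mask.sum()),
            }
    return report


def stratified_kfold(table: pd.DataFrame, k: int, seed: int = 0) -> np.ndarray:
    """Partition a pairs table into k folds stratified by cell line.

    Returns an integer fold id per row.  Deterministic per seed; every
    cell line must contribute at least k records.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lines = table["cell_line"].to_numpy()
    counts = pd.Series(lines).value_counts()
    thin = counts[counts < k]
    if len(thin):
        raise ValueError(
            f"cell line(s) with fewer than {k} records: {sorted(thin.index)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(table), dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(table)), lines)):
        folds[test_idx] = fold_id
    return folds


def _assert_disjoint(train_idx: np.ndarray, test_idx: np.ndarray, context: str) -> None:
    overlap = np.intersect1d(train_idx, test_idx)
    if overlap.size:
        raise LeakageError(f"{context}: {overlap.size} test indices found in training set")


def _fit_on_split(
    X: np.ndarray,
    y_raw: np.ndarray,
    train_idx: np.ndarray,
    hp: HyperParams,
    schedule: TrainingSchedule,
    seed: int,
    n_targets: int,
) -> tuple[SynergyRegressor, feat.ScoreNormalizer]:
    """Fit normalizer + regressor using only ``train_idx`` rows.

    A validation slice for early stopping is carved from the training rows
    before augmentation, so no mirrored twin of a validation row is seen
    in training.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(train_idx)
    n_val = int(round(schedule.validation_fraction * len(order)))
    val_idx, fit_idx = order[:n_val], order[n_val:]

    normalizer = feat.ScoreNormalizer.fit(y_raw[fit_idx])
    y_fit = normalizer.transform(y_raw[fit_idx])
    X_aug, y_aug = feat.augment_by_swap(X[fit_idx], y_fit, n_targets)

    model = build_regressor(hp, X.shape[1], n_targets=n_targets, seed=seed)
    train_regressor(
        model,
        X_aug,
        y_aug,
        schedule=schedule,
        seed=seed,
        X_val=X[val_idx] if n_val else None,
        y_val=normalizer.transform(y_raw[val_idx]) if n_val else None,
    )
    model.normalizer = normalizer
    return model, normalizer


def grid_search_inner(
    X: np.ndarray,
    y_raw: np.ndarray,
    table: pd.DataFrame,
    grid: list[HyperParams],
    k_inner: int = 3,
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
    n_targets: int = 13,
) -> tuple[HyperParams, dict[str, float | None]]:
    """Pick the grid combination with the best mean inner-fold Pearson r.

    Each combination is trained on k_inner-1 inner folds (swap-augmented)
    and scored by swap-averaged Pearson r on the held inner fold, averaged
    over the rotations.  Constant predictions on a fold make that
    combination's mean undefined (None) and rank it last; ties break by
    grid order.  A single-combination grid is returned immediately.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if len(grid) == 1:
        return grid[0], {grid[0].label(): None}

    folds = stratified_kfold(table, k_inner, seed=seed)
    means: dict[str, float | None] = {}
    best: tuple[int, float] | None = None  # (grid position, mean r)
    for gi, hp in enumerate(grid):
        rs: list[float | None] = []
        for f in range(k_inner):
            tr = np.flatnonzero(folds != f)
            te = np.flatnonzero(folds == f)
            _assert_disjoint(tr, te, f"inner fold {f}")
            model, norm = _fit_on_split(
                X, y_raw, tr, hp, schedule, seed=seed + 1000 * f, n_targets=n_targets
            )
            pred = predict_symmetric_matrix(model, X[te])
            rs.append(pearson_r(pred, norm.transform(y_raw[te])))
        mean_r = None if any(r is None for r in rs) else float(np.mean(rs))
        means[hp.label()] = mean_r
        if mean_r is not None and (best is None or mean_r > best[1]):
            best = (gi, mean_r)
    if best is None:
        warnings.warn("every combination produced undefined correlations", stacklevel=2)
        return grid[0], means
    return grid[best[0]], means


@dataclass
class OuterFoldResult:
    """One outer fold of the nested CV: its model, choice, and report."""

    fold: int
    model: SynergyRegressor
    best_hp: HyperParams
    inner_scores: dict[str, float | None]
    report: EvalReport
    test_index: np.ndarray
    predictions: pd.DataFrame


def nested_cv(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    panel: CellLinePanel,
    grid: list[HyperParams],
    k_outer: int = 3,
    k_inner: int = 3,
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
) -> list[OuterFoldResult]:
    """Nested cross-validation with cell-line stratification at both levels.

    For each of the k_outer folds: run the inner grid search on the
    remaining folds, refit with the winning combination, and report
    swap-averaged Pearson r / MSE (normalized and original scales) on the
    untouched outer test fold.  The k_outer fitted models double as the
    interpretation ensemble.
    """
    n_targets = profiles.shape[1]
    X, y_raw = feat.build_pair_design(table, profiles, panel)
    outer = stratified_kfold(table, k_outer, seed=seed)
    lines = table["cell_line"].to_numpy()
    results = []
    for f in range(k_outer):
        tr = np.flatnonzero(outer != f)
        te = np.flatnonzero(outer == f)
        _assert_disjoint(tr, te, f"outer fold {f}")
        best_hp, inner_scores = grid_search_inner(
            X[tr],
            y_raw[tr],
            table.iloc[tr].reset_index(drop=True),
            grid,
            k_inner=k_inner,
            seed=seed + 17 * f,
            schedule=schedule,
            n_targets=n_targets,
        )
        model, norm = _fit_on_split(
            X, y_raw, tr, best_hp, schedule, seed=seed + 17 * f, n_targets=n_targets
        )
        pred_norm = predict_symmetric_matrix(model, X[te])
        obs_norm = norm.transform(y_raw[te])
        report = evaluate_predictions(pred_norm, obs_norm, groups=lines[te])
        report.extras["mse_original_scale"] = float(
            np.mean((norm.invert(pred_norm) - y_raw[te]) ** 2)
        )
        report.extras["best_hyperparams"] = best_hp.label()
        predictions = table.iloc[te][["drug_a", "drug_b", "cell_line"]].copy()
        predictions["observed"] = y_raw[te]
        predictions["predicted_normalized"] = pred_norm
        predictions["predicted_original_scale"] = norm.invert(pred_norm)
        predictions["outer_fold"] = f
        results.append(
            OuterFoldResult(
                fold=f,
                model=model,
                best_hp=best_hp,
                inner_scores=inner_scores,
                report=report,
                test_index=te,
                predictions=predictions.reset_index(drop=True),
            )
        )
    return results


def _holdout_eval(
    X, y_raw, lines, tr, te, hp, schedule, seed, n_targets
) -> EvalReport:
    _assert_disjoint(tr, te, "holdout split")
    model, norm = _fit_on_split(X, y_raw, tr, hp, schedule, seed=seed, n_targets=n_targets)
    pred = predict_symmetric_matrix(model, X[te])
    report = evaluate_predictions(pred, norm.transform(y_raw[te]), groups=lines[te])
    report.extras["mse_original_scale"] = float(np.mean((norm.invert(pred) - y_raw[te]) ** 2))
    return report


def leave_one_cell_line_out(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    panel: CellLinePanel,
    hp: HyperParams,
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
) -> dict:
    """Hold out all pairs of one cell line at a time; summarize mean ± sd."""
    lines_present = [l for l in panel.line_ids if l in set(table["cell_line"])]
    if len(lines_present) < 2:
        raise ValueError("leave-one-cell-line-out needs at least 2 cell lines")
    n_targets = profiles.shape[1]
    X, y_raw = feat.build_pair_design(table, profiles, panel)
    lines = table["cell_line"].to_numpy()
    per_line: dict[str, EvalReport] = {}
    for line in lines_present:
        te = np.flatnonzero(lines == line)
        tr = np.flatnonzero(lines != line)
        per_line[line] = _holdout_eval(
            X, y_raw, lines, tr, te, hp, schedule, seed=seed, n_targets=n_targets
        )
    return _summarize(per_line)


def leave_one_drug_out(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    panel: CellLinePanel,
    drugs: list[str],
    hp: HyperParams,
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
) -> dict:
    """Hold out all pairs containing one drug at a time; summarize mean ± sd."""
    in_table = set(table["drug_a"]) | set(table["drug_b"])
    n_targets = profiles.shape[1]
    X, y_raw = feat.build_pair_design(table, profiles, panel)
    lines = table["cell_line"].to_numpy()
    contains = {
        d: ((table["drug_a"] == d) | (table["drug_b"] == d)).to_numpy() for d in drugs
    }
    per_drug: dict[str, EvalReport] = {}
    for d in drugs:
        if d not in in_table:
            raise KeyError(f"drug {d!r} does not appear in the pairs table")
        if contains[d].sum() < 2:
            raise ValueError(f"drug {d!r} appears in fewer than 2 pairs")
        te = np.flatnonzero(contains[d])
        tr = np.flatnonzero(~contains[d])
        per_drug[d] = _holdout_eval(
            X, y_raw, lines, tr, te, hp, schedule, seed=seed, n_targets=n_targets
        )
    return _summarize(per_drug)


def _summarize(per_unit: dict[str, EvalReport]) -> dict:
    rs = [rep.overall_r for rep in per_unit.values() if rep.overall_r is not None]
    mses = [rep.overall_mse for rep in per_unit.values()]
    return {
        "per_unit": {k: rep.to_dict() for k, rep in per_unit.items()},
        "mean_r": float(np.mean(rs)) if rs else None,
        "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else None,
        "mean_mse": float(np.mean(mses)),
        "sd_mse": float(np.std(mses, ddof=1)) if len(mses) > 1 else None,
    }


def compare_feature_sets(
    library: CompoundLibrary,
    panel: CellLinePanel,
    table: pd.DataFrame,
    modes: list[AblationMode | str],
    hp: HyperParams,
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
    estimated_profiles: pd.DataFrame | None = None,
    lodo_drugs: list[str] | None = None,
    n_lodo_drugs: int = 5,
) -> pd.DataFrame:
    """Paired four-way feature-set comparison: test, LOCO, and LODO metrics.

    Every mode sees the same pairs, the same stratified test split, the
    same left-out lines, and the same left-out drugs (drawn once from
    ``seed``), so differences between rows reflect the feature sets alone.
    Returns one row per mode with r and MSE for each protocol.
    """
    modes = [AblationMode(m) for m in modes]
    rng = np.random.default_rng(seed)
    if lodo_drugs is None:
        in_table = sorted(set(table["drug_a"]) | set(table["drug_b"]))
        counts = {
            d: int(((table["drug_a"] == d) | (table["drug_b"] == d)).sum()) for d in in_table
        }
        eligible = [d for d in in_table if counts[d] >= 2]
        lodo_drugs = list(rng.choice(eligible, size=min(n_lodo_drugs, len(eligible)),
                                     replace=False))
    folds = stratified_kfold(table, 3, seed=seed)
    te = np.flatnonzero(folds == 0)
    tr = np.flatnonzero(folds != 0)
    lines = table["cell_line"].to_numpy()

    rows = []
    for mode in modes:
        prof = make_ablation_profiles(
            library, mode, seed=seed, estimated_profiles=estimated_profiles
        )
        n_targets = prof.shape[1]
        X, y_raw = feat.build_pair_design(table, prof, panel)
        test_rep = _holdout_eval(
            X, y_raw, lines, tr, te, hp, schedule, seed=seed, n_targets=n_targets
        )
        loco = leave_one_cell_line_out(table, prof, panel, hp, seed=seed, schedule=schedule)
        lodo = leave_one_drug_out(
            table, prof, panel, lodo_drugs, hp, seed=seed, schedule=schedule
        )
        rows.append(
            {
                "mode": mode.value,
                "r_test": test_rep.overall_r,
                "mse_test": test_rep.overall_mse,
                "r_loco_mean": loco["mean_r"],
                "r_loco_sd": loco["sd_r"],
                "mse_loco_mean": loco["mean_mse"],
                "r_lodo_mean": lodo["mean_r"],
                "r_lodo_sd": lodo["sd_r"],
                "mse_lodo_mean": lodo["mean_mse"],
            }
        )
    return pd.DataFrame(rows).set_index("mode")
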