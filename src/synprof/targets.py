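"""Per-target bioactivity classifiers (stage 1 of the two-stage framework).

Each of the T panel proteins gets a binary classifier that maps a
compound's structure fingerprint to an inhibition score in [0, 1].  The
activity labelling rule is the standard screening convention: IC50 ≤ 10 μM
is inhibitory, an explicit inactive flag is non-inhibitory, and anything
else (e.g. a weak IC50 above 10 μM with no flag) is excluded.  Performance
is reported as ROC-AUC under stratified tenfold cross-validation, plus a
held-out split, since class imbalance is the norm in screening data.

The classifier is pluggable: any scikit-learn-style estimator factory with
``predict_proba`` can stand behind the interface, so a graph neural network
can replace the default regularized logistic model without touching the
rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .synthetic import ACTIVE_IC50_UM, ActivityRecord, CompoundLibrary, target_names

__all__ = [
    "LabeledActivitySet",
    "TargetModel",
    "DataConsistencyError",
    "label_activity",
    "train_target_classifier",
    "build_inhibition_profiles",
]


class DataConsistencyError(ValueError):
    """A record is simultaneously active and flagged inactive."""


@dataclass
class LabeledActivitySet:
    """Labelled compounds for one target: fingerprints + binary class."""

    target_index: int
    compound_ids: list[str]
    features: np.ndarray  # (n, B) fingerprint bits
    labels: np.ndarray  # 1 = inhibitory, 0 = non-inhibitory
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.compound_ids)


@dataclass
class TargetModel:
    """A fitted per-target classifier with its CV report."""

    target_index: int
    estimator: object
    fold_rocs: list[float] = field(default_factory=list)
    holdout_roc: float | None = None
    n_excluded: int = 0

    @property
    def cv_roc(self) -> float:
        return float(np.mean(self.fold_rocs))

    def score(self, fingerprints: np.ndarray) -> np.ndarray:
        """Inhibition scores in [0, 1], one per compound."""
        proba = self.estimator.predict_proba(np.asarray(fingerprints, dtype=float))
        return proba[:, 1]


def label_activity(
    records: Sequence[ActivityRecord], library: CompoundLibrary
) -> LabeledActivitySet:
    """Apply the activity rule: IC50 ≤ 10 μM inhibitory, flag non-inhibitory.

    Records with an IC50 above 10 μM and no inactive flag are excluded and
    counted.  A record claiming both activity and inactivity raises
    :class:`DataConsistencyError`.
    """
    fp_by_id = dict(zip(library.compound_ids, library.fingerprints))
    target_index = records[0].target_index if records else -1
    ids: list[str] = []
    feats: list[np.ndarray] = []
    labels: list[int] = []
    n_excluded = 0
    for r in records:
        if r.compound_id not in fp_by_id:
            raise KeyError(f"record references unknown compound {r.compound_id!r}")
        if r.ic50_um is not None and r.ic50_um <= ACTIVE_IC50_UM and r.inactive_flag:
            raise DataConsistencyError(
                f"{r.compound_id}: IC50 {r.ic50_um} μM (active) but flagged inactive"
            )
        if r.ic50_um is not None and r.ic50_um <= ACTIVE_IC50_UM:
            label = 1
        elif r.inactive_flag:
            label = 0
        else:
            n_excluded += 1
            continue
        ids.append(r.compound_id)
        feats.append(fp_by_id[r.compound_id])
        labels.append(label)
    features = (
        np.asarray(feats, dtype=np.int8) if feats else np.zeros((0, library.n_bits), np.int8)
    )
    return LabeledActivitySet(
        target_index=target_index,
        compound_ids=ids,
        features=features,
        labels=np.asarray(labels, dtype=np.int8),
        n_excluded=n_excluded,
    )


def _default_classifier() -> LogisticRegression:
    return LogisticRegression(C=1.0, max_iter=2000)


def train_target_classifier(
    data: LabeledActivitySet,
    folds: int = 10,
    seed: int = 0,
    classifier_factory: Callable[[], object] = _default_classifier,
    holdout_fraction: float = 0.2,
) -> TargetModel:
    """Fit a per-target classifier with stratified k-fold ROC reporting.

    Two ROC figures are reported because conventions differ: ``cv_roc``
    (mean of the per-fold held-out ROCs) and ``holdout_roc`` (a single
    stratified split refit on the remainder).  The returned estimator is
    refit on all labelled data.
    """
    classes = set(np.unique(data.labels))
    for cls_label, name in ((1, "inhibitory"), (0, "non_inhibitory")):
        if cls_label not in classes:
            raise ValueError(f"cannot train: no {name} compounds in the labelled set")
    if len(data) < folds:
        raise ValueError(f"need at least {folds} compounds for {folds}-fold CV")

    X = data.features.astype(float)
    y = data.labels.astype(int)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_rocs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = classifier_factory()
        clf.fit(X[train_idx], y[train_idx])
        fold_rocs.append(float(roc_auc_score(y[test_idx], clf.predict_proba(X[test_idx])[:, 1])))

    holdout_roc = None
    if 0.0 < holdout_fraction < 1.0 and min(np.bincount(y)) >= 2:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout_fraction, stratify=y, random_state=seed
        )
        if len(np.unique(y_te)) == 2:
            clf = classifier_factory()
            clf.fit(X_tr, y_tr)
            holdout_roc = float(roc_auc_score(y_te, clf.predict_proba(X_te)[:, 1]))

    final = classifier_factory()
    final.fit(X, y)
    return TargetModel(
        target_index=data.target_index,
        estimator=final,
        fold_rocs=fold_rocs,
        holdout_roc=holdout_roc,
        n_excluded=data.n_excluded,
    )


def build_inhibition_profiles(
    models: Sequence[TargetModel], library: CompoundLibrary
) -> pd.DataFrame:
    """Score every library compound with every target model.

    Returns one row per drug and one score column per target, values in
    [0, 1], rows in library order — the drug-level feature table consumed
    by the synergy model.
    """
    if len(models) != library.n_targets:
        raise ValueError(
            f"got {len(models)} models for {library.n_targets} targets"
        )
    names = target_names(library.n_targets)
    if library.n_compounds == 0:
        return pd.DataFrame(columns=list(names), index=pd.Index([], name="compound_id"))
    cols = {}
    fp = library.fingerprints.astype(float)
    for m, name in zip(models, names):
        scores = m.score(fp)
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError(f"classifier for {name} produced scores outside [0, 1]")
        cols[name] = scores
    return pd.DataFrame(cols, index=pd.Index(library.compound_ids, name="compound_id"))
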