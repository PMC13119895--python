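"""Random-forest cluster-separability oracle.

Given a fixed cluster partition (the labels from the baseline clustering
solution) and a candidate marker panel, the oracle measures how separable
the partition is from that panel alone: a random forest is trained on a
stratified 70/30 split, tuned by 3-fold cross-validation within the
training set, and scored on the held-out test set.  It reports held-out
accuracy, Cohen's kappa, and permutation-based variable importances
normalised to percentage contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass
class OracleConfig:
    """Oracle settings; defaults follow the common processing pipeline:
    500 trees, 70/30 stratified split, 3-fold CV tuning of ``mtry``,
    permutation importance averaged over 10 shuffles."""

    n_trees: int = 500
    train_fraction: float = 0.70
    cv_folds: int = 3
    mtry: int | str = "cv"          # "cv": tune over {sqrt(p)-1, sqrt(p), sqrt(p)+1}
    n_importance_permutations: int = 10
    compute_importance: bool = True  # skip when only accuracy/kappa are needed
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class OracleResult:
    """One oracle evaluation of a panel against fixed cluster labels."""

    accuracy: float
    kappa: float
    importance_pct: pd.Series
    confusion: np.ndarray
    cv_accuracy: float
    mtry: int
    seed: int

    def passes(self, accuracy_min: float, kappa_min: float) -> bool:
        return self.accuracy > accuracy_min and self.kappa > kappa_min


def stratified_partition(labels: np.ndarray, train_fraction: float = 0.70,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into train/test preserving class proportions.

    Per-class train counts are the rounded ``class_size x train_fraction``
    (always leaving at least one member on each side), so proportions are
    preserved to within one participant per class.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        rng.shuffle(idx)
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a k x k confusion matrix:
    ``kappa = (p_o - p_e) / (1 - p_e)``, with ``p_o`` the observed accuracy
    and ``p_e`` the marginal chance agreement.  Returns 0 for the
    degenerate single-class case where ``p_e = p_o = 1``."""
    C = np.asarray(confusion, dtype=float)
    if C.size == 0 or C.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    n = C.sum()
    p_o = np.trace(C) / n
    p_e = float(C.sum(axis=1) @ C.sum(axis=0)) / n**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _mtry_grid(p: int) -> list[int]:
    base = int(np.floor(np.sqrt(p)))
    return sorted({min(max(v, 1), p) for v in (base - 1, base, base + 1)})


def evaluate_panel(matrix: pd.DataFrame, panel: list[str], labels: np.ndarray,
                   config: OracleConfig | None = None) -> OracleResult:
    """Fit and score the oracle for one marker panel.

    ``matrix`` is the preprocessed (standardised) participants x markers
    frame; ``labels`` is the fixed baseline cluster partition.  The split,
    tree construction and importance permutations all derive from
    ``config.seed``, so results are reproducible.
    """
    config = config or OracleConfig()
    config.validate()
    if len(panel) == 0:
        raise ValueError("panel is empty")
    missing = [m for m in panel if m not in matrix.columns]
    if missing:
        raise ValueError(f"markers not in matrix: {missing}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant; separability is undefined")

    X = matrix[list(panel)].to_numpy(dtype=float)
    train_idx, test_idx = stratified_partition(labels, config.train_fraction, config.seed)
    X_tr, y_tr = X[train_idx], labels[train_idx]
    X_te, y_te = X[test_idx], labels[test_idx]

    p = X.shape[1]
    if config.mtry == "cv":
        grid = _mtry_grid(p)
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                             random_state=config.seed)
        cv_scores = {}
        for m in grid:
            rf = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=m,
                random_state=config.seed, n_jobs=1,
            )
            cv_scores[m] = float(np.mean(cross_val_score(rf, X_tr, y_tr, cv=cv)))
        mtry = max(cv_scores, key=lambda m: (cv_scores[m], -m))
        cv_accuracy = cv_scores[mtry]
    else:
        mtry = min(int(np.floor(np.sqrt(p))), p) if config.mtry == "sqrt" else int(config.mtry)
        mtry = min(max(mtry, 1), p)
        cv_accuracy = np.nan

    rf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=mtry,
        random_state=config.seed, n_jobs=1,
    )
    rf.fit(X_tr, y_tr)
    pred = rf.predict(X_te)

    classes = np.unique(labels)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, q in zip(y_te, pred):
        confusion[pos[t], pos[q]] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    kappa = cohen_kappa(confusion)

    if config.compute_importance:
        # test-set permutation importance: shuffle one column, measure the
        # accuracy drop, average over permutations; floor at 0, scale to %
        imp = permutation_importance(
            rf, X_te, y_te, n_repeats=config.n_importance_permutations,
            random_state=config.seed, scoring="accuracy", n_jobs=1,
        )
        raw = np.maximum(imp.importances_mean, 0.0)
        total = raw.sum()
        if total > 0:
            pct = 100.0 * raw / total
        else:  # no marker moves accuracy: spread uniformly over varying markers
            varying = X_te.std(axis=0) > 0
            pct = np.where(varying, 100.0 / max(varying.sum(), 1), 0.0)
        importance_pct = pd.Series(pct, index=list(panel), name="importance_pct")
    else:
        importance_pct = pd.Series(np.nan, index=list(panel), name="importance_pct")

    return OracleResult(
        accuracy=accuracy,
        kappa=kappa,
        importance_pct=importance_pct,
        confusion=confusion,
        cv_accuracy=cv_accuracy,
        mtry=int(mtry),
        seed=config.seed,
    )
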