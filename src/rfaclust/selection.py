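"""Recursive feature addition: three candidate-inclusion strategies.

All three strategies extend a fixed baseline marker panel with candidates,
judged by the random-forest separability oracle against the *baseline*
cluster labels (the partition never changes during selection):

* **Model 1 — cumulative addition**: candidates are tried one at a time in
  a fixed, biologically motivated order; a candidate that passes the
  importance / accuracy / kappa thresholds stays in the panel for all
  subsequent steps.
* **Model 2 — independent addition**: every candidate is evaluated on its
  own against ``baseline + {candidate}``; no cumulative retention, so the
  result is invariant to evaluation order.
* **Model 3 — greedy bidirectional**: forward steps add whichever candidate
  most improves held-out accuracy (kappa, then marker id, break ties);
  once no candidate strictly improves, backward steps drop previously
  added markers whose removal strictly improves accuracy; forward/backward
  cycles repeat until a full cycle changes nothing.

Selection stability is assessed by repeating the procedure over fresh
stratified train/test splits and recording, per candidate, the fraction of
iterations in which it produced a strict improvement in both accuracy and
kappa over that iteration's baseline (models 1-2) or survived the full
greedy path (model 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .oracle import OracleConfig, OracleResult, evaluate_panel


@dataclass
class SelectionCriteria:
    """Retention thresholds.

    ``accuracy_min`` / ``kappa_min`` are strict lower bounds (a candidate
    must *exceed* them).  ``importance_min_pct`` is the minimum normalised
    permutation importance; ``None`` means the uniform share ``100 / p`` of
    the evaluated panel.  The delta thresholds govern the resampling-based
    stability criterion: improvement over the iteration's baseline must be
    strictly greater than these (default 0)."""

    accuracy_min: float = 0.80
    kappa_min: float = 0.65
    importance_min_pct: float | None = None
    delta_accuracy_min: float = 0.0
    delta_kappa_min: float = 0.0

    def importance_threshold(self, panel_size: int) -> float:
        if self.importance_min_pct is not None:
            return self.importance_min_pct
        return 100.0 / panel_size


@dataclass
class SelectionResult:
    model_id: int
    retained: list[str]
    per_candidate: pd.DataFrame     # accuracy, kappa, importance_pct, retained
    baseline_metrics: OracleResult
    path: list[tuple[int, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.per_candidate.attrs.get("baseline", []))
        if overlap:
            raise ValueError(f"baseline markers cannot be retained candidates: {overlap}")


@dataclass
class FrequencyReport:
    frequencies: pd.Series          # per candidate, in [0, 1]
    n_iterations: int
    per_iteration: list[set[str]]

    def __post_init__(self) -> None:
        counts = pd.Series(0, index=self.frequencies.index, dtype=int)
        for s in self.per_iteration:
            for m in s:
                counts[m] += 1
        if not np.allclose(self.frequencies, counts / self.n_iterations):
            raise ValueError("frequencies inconsistent with per-iteration sets")


def _check_candidates(matrix: pd.DataFrame, baseline: list[str],
                      candidates: list[str]) -> None:
    for m in list(baseline) + list(candidates):
        if m not in matrix.columns:
            raise ValueError(f"marker {m!r} not present in matrix")
    if set(baseline) & set(candidates):
        raise ValueError("baseline and candidate panels overlap")


# ----------------------------------------------------------------------
# Model 1: cumulative addition in a fixed order
# ----------------------------------------------------------------------

def run_model1(matrix: pd.DataFrame, baseline: list[str],
               candidates_ordered: list[str], labels: np.ndarray,
               criteria: SelectionCriteria | None = None,
               oracle_config: OracleConfig | None = None) -> SelectionResult:
    """Cumulative stepwise addition: candidates are appended in their fixed
    order; a candidate is retained (and persists) iff the expanded panel
    exceeds the accuracy and kappa thresholds and the candidate's own
    importance reaches the importance threshold."""
    criteria = criteria or SelectionCriteria()
    oracle_config = oracle_config or OracleConfig()
    _check_candidates(matrix, baseline, candidates_ordered)
    baseline_metrics = evaluate_panel(matrix, baseline, labels, oracle_config)

    retained: list[str] = []
    records = []
    for cand in candidates_ordered:
        panel = list(baseline) + retained + [cand]
        res = evaluate_panel(matrix, panel, labels, oracle_config)
        imp = float(res.importance_pct[cand])
        keep = (
            res.accuracy > criteria.accuracy_min
            and res.kappa > criteria.kappa_min
            and imp >= criteria.importance_threshold(len(panel))
        )
        if keep:
            retained.append(cand)
        records.append(
            {"marker": cand, "accuracy": res.accuracy, "kappa": res.kappa,
             "importance_pct": imp, "retained": keep}
        )
    per_candidate = pd.DataFrame(records).set_index("marker")
    per_candidate.attrs["baseline"] = list(baseline)
    return SelectionResult(1, retained, per_candidate, baseline_metrics)


# ----------------------------------------------------------------------
# Model 2: independent single-marker addition
# ----------------------------------------------------------------------

def run_model2(matrix: pd.DataFrame, baseline: list[str], candidates: list[str],
               labels: np.ndarray, criteria: SelectionCriteria | None = None,
               oracle_config: OracleConfig | None = None) -> SelectionResult:
    """Independent addition: each candidate is judged on
    ``baseline + {candidate}`` alone, so the retained set does not depend on
    evaluation order."""
    criteria = criteria or SelectionCriteria()
    oracle_config = oracle_config or OracleConfig()
    _check_candidates(matrix, baseline, candidates)
    baseline_metrics = evaluate_panel(matrix, baseline, labels, oracle_config)

    records = []
    retained = []
    for cand in sorted(candidates):
        panel = list(baseline) + [cand]
        res = evaluate_panel(matrix, panel, labels, oracle_config)
        imp = float(res.importance_pct[cand])
        keep = (
            res.accuracy > criteria.accuracy_min
            and res.kappa > criteria.kappa_min
            and imp >= criteria.importance_threshold(len(panel))
        )
        if keep:
            retained.append(cand)
        records.append(
            {"marker": cand, "accuracy": res.accuracy, "kappa": res.kappa,
             "importance_pct": imp, "retained": keep}
        )
    per_candidate = pd.DataFrame(records).set_index("marker")
    per_candidate = per_candidate.loc[list(candidates)]   # original order
    per_candidate.attrs["baseline"] = list(baseline)
    return SelectionResult(2, retained, per_candidate, baseline_metrics)


# ----------------------------------------------------------------------
# Model 3: greedy forward-backward selection
# ----------------------------------------------------------------------

def run_model3(matrix: pd.DataFrame, baseline: list[str], candidates: list[str],
               labels: np.ndarray,
               oracle_config: OracleConfig | None = None) -> SelectionResult:
    """Greedy bidirectional selection driven purely by held-out accuracy.

    Baseline markers are never removable; the forward accuracy trace is
    non-decreasing by construction.  A hard cap of ``2 x |candidates|``
    forward/backward rounds guards against non-termination."""
    oracle_config = oracle_config or OracleConfig()
    # the greedy path is driven by accuracy/kappa only
    oracle_config = replace(oracle_config, compute_importance=False)
    _check_candidates(matrix, baseline, candidates)
    baseline_metrics = evaluate_panel(matrix, baseline, labels, oracle_config)

    selected: list[str] = []
    remaining = sorted(candidates)
    current_acc = baseline_metrics.accuracy
    path: list[tuple[int, str, str, float]] = []
    records: dict[str, dict] = {}
    round_no = 0
    max_rounds = max(2 * len(candidates), 2)

    changed = True
    while changed:
        changed = False
        # forward phase: add best strict improver until none remains
        while remaining:
            best = None
            for cand in remaining:
                res = evaluate_panel(matrix, list(baseline) + selected + [cand],
                                     labels, oracle_config)
                records[cand] = {"accuracy": res.accuracy, "kappa": res.kappa}
                key = (res.accuracy, res.kappa)
                # ties: higher kappa, then lexicographically first marker id
                if res.accuracy > current_acc and (best is None or key > best[0]):
                    best = (key, cand)
            if best is None:
                break
            (_, _), cand = best[0], best[1]
            round_no += 1
            if round_no > max_rounds:
                raise RuntimeError("greedy selection failed to reach a plateau")
            selected.append(cand)
            remaining.remove(cand)
            current_acc = records[cand]["accuracy"]
            path.append((round_no, "add", cand, current_acc))
            changed = True
        # backward phase: drop markers whose removal strictly improves
        for cand in list(selected):
            trial = [m for m in selected if m != cand]
            panel = list(baseline) + trial
            res = evaluate_panel(matrix, panel, labels, oracle_config)
            if res.accuracy > current_acc:
                round_no += 1
                if round_no > max_rounds:
                    raise RuntimeError("greedy selection failed to reach a plateau")
                selected = trial
                remaining.append(cand)
                current_acc = res.accuracy
                path.append((round_no, "remove", cand, current_acc))
                changed = True
        remaining.sort()

    per_candidate = pd.DataFrame.from_dict(records, orient="index")
    if per_candidate.empty:
        per_candidate = pd.DataFrame(columns=["accuracy", "kappa"])
    per_candidate["retained"] = [m in selected for m in per_candidate.index]
    per_candidate.attrs["baseline"] = list(baseline)
    return SelectionResult(3, selected, per_candidate, baseline_metrics, path)


def run_model(model_id: int, matrix: pd.DataFrame, baseline: list[str],
              candidates: list[str], labels: np.ndarray,
              criteria: SelectionCriteria | None = None,
              oracle_config: OracleConfig | None = None) -> SelectionResult:
    if model_id == 1:
        return run_model1(matrix, baseline, candidates, labels, criteria, oracle_config)
    if model_id == 2:
        return run_model2(matrix, baseline, candidates, labels, criteria, oracle_config)
    if model_id == 3:
        return run_model3(matrix, baseline, candidates, labels, oracle_config)
    raise ValueError("model_id must be 1, 2 or 3")


# ----------------------------------------------------------------------
# selection-frequency resampling
# ----------------------------------------------------------------------

def selection_frequency(matrix: pd.DataFrame, baseline: list[str],
                        candidates: list[str], labels: np.ndarray,
                        model_id: int, n_iterations: int = 50,
                        criteria: SelectionCriteria | None = None,
                        oracle_config: OracleConfig | None = None,
                        seed: int = 0) -> FrequencyReport:
    """Per-candidate selection frequency over repeated train/test splits.

    Each iteration draws a fresh stratified split (via an iteration-indexed
    seed).  For models 1 and 2 a candidate counts as selected when its
    panel strictly improves both accuracy and kappa over that iteration's
    baseline (the delta criterion); for model 3 when it survives the full
    greedy forward-backward path.
    """
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    criteria = criteria or SelectionCriteria()
    oracle_config = oracle_config or OracleConfig()
    _check_candidates(matrix, baseline, candidates)

    master = np.random.default_rng(seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=n_iterations)
    per_iteration: list[set[str]] = []
    for it in range(n_iterations):
        # the delta criterion needs accuracy/kappa only
        cfg = replace(oracle_config, seed=int(iter_seeds[it]),
                      compute_importance=False)
        selected: set[str] = set()
        if model_id in (1, 2):
            base = evaluate_panel(matrix, baseline, labels, cfg)
            retained_cum: list[str] = []
            for cand in candidates:
                if model_id == 1:
                    panel = list(baseline) + retained_cum + [cand]
                else:
                    panel = list(baseline) + [cand]
                res = evaluate_panel(matrix, panel, labels, cfg)
                improves = (
                    res.accuracy - base.accuracy > criteria.delta_accuracy_min
                    and res.kappa - base.kappa > criteria.delta_kappa_min
                )
                if improves:
                    selected.add(cand)
                    if model_id == 1:
                        retained_cum.append(cand)
        elif model_id == 3:
            res3 = run_model3(matrix, baseline, candidates, labels, cfg)
            selected = set(res3.retained)
        else:
            raise ValueError("model_id must be 1, 2 or 3")
        per_iteration.append(selected)

    counts = pd.Series(0, index=list(candidates), dtype=float)
    for s in per_iteration:
        for m in s:
            counts[m] += 1
    return FrequencyReport(counts / n_iterations, n_iterations, per_iteration)


# ----------------------------------------------------------------------
# scikit-learn style selector estimators
# ----------------------------------------------------------------------

class BaseRFASelector(BaseEstimator):
    """Shared machinery for the three selection strategies.

    ``fit(X, y)`` takes the preprocessed marker frame and the fixed
    baseline cluster labels; afterwards ``retained_`` lists the selected
    candidates, ``result_`` holds the full trace, and ``transform(X)``
    returns the baseline + retained sub-frame ready for re-clustering.
    """

    model_id: int = 0

    def __init__(self, baseline: list[str] | None = None,
                 candidates: list[str] | None = None,
                 criteria: SelectionCriteria | None = None,
                 oracle_config: OracleConfig | None = None):
        self.baseline = baseline
        self.candidates = candidates
        self.criteria = criteria
        self.oracle_config = oracle_config

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        if self.baseline is None or self.candidates is None:
            raise ValueError("baseline and candidates must be set")
        self.result_ = run_model(
            self.model_id, pd.DataFrame(X), list(self.baseline),
            list(self.candidates), np.asarray(y), self.criteria,
            self.oracle_config,
        )
        self.retained_ = list(self.result_.retained)
        self.panel_ = list(self.baseline) + self.retained_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.panel_]

    def fit_transform(self, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


class CumulativeAdditionSelector(BaseRFASelector):
    """Model 1: fixed-order cumulative addition with threshold retention."""

    model_id = 1


class IndependentAdditionSelector(BaseRFASelector):
    """Model 2: order-free independent single-candidate addition."""

    model_id = 2


class GreedyBidirectionalSelector(BaseRFASelector):
    """Model 3: accuracy-driven greedy forward-backward selection."""

    model_id = 3
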