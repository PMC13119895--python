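"""Bootstrap cluster-stability assessment and cohort-effect diagnostics.

Stability of a clustering solution is measured by resampling participants
with replacement, re-running the identical PCA + Ward pipeline on each
resample, and comparing the resampled assignments with the original ones
using the Adjusted Rand Index (ARI) over the participants drawn in that
iteration.  Cohort (site) effects are probed with a chi-squared test on
the cluster x cohort table and per-component analyses of variance of the
PCA scores on cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterSolution, PCAWardClusterer


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions of the same items
    (1 = identical up to label permutation, ~0 = random)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("partitions must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


@dataclass
class StabilityReport:
    ari_values: list[float]
    k_values: list[int]
    n_requested: int
    n_valid: int
    n_failed: int
    panel_fingerprint: str

    @property
    def summary(self) -> dict[str, float]:
        arr = np.asarray(self.ari_values, dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        return {
            "median": float(np.median(arr)),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
            "iqr": float(q3 - q1),
        }


def bootstrap_cluster_stability(matrix: pd.DataFrame, panel: list[str],
                                original: ClusterSolution,
                                n_boot: int = 500, seed: int = 0,
                                pipeline: PCAWardClusterer | None = None,
                                ) -> StabilityReport:
    """Bootstrap re-clustering stability of ``original`` on ``matrix[panel]``.

    Each iteration resamples rows with replacement to the original size,
    re-runs the pipeline (same parameters as the original solution) and
    computes the ARI between the resampled assignments, collapsed to one
    label per unique drawn participant (first occurrence), and the original
    assignments restricted to those participants.  Iterations that raise
    (degenerate PCA, constant marker, undefined criterion) are counted as
    failures, not errors, unless at least half of them fail.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pipeline = pipeline or PCAWardClusterer()
    sub = matrix[list(panel)]
    n = len(sub)
    orig = original.assignments.to_numpy()
    rng = np.random.default_rng(seed)
    ari_values: list[float] = []
    k_values: list[int] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = PCAWardClusterer(**pipeline.get_params())
            labels = est.fit_predict(sub.iloc[idx])
            first = pd.Series(np.arange(n)).groupby(pd.Series(idx)).first()
            uniq = first.index.to_numpy()
            boot_labels = labels[first.to_numpy()]
            ari_values.append(adjusted_rand_index(orig[uniq], boot_labels))
            k_values.append(est.k_)
        except Exception:
            n_failed += 1
    if n_failed / n_boot >= 0.5:
        raise RuntimeError(
            f"clustering failed on {n_failed}/{n_boot} bootstrap resamples; "
            "the pipeline is unstable on this panel"
        )
    return StabilityReport(
        ari_values=ari_values,
        k_values=k_values,
        n_requested=n_boot,
        n_valid=len(ari_values),
        n_failed=n_failed,
        panel_fingerprint=pipeline.fingerprint(),
    )


@dataclass
class CohortEffectReport:
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    contingency: pd.DataFrame
    anova_F: list[float]
    anova_p: list[float]
    variance_fraction: list[float]


def cohort_effect_tests(solution: ClusterSolution, cohorts: pd.Series,
                        ) -> CohortEffectReport:
    """Chi-squared test of cluster x cohort association plus one-way ANOVA
    of each retained principal-component score on cohort (with the
    between-cohort variance fraction of each component)."""
    cohorts = pd.Series(cohorts)
    if cohorts.nunique() < 2:
        raise ValueError("need at least 2 cohorts")
    assign = solution.assignments
    table = pd.crosstab(assign, cohorts.loc[assign.index])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"empty cohort or cluster in contingency table:\n{table}")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)

    groups_idx = [np.flatnonzero(cohorts.loc[assign.index].to_numpy() == c)
                  for c in table.columns]
    anova_F, anova_p, var_frac = [], [], []
    for j in range(solution.n_components):
        comp = solution.scores[:, j]
        samples = [comp[g] for g in groups_idx]
        F, pv = stats.f_oneway(*samples)
        grand = comp.mean()
        ss_between = sum(len(g) * (comp[g].mean() - grand) ** 2 for g in groups_idx)
        ss_total = float(((comp - grand) ** 2).sum())
        anova_F.append(float(F))
        anova_p.append(float(pv))
        var_frac.append(ss_between / ss_total if ss_total > 0 else 0.0)
    return CohortEffectReport(
        chi2_stat=float(chi2), chi2_df=int(df), chi2_p=float(p),
        contingency=table, anova_F=anova_F, anova_p=anova_p,
        variance_fraction=var_frac,
    )
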