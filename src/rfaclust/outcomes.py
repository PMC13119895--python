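"""Cluster-outcome association modelling.

Binary outcomes (the composite vascular phenotype and its components) are
modelled by logistic regression with the uninflamed cluster as reference;
odds ratios carry profile-likelihood 95 % confidence intervals (the
likelihood-ratio statistic for each cluster coefficient is inverted by
bisection).  Adjusted models add age, sex, smoking history (collapsed to
ever vs never), BMI and dyslipidaemia.  Robustness is probed with a
stratified bootstrap that resamples cases and controls separately so the
outcome prevalence is preserved.  The continuous 10-year risk score is
compared across clusters as a fold change from a log-linear model, and
with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cluster import VTestProfile

CHI2_95 = float(stats.chi2.ppf(0.95, df=1))
SEPARATION_BOUND = 15.0
ADJUST_COVARIATES = ("age", "sex", "bmi", "smoking_ever", "dyslipidaemia")


@dataclass
class AssociationResult:
    outcome: str
    estimates: pd.DataFrame       # per non-reference cluster: estimate, ci_low, ci_high, p
    adjusted: bool
    covariates: list[str]
    reference: int
    kind: str = "odds_ratio"      # or "fold_change"

    def __post_init__(self) -> None:
        est = self.estimates
        bad = (est["ci_low"] >= est["estimate"]) | (est["estimate"] >= est["ci_high"])
        if bad.any():
            raise ValueError("confidence bounds must bracket the estimate")


@dataclass
class BootstrapORReport:
    outcome: str
    summary: pd.DataFrame     # per cluster: median_or, ci_low, ci_high, prop_or_gt_1
    n_iterations: int
    n_dropped: int
    draws: pd.DataFrame       # iterations x clusters OR draws


def _design(participants: pd.DataFrame, assignments: pd.Series, reference: int,
            covariates: list[str] | None) -> tuple[pd.DataFrame, list[str]]:
    df = participants.loc[assignments.index].copy()
    df["cluster"] = assignments
    clusters = sorted(df["cluster"].unique())
    if reference not in clusters:
        raise ValueError(f"reference cluster {reference} absent from assignments")
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    cluster_cols = []
    for c in clusters:
        if c == reference:
            continue
        col = f"cluster_{c}"
        X[col] = (df["cluster"] == c).astype(float)
        cluster_cols.append(col)
    if covariates:
        for cov in covariates:
            if cov == "smoking_ever":
                X[cov] = (df["smoking"].isin(["current", "ex"])).astype(float)
            else:
                X[cov] = pd.to_numeric(df[cov], errors="raise")
    return X, cluster_cols


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except Exception as exc:
        if "Singular" in str(exc) or "separation" in str(exc).lower():
            raise RuntimeError(
                "separation or singular design in logistic fit; "
                "consider a penalised fallback"
            ) from exc
        raise
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge within 100 iterations")
    if np.any(np.abs(fit.params) > SEPARATION_BOUND):
        raise RuntimeError(
            "separation detected (|coefficient| > 15); consider a penalised fit"
        )
    return fit


def _profile_ci(y: np.ndarray, X: pd.DataFrame, fit, col: str,
                tol: float = 1e-6) -> tuple[float, float]:
    """Invert the likelihood-ratio statistic for one coefficient at the
    chi-squared(1) 95 % quantile, by bisection on the coefficient scale."""
    llmax = fit.llf
    beta_hat = float(fit.params[col])
    se = float(fit.bse[col])
    others = [c for c in X.columns if c != col]
    x_col = X[col].to_numpy()
    X_rest = X[others]

    def deviance(b: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = sm.Logit(y, X_rest, offset=b * x_col).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0
            )
        return 2.0 * (llmax - sub.llf) - CHI2_95

    def solve(direction: float) -> float:
        step = max(se, 1e-3)
        lo, hi = beta_hat, beta_hat + direction * step
        for _ in range(200):
            if deviance(hi) >= 0:
                break
            lo = hi
            hi = hi + direction * step
            step *= 1.5
        else:
            raise RuntimeError("profile-likelihood bound not bracketed")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if abs(hi - lo) < tol:
                return mid
            if deviance(mid) >= 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    return solve(-1.0), solve(+1.0)


def fit_logistic_profile(participants: pd.DataFrame, assignments: pd.Series,
                         outcome: str = "outcome_cvp",
                         covariates: list[str] | None = None,
                         reference: int = 1,
                         profile: bool = True) -> AssociationResult:
    """Logistic model of a binary outcome on cluster membership.

    Returns odds ratios per non-reference cluster with 95 % CIs, by
    default from the profile likelihood (set ``profile=False`` for Wald
    intervals, e.g. inside bootstrap loops), and Wald p-values.
    """
    y = pd.to_numeric(participants.loc[assignments.index, outcome]).to_numpy()
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} must be binary with both classes present")
    X, cluster_cols = _design(participants, assignments, reference, covariates)
    fit = _fit_logit(y, X)

    rows = []
    for col in cluster_cols:
        beta = float(fit.params[col])
        if profile:
            lo, hi = _profile_ci(y, X, fit, col)
        else:
            se = float(fit.bse[col])
            lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        rows.append(
            {"cluster": int(col.split("_")[1]), "estimate": float(np.exp(beta)),
             "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
             "p": float(fit.pvalues[col])}
        )
    return AssociationResult(
        outcome=outcome,
        estimates=pd.DataFrame(rows).set_index("cluster"),
        adjusted=bool(covariates),
        covariates=list(covariates or []),
        reference=reference,
    )


def stratified_bootstrap_or(participants: pd.DataFrame, assignments: pd.Series,
                            outcome: str = "outcome_cvp",
                            covariates: list[str] | None = None,
                            n_iterations: int = 1000, seed: int = 0,
                            reference: int = 1) -> BootstrapORReport:
    """Bootstrap OR distributions preserving outcome prevalence.

    Cases and controls are resampled with replacement within their own
    stratum (keeping stratum sizes), the adjusted model is refitted with
    Wald machinery, and per-cluster ORs are collected.  Iterations hitting
    separation or non-convergence are dropped and counted; more than 20 %
    drops is an error.
    """
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    y_all = pd.to_numeric(participants.loc[assignments.index, outcome])
    case_ids = y_all.index[y_all == 1]
    ctrl_ids = y_all.index[y_all == 0]
    rng = np.random.default_rng(seed)
    draws = []
    n_dropped = 0
    for _ in range(n_iterations):
        ids = np.concatenate([
            rng.choice(case_ids, size=len(case_ids), replace=True),
            rng.choice(ctrl_ids, size=len(ctrl_ids), replace=True),
        ])
        boot_assign = pd.Series(
            assignments.loc[ids].to_numpy(),
            index=pd.RangeIndex(len(ids)), name="cluster",
        )
        boot_part = participants.loc[ids].reset_index(drop=True)
        try:
            res = fit_logistic_profile(
                boot_part, boot_assign, outcome=outcome, covariates=covariates,
                reference=reference, profile=False,
            )
            draws.append(res.estimates["estimate"])
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_dropped += 1
    if n_dropped > 0.2 * n_iterations:
        raise RuntimeError(
            f"{n_dropped}/{n_iterations} bootstrap refits failed; "
            "estimates would be unreliable"
        )
    draw_df = pd.DataFrame(draws).reset_index(drop=True)
    summary = pd.DataFrame(
        {
            "median_or": draw_df.median(),
            "ci_low": draw_df.quantile(0.025),
            "ci_high": draw_df.quantile(0.975),
            "prop_or_gt_1": (draw_df > 1.0).mean(),
        }
    )
    return BootstrapORReport(
        outcome=outcome, summary=summary,
        n_iterations=n_iterations, n_dropped=n_dropped, draws=draw_df,
    )


def fold_change_continuous(participants: pd.DataFrame, assignments: pd.Series,
                           outcome: str = "ascvd",
                           reference: int = 1) -> AssociationResult:
    """Fold change of a positive continuous outcome across clusters.

    Ordinary least squares of ``log(outcome)`` on cluster indicators;
    fold change = exp(coefficient) with exponentiated normal-theory 95 %
    CIs.  Left unadjusted by design when the outcome is itself a composite
    risk score."""
    y_raw = pd.to_numeric(participants.loc[assignments.index, outcome])
    if (y_raw <= 0).any():
        bad = list(y_raw.index[y_raw <= 0])[:5]
        raise ValueError(f"nonpositive outcome values for participants {bad}")
    X, cluster_cols = _design(participants, assignments, reference, covariates=None)
    fit = sm.OLS(np.log(y_raw.to_numpy()), X).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for col in cluster_cols:
        rows.append(
            {"cluster": int(col.split("_")[1]),
             "estimate": float(np.exp(fit.params[col])),
             "ci_low": float(np.exp(ci.loc[col, 0])),
             "ci_high": float(np.exp(ci.loc[col, 1])),
             "p": float(fit.pvalues[col])}
        )
    return AssociationResult(
        outcome=outcome, estimates=pd.DataFrame(rows).set_index("cluster"),
        adjusted=False, covariates=[], reference=reference, kind="fold_change",
    )


def compare_clusters_nonparametric(participants: pd.DataFrame,
                                   assignments: pd.Series,
                                   outcome: str = "ascvd",
                                   ) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a continuous outcome across clusters
    (tie-corrected; all-tied data returns statistic 0 and p = 1)."""
    y = pd.to_numeric(participants.loc[assignments.index, outcome]).to_numpy()
    groups = [y[assignments.to_numpy() == g] for g in np.unique(assignments)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 nonempty groups")
    if np.ptp(y) == 0:  # every observation tied: no evidence by convention
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def identify_uninflamed(vtest: VTestProfile, marker_meta: pd.DataFrame,
                        pathway: str = "Systemic Inflammation") -> int:
    """Pick the reference ("uninflamed") cluster: the one with the lowest
    mean v statistic over the systemic-inflammation pathway markers."""
    markers = list(marker_meta.index[marker_meta["pathway"] == pathway])
    table = vtest.table
    sub = table[table["marker"].isin(markers)]
    if sub.empty:
        sub = table  # no pathway annotation: fall back to all markers
    means = sub.groupby("cluster")["v"].mean()
    return int(means.idxmin())
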