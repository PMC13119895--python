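"""Data preparation: imputation, batch correction, log transform, scaling.

The canonical chain for assay concentrations is

    impute -> log -> ComBat -> scale

Chained-equation imputation uses predictive mean matching (PMM) for
continuous variables and single-tree CART draws for categorical ones.
Batch correction is the parametric empirical-Bayes location/scale model
(ComBat): per-marker batch effects are estimated, shrunk towards common
priors (normal for location, inverse-gamma for scale, moment-matched
hyperparameters) and removed.  Markers are then log-transformed and scaled
to zero mean / unit variance so no marker dominates the PCA by sheer
intrinsic variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.tree import DecisionTreeClassifier

from .dataset import BiomarkerDataset

MAX_MISSING_FRACTION = 0.10


@dataclass
class PreprocessReport:
    """Record of what each preprocessing step did, sufficient to re-apply
    the identical transform to held-out rows."""

    imputed_cell_count: pd.Series | None = None
    batch_means_before: pd.DataFrame | None = None
    batch_means_after: pd.DataFrame | None = None
    log_offsets: pd.Series | None = None
    centers: pd.Series | None = None
    scales: pd.Series | None = None
    extra: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# chained-equation imputation with PMM / CART
# ----------------------------------------------------------------------

def _pmm_draw(y: np.ndarray, X: np.ndarray, miss: np.ndarray, k_donors: int,
              rng: np.random.Generator) -> np.ndarray:
    """PMM: regress y on X over observed rows, match each missing row to the
    ``k_donors`` observed rows with closest predicted mean, draw one donor's
    observed value."""
    obs = ~miss
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
    pred_obs = Xo @ beta
    Xm = np.column_stack([np.ones(miss.sum()), X[miss]])
    pred_mis = Xm @ beta
    y_obs = y[obs]
    k = min(k_donors, len(y_obs))
    out = np.empty(miss.sum())
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        donors = np.argpartition(d, k - 1)[:k]
        out[i] = y_obs[rng.choice(donors)]
    return out


def _cart_draw(y: np.ndarray, X: np.ndarray, miss: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """CART: fit a classification tree on observed rows, then for each
    missing row draw uniformly from the observed values in its leaf."""
    obs = ~miss
    tree = DecisionTreeClassifier(
        min_samples_leaf=5, random_state=int(rng.integers(0, 2**31 - 1))
    )
    tree.fit(X[obs], y[obs])
    leaves_obs = tree.apply(X[obs])
    leaves_mis = tree.apply(X[miss])
    y_obs = y[obs]
    out = np.empty(miss.sum(), dtype=y.dtype)
    for i, leaf in enumerate(leaves_mis):
        pool = y_obs[leaves_obs == leaf]
        out[i] = pool[rng.integers(len(pool))] if len(pool) else y_obs[rng.integers(len(y_obs))]
    return out


def _encode_predictors(frame: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [c for c in frame.columns if c != exclude]
    enc = pd.get_dummies(frame[cols], dtype=float)
    return enc.to_numpy(dtype=float)


def chained_impute(frame: pd.DataFrame, m: int = 5, iterations: int = 50,
                   k_donors: int = 5, seed: int = 0) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations on a mixed-type frame.

    Numeric columns are imputed by PMM, object/categorical columns by CART.
    Returns ``m`` completed copies; observed cells are preserved bitwise.
    """
    if m < 1 or iterations < 1:
        raise ValueError("m and iterations must be >= 1")
    miss = frame.isna()
    incomplete = [c for c in frame.columns if miss[c].any()]
    for c in incomplete:
        frac = miss[c].mean()
        if frac >= MAX_MISSING_FRACTION:
            raise ValueError(
                f"column {c!r} has {frac:.1%} missing values; only columns with "
                f"less than {MAX_MISSING_FRACTION:.0%} missing data are imputed"
            )
        if miss[c].all():
            raise ValueError(f"column {c!r} is entirely missing")
    if not incomplete:
        return [frame.copy() for _ in range(m)]

    completions = []
    master = np.random.default_rng(seed)
    for _ in range(m):
        rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        work = frame.copy()
        # start from random draws of observed values
        for c in incomplete:
            pool = frame.loc[~miss[c], c].to_numpy()
            work.loc[miss[c], c] = pool[rng.integers(len(pool), size=int(miss[c].sum()))]
        for _ in range(iterations):
            for c in incomplete:
                X = _encode_predictors(work, exclude=c)
                col_miss = miss[c].to_numpy()
                y = work[c].to_numpy()
                if pd.api.types.is_numeric_dtype(frame[c]):
                    work.loc[col_miss, c] = _pmm_draw(
                        y.astype(float), X, col_miss, k_donors, rng
                    )
                else:
                    work.loc[col_miss, c] = _cart_draw(y, X, col_miss, rng)
        completions.append(work)
    return completions


def multiple_impute(dataset: BiomarkerDataset, m: int = 5, iterations: int = 50,
                    k_donors: int = 5, seed: int = 0,
                    covariates: tuple[str, ...] = ("bmi", "smoking"),
                    ) -> tuple[list[BiomarkerDataset], PreprocessReport]:
    """Impute missing marker values (and clinical covariates) by chained
    equations with PMM/CART; defaults m=5 completions, 50 cycles each.

    Markers and covariates are imputed jointly: each incomplete variable is
    regressed on all others, cycling ``iterations`` times per completion.
    """
    cov = [c for c in covariates if c in dataset.participant_meta.columns]
    joint = pd.concat([dataset.values, dataset.participant_meta[cov]], axis=1)
    completions = chained_impute(joint, m=m, iterations=iterations,
                                 k_donors=k_donors, seed=seed)
    report = PreprocessReport(imputed_cell_count=dataset.values.isna().sum())
    out = []
    for comp in completions:
        values = comp[dataset.values.columns].astype(float)
        pmeta = dataset.participant_meta.copy()
        for c in cov:
            pmeta[c] = comp[c]
        out.append(BiomarkerDataset(values, dataset.marker_meta.copy(), pmeta))
    return out, report


# ----------------------------------------------------------------------
# ComBat empirical-Bayes batch correction
# ----------------------------------------------------------------------

class ComBat(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardises each marker, estimates per-batch location and scale,
    shrinks them towards cross-marker priors (normal / inverse-gamma with
    moment-matched hyperparameters), removes the shrunken effects and
    restores the overall location/scale.  Expects log-scale values.

    Fitted attributes: ``gamma_star_``, ``delta_star_`` (shrunken batch
    effects), ``grand_mean_``, ``pooled_var_``, ``batches_``.
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def fit_transform(self, X, batch, y=None):  # noqa: D102 - sklearn idiom
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        levels, codes = np.unique(batch, return_inverse=True)
        counts = np.bincount(codes)
        if len(levels) == 1:
            warnings.warn("single batch: ComBat is the identity", stacklevel=2)
            self.batches_ = levels
            return X.copy()
        if counts.min() < 2:
            small = levels[counts < 2]
            raise ValueError(f"batches with fewer than 2 participants: {list(small)}")

        n, p = X.shape
        G = len(levels)
        # per-batch means, grand mean weighted by batch size
        B = np.vstack([X[codes == g].mean(axis=0) for g in range(G)])  # G x p
        grand = (counts / n) @ B
        resid = X - B[codes]
        pooled_var = (resid**2).sum(axis=0) / n
        pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
        s = (X - grand) / np.sqrt(pooled_var)

        gamma_hat = np.vstack([s[codes == g].mean(axis=0) for g in range(G)])
        delta_hat = np.vstack([s[codes == g].var(axis=0, ddof=1) for g in range(G)])

        gamma_bar = gamma_hat.mean(axis=1)          # per batch, over markers
        t2 = gamma_hat.var(axis=1, ddof=1)
        d_mean = delta_hat.mean(axis=1)
        d_var = delta_hat.var(axis=1, ddof=1)
        d_var = np.where(d_var <= 0, 1e-12, d_var)
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for g in range(G):
            n_g = counts[g]
            g_old = gamma_hat[g].copy()
            d_old = delta_hat[g].copy()
            for _ in range(self.max_iter):
                g_new = (t2[g] * n_g * gamma_hat[g] + d_old * gamma_bar[g]) / (
                    t2[g] * n_g + d_old
                )
                sum2 = ((s[codes == g] - g_new) ** 2).sum(axis=0)
                d_new = (0.5 * sum2 + b_prior[g]) / (n_g / 2.0 + a_prior[g] - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                    np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
                )
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            gamma_star[g] = g_old
            delta_star[g] = d_old

        adj = (s - gamma_star[codes]) / np.sqrt(delta_star[codes])
        out = adj * np.sqrt(pooled_var) + grand

        self.batches_ = levels
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.grand_mean_ = grand
        self.pooled_var_ = pooled_var
        return out


def combat_adjust(dataset: BiomarkerDataset,
                  ) -> tuple[BiomarkerDataset, PreprocessReport]:
    """Remove plate/batch effects from the marker matrix (log-scale values)
    via parametric empirical-Bayes adjustment."""
    batch = dataset.participant_meta["batch"]
    values = dataset.values

    def _batch_means(mat: pd.DataFrame) -> pd.DataFrame:
        return mat.groupby(batch).mean()

    before = _batch_means(values)
    cb = ComBat()
    adjusted = cb.fit_transform(values.to_numpy(), batch.to_numpy())
    out_values = pd.DataFrame(adjusted, index=values.index, columns=values.columns)
    report = PreprocessReport(
        batch_means_before=before, batch_means_after=_batch_means(out_values)
    )
    return dataset.with_values(out_values), report


# ----------------------------------------------------------------------
# log transform and unit-variance scaling
# ----------------------------------------------------------------------

class LogScaleTransformer(BaseEstimator, TransformerMixin):
    """Per-marker natural-log transform followed by standardisation.

    The log offset is 0 when all values of a marker are strictly positive,
    otherwise half the smallest positive value (zero-tolerant and
    deterministic).  ``with_log`` / ``with_scale`` allow running the two
    halves separately, e.g. when batch correction sits between them.
    """

    def __init__(self, with_log: bool = True, with_scale: bool = True):
        self.with_log = with_log
        self.with_scale = with_scale

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if self.with_log:
            if (X < 0).any().any():
                raise ValueError("negative concentrations cannot be log-transformed")
            offsets = {}
            for c in X.columns:
                col = X[c]
                offsets[c] = 0.0 if (col > 0).all() else float(col[col > 0].min()) / 2.0
            self.offsets_ = pd.Series(offsets)
            work = np.log(X + self.offsets_)
        else:
            self.offsets_ = pd.Series(0.0, index=X.columns)
            work = X.astype(float)
        self.centers_ = work.mean()
        self.scales_ = work.std(ddof=0)
        if self.with_scale and (self.scales_ <= 0).any():
            bad = list(self.scales_.index[self.scales_ <= 0])
            raise ValueError(f"constant markers cannot be scaled: {bad}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        work = np.log(X + self.offsets_) if self.with_log else X.astype(float)
        if self.with_scale:
            work = (work - self.centers_) / self.scales_
        return work

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        work = pd.DataFrame(X)
        if self.with_scale:
            work = work * self.scales_ + self.centers_
        if self.with_log:
            work = np.exp(work) - self.offsets_
        return work


def log_scale_transform(dataset: BiomarkerDataset,
                        ) -> tuple[BiomarkerDataset, PreprocessReport]:
    """Log-transform and scale every marker to mean 0 / SD 1."""
    tf = LogScaleTransformer()
    out = tf.fit(dataset.values).transform(dataset.values)
    report = PreprocessReport(
        log_offsets=tf.offsets_, centers=tf.centers_, scales=tf.scales_
    )
    return dataset.with_values(out), report


# ----------------------------------------------------------------------
# full chain
# ----------------------------------------------------------------------

def preprocess(dataset: BiomarkerDataset, m: int = 5, iterations: int = 50,
               k_donors: int = 5, seed: int = 0, completion: str | int = "first",
               ) -> tuple[BiomarkerDataset, PreprocessReport]:
    """Run the full chain impute -> log -> ComBat -> scale.

    ``completion`` picks which imputation feeds the downstream analysis:
    ``"first"`` (default), ``"average"`` (cell-wise mean of the m completed
    marker matrices) or an integer index.
    """
    report = PreprocessReport()
    if dataset.values.isna().any().any() or dataset.participant_meta[
        [c for c in ("bmi", "smoking") if c in dataset.participant_meta.columns]
    ].isna().any().any():
        completions, rep_i = multiple_impute(
            dataset, m=m, iterations=iterations, k_donors=k_donors, seed=seed
        )
        report.imputed_cell_count = rep_i.imputed_cell_count
        if completion == "first":
            ds = completions[0]
        elif completion == "average":
            avg = sum(c.values for c in completions) / len(completions)
            ds = completions[0].with_values(avg)
        else:
            ds = completions[int(completion)]
    else:
        ds = dataset.copy()

    logger = LogScaleTransformer(with_log=True, with_scale=False)
    logged = ds.with_values(logger.fit(ds.values).transform(ds.values))
    report.log_offsets = logger.offsets_

    n_batches = ds.participant_meta["batch"].nunique()
    if n_batches >= 2:
        corrected, rep_c = combat_adjust(logged)
        report.batch_means_before = rep_c.batch_means_before
        report.batch_means_after = rep_c.batch_means_after
    else:
        corrected = logged

    scaler = LogScaleTransformer(with_log=False, with_scale=True)
    scaled = corrected.with_values(
        scaler.fit(corrected.values).transform(corrected.values)
    )
    report.centers = scaler.centers_
    report.scales = scaler.scales_
    return scaled, report
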