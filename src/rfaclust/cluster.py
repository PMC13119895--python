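"""PCA + Ward hierarchical clustering with automatic cluster-count selection.

The pipeline mirrors hierarchical clustering on principal components
(HCPC): standardised markers are projected onto the principal components
that jointly explain at least a target fraction of total variance
(default 70 %), the scores are clustered with Ward's minimum-variance
method on squared Euclidean distances, and the number of clusters is the
one maximising the relative between-cluster inertia gain
``delta(k) / delta(k+1)`` over a bounded search range.  Cluster profiles
are characterised by the v-test: the standardised difference between a
cluster's marker mean and the overall mean.

Merge heights are expressed directly as within-inertia gains (the Ward
criterion), so the sum of all merge heights equals the total inertia of
the score matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA


# ----------------------------------------------------------------------
# elemental operations
# ----------------------------------------------------------------------

def pca_reduce(matrix: np.ndarray | pd.DataFrame, variance_threshold: float = 0.70,
               n_components: int | None = None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a column-standardised matrix onto its leading components.

    Retains the smallest prefix of components whose cumulative explained
    variance reaches ``variance_threshold`` (or exactly ``n_components``
    when given).  Component signs are fixed so the largest-|loading| entry
    of each component is positive.

    Returns ``(scores, loadings, variance_explained)`` with loadings of
    shape (markers, components).
    """
    X = np.asarray(matrix, dtype=float)
    if n_components is None and not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    pca = PCA(svd_solver="full")
    scores_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if ratios[0] == 0 or not np.isfinite(ratios).all():
        raise ValueError("degenerate matrix: no variance to decompose")
    if n_components is not None:
        ncp = int(n_components)
        if not (1 <= ncp <= len(ratios)):
            raise ValueError("n_components out of range")
    else:
        ncp = int(np.searchsorted(np.cumsum(ratios), variance_threshold - 1e-12) + 1)
        ncp = min(ncp, len(ratios))
    loadings = pca.components_[:ncp].T.copy()          # markers x components
    scores = scores_full[:, :ncp].copy()
    for j in range(ncp):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, ratios[:ncp].copy()


def ward_linkage(scores: np.ndarray) -> np.ndarray:
    """Agglomerative Ward merge history on squared Euclidean distances.

    Returns a linkage matrix in scipy layout whose third column holds the
    Ward criterion value of each merge, i.e. the increase in total
    within-cluster inertia.  Heights are non-decreasing.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to build a tree")
    if not np.isfinite(X).all():
        raise ValueError("scores must be finite")
    Z = hierarchy.linkage(X, method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2 / 2.0      # Euclidean merge distance -> inertia gain
    return Z


def choose_k_inertia(linkage_tree: np.ndarray, k_min: int = 2, k_max: int = 6,
                     ) -> tuple[int, dict[int, float], np.ndarray]:
    """Pick the cluster count maximising the relative inertia-gain ratio.

    ``delta(k)`` is the between-cluster inertia gained by splitting k-1
    clusters into k (the height of the corresponding merge).  The chosen k
    maximises ``delta(k)/delta(k+1)`` over ``[k_min, k_max]``, ties broken
    toward smaller k.  Returns ``(k, ratios, assignments)`` with cluster
    labels 1..k renumbered by decreasing cluster size.
    """
    Z = np.asarray(linkage_tree, dtype=float)
    n = Z.shape[0] + 1
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(f"need 2 <= k_min <= k_max <= {n - 1}")
    heights = Z[:, 2]

    def delta(k: int) -> float:
        # merge number n-k+1 (1-based) takes k clusters down to k-1
        return float(heights[n - k])

    ratios: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        num, den = delta(k), delta(k + 1)
        if den > 0:
            ratios[k] = num / den
        else:
            ratios[k] = np.inf if num > 0 else 0.0
    best_k = max(ratios, key=lambda k: (ratios[k], -k))
    raw = hierarchy.fcluster(Z, t=best_k, criterion="maxclust")
    assignments = _relabel_by_size(raw)
    return best_k, ratios, assignments


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by decreasing size (ties: first seen)."""
    vals, counts = np.unique(labels, return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.asarray([mapping[v] for v in labels])


@dataclass
class VTestProfile:
    """Cluster characterisation table.

    ``table`` has one row per (cluster, marker): the v statistic, its
    significance at the configured quantile threshold, the direction
    (elevated / suppressed) and the within-cluster rank by |v|.
    """

    table: pd.DataFrame
    alpha: float

    def ranked_markers(self, cluster: int, significant_only: bool = True) -> pd.DataFrame:
        sub = self.table[self.table["cluster"] == cluster]
        if significant_only:
            sub = sub[sub["significant"]]
        return sub.sort_values("rank")


def vtest_characterize(matrix: pd.DataFrame, assignments: np.ndarray,
                       alpha: float = 0.05) -> VTestProfile:
    """v-test per (cluster, marker): standardised deviation of the cluster
    mean from the overall mean.

    For cluster g of size ``n_g`` out of ``N`` participants and a marker
    with overall mean ``x̄`` and population variance ``s²``::

        v = (x̄_g − x̄) / sqrt( (s²/n_g) · (N − n_g)/(N − 1) )

    Significant when ``|v|`` exceeds the standard normal quantile at
    ``alpha`` (two-sided).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    X = pd.DataFrame(matrix)
    labels = np.asarray(assignments)
    N = len(X)
    if len(labels) != N:
        raise ValueError("assignments length must match matrix rows")
    overall_mean = X.mean(axis=0)
    s2 = X.var(axis=0, ddof=0)
    threshold = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for g in np.unique(labels):
        idx = labels == g
        n_g = int(idx.sum())
        if n_g == N:
            raise ValueError(
                "a cluster containing every participant has an undefined v-test"
            )
        denom = np.sqrt((s2 / n_g) * (N - n_g) / (N - 1))
        v = (X.loc[idx].mean(axis=0) - overall_mean) / denom
        sub = pd.DataFrame(
            {
                "cluster": g,
                "marker": X.columns,
                "v": v.to_numpy(),
                "significant": np.abs(v.to_numpy()) > threshold,
                "direction": np.where(v.to_numpy() >= 0, "elevated", "suppressed"),
            }
        )
        sub["rank"] = (-sub["v"].abs()).rank(method="first").astype(int)
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    return VTestProfile(table=table, alpha=alpha)


# ----------------------------------------------------------------------
# the reusable pipeline object
# ----------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Result of one PCA + Ward clustering run."""

    panel: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    n_components: int
    linkage_tree: np.ndarray
    k: int
    assignments: pd.Series            # participant id -> label 1..k
    inertia_gain_ratios: dict[int, float]
    config_fingerprint: str
    vtest: VTestProfile | None = None

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


class PCAWardClusterer(BaseEstimator, ClusterMixin):
    """PCA reduction followed by Ward clustering with automatic k.

    Parameters
    ----------
    variance_threshold : float
        Minimum cumulative explained-variance fraction of the retained
        components (default 0.70).
    n_components : int, optional
        Retain exactly this many components instead of using the variance
        threshold.
    k_min, k_max : int
        Search range for the cluster count (default [2, 6]).
    k : int, optional
        Force the cluster count, bypassing the inertia-gain criterion
        (used by bootstrap replications that fix k).
    alpha : float
        Two-sided significance level of the v-test profile.

    The same estimator (identical parameters, hence identical
    ``fingerprint()``) is reused for the baseline panel and every post-RFA
    re-clustering.
    """

    def __init__(self, variance_threshold: float = 0.70,
                 n_components: int | None = None, k_min: int = 2, k_max: int = 6,
                 k: int | None = None, alpha: float = 0.05):
        self.variance_threshold = variance_threshold
        self.n_components = n_components
        self.k_min = k_min
        self.k_max = k_max
        self.k = k
        self.alpha = alpha

    def fingerprint(self) -> str:
        payload = json.dumps(self.get_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        scores, loadings, var_exp = pca_reduce(
            X, self.variance_threshold, self.n_components
        )
        tree = ward_linkage(scores)
        if self.k is not None:
            raw = hierarchy.fcluster(tree, t=self.k, criterion="maxclust")
            labels = _relabel_by_size(raw)
            k, ratios = self.k, {}
        else:
            k, ratios, labels = choose_k_inertia(tree, self.k_min, self.k_max)
        self.scores_ = scores
        self.loadings_ = loadings
        self.variance_explained_ = var_exp
        self.n_components_ = scores.shape[1]
        self.linkage_tree_ = tree
        self.k_ = k
        self.inertia_gain_ratios_ = ratios
        self.labels_ = labels
        self._index = X.index
        self._columns = list(X.columns)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def solution(self, X: pd.DataFrame | None = None,
                 with_vtest: bool = True) -> ClusterSolution:
        """Package fitted state as a :class:`ClusterSolution`.

        When ``X`` is given (the standardised matrix used for fitting) a
        v-test profile is attached.
        """
        vt = None
        if with_vtest and X is not None:
            vt = vtest_characterize(X, self.labels_, self.alpha)
        return ClusterSolution(
            panel=self._columns,
            scores=self.scores_,
            loadings=self.loadings_,
            variance_explained=self.variance_explained_,
            n_components=self.n_components_,
            linkage_tree=self.linkage_tree_,
            k=self.k_,
            assignments=pd.Series(self.labels_, index=self._index, name="cluster"),
            inertia_gain_ratios=self.inertia_gain_ratios_,
            config_fingerprint=self.fingerprint(),
            vtest=vt,
        )


def cluster_panel(matrix: pd.DataFrame, panel: list[str] | None = None,
                  **params) -> ClusterSolution:
    """Convenience wrapper: cluster ``matrix[panel]`` with default settings."""
    sub = matrix if panel is None else matrix[panel]
    est = PCAWardClusterer(**params)
    est.fit(sub)
    return est.solution(sub)
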