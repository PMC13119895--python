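"""Synthetic biomarker-cohort generator.

Emulates a multi-site inflammatory-biomarker study: a few hundred
participants measured on a ~55-marker immunoassay panel with

* ``k_true`` latent inflammatory clusters with per-cluster mean shifts on a
  subset of markers (in SD units on the log scale),
* block-correlated markers within functional pathways,
* multiplicative plate (batch) effects,
* cohort/site labels,
* clinical covariates and a binary composite vascular phenotype whose
  log-odds depend on the latent cluster and on the covariates,
* a continuous 10-year cardiovascular risk score in (0, 100),
* optional missing-completely-at-random cells (at most 10 % per marker,
  mirroring the imputation eligibility rule used downstream).

Concentrations are generated on the log scale and exponentiated, so the
pipeline's log transform exactly Gaussianises them and parameter-recovery
tests stay sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BiomarkerDataset

PATHWAYS = (
    "Systemic Inflammation",
    "Innate Immune Activation",
    "Endothelial Activation",
    "Coagulation",
    "T Helper 1 Response",
    "Microbial Translocation",
    "T Cell Modulation",
    "Gut Epithelial Barrier",
    "Obesity",
    "Antiviral",
    "Tissue Repair",
    "Immune Regulation",
    "Anti-inflammatory",
    "Neuronal Pathways",
)

DEFAULT_COHORTS = {"Amsterdam": 0.27, "Dublin": 0.60, "London": 0.13}

#: log-odds for the composite vascular phenotype given centred covariates
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.07,        # per year, centred at 52
    "sex": 0.20,        # male vs female
    "bmi": 0.10,        # per kg/m^2, centred at 26
    "smoking_ever": 0.62,
    "dyslipidaemia": 0.92,
}


def default_shift_matrix(
    k: int,
    n_markers: int,
    n_baseline: int,
    n_informative_candidates: int,
    magnitude: float,
) -> np.ndarray:
    """Per-cluster per-marker mean shifts (k x n_markers, SD units).

    All baseline markers plus the first ``n_informative_candidates``
    candidates carry signal.  Cluster 1 sits ``magnitude/2`` below the grand
    mean, cluster 2 the same amount above, and cluster 3 alternates a full
    ``magnitude`` up/down across markers so all three clusters are mutually
    separable.  Remaining candidates are pure noise.
    """
    shifts = np.zeros((k, n_markers))
    informative = list(range(n_baseline)) + list(
        range(n_baseline, min(n_baseline + n_informative_candidates, n_markers))
    )
    for m, j in enumerate(informative):
        shifts[0, j] = -0.5 * magnitude
        if k > 1:
            shifts[1, j] = +0.5 * magnitude
        for g in range(2, k):
            shifts[g, j] = magnitude if (m + g) % 2 == 0 else -magnitude
    return shifts


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults mirror the study setting
    of ~408 participants, a 24-marker baseline panel within 55 markers, three
    latent clusters with proportions ~(0.45, 0.45, 0.10), and three sites."""

    n_participants: int = 408
    n_markers: int = 55
    n_baseline: int = 24
    k_true: int = 3
    cluster_proportions: tuple[float, ...] = (0.45, 0.45, 0.10)
    cluster_mean_shifts: np.ndarray | None = None  # k_true x n_markers, SD units
    n_informative_candidates: int = 6
    shift_magnitude: float = 2.0
    block_correlation: float = 0.3
    n_batches: int = 4
    batch_shift_sd: float = 0.2
    batch_scale_sd: float = 0.05
    cohort_labels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    outcome_intercept: float = -1.0
    outcome_cluster_log_odds: tuple[float, ...] = (0.0, 0.2, 0.8)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if len(self.cluster_proportions) != self.k_true:
            raise ValueError("cluster_proportions length must equal k_true")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if (props <= 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("cluster_proportions must be positive and sum to 1")
        if not (0.0 <= self.missing_rate <= 0.10):
            raise ValueError(
                "missing_rate must be <= 0.10 (markers with more missing data "
                "are ineligible for imputation)"
            )
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must be in [0, 1)")
        if self.n_baseline > self.n_markers:
            raise ValueError("n_baseline cannot exceed n_markers")
        if len(self.outcome_cluster_log_odds) != self.k_true:
            raise ValueError("outcome_cluster_log_odds length must equal k_true")

    def shifts(self) -> np.ndarray:
        if self.cluster_mean_shifts is not None:
            arr = np.asarray(self.cluster_mean_shifts, dtype=float)
            if arr.shape != (self.k_true, self.n_markers):
                raise ValueError("cluster_mean_shifts must be k_true x n_markers")
            return arr
        return default_shift_matrix(
            self.k_true,
            self.n_markers,
            self.n_baseline,
            self.n_informative_candidates,
            self.shift_magnitude,
        )


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    dataset: BiomarkerDataset
    true_cluster: pd.Series  # latent label per participant, 1..k_true
    true_retained_markers: list[str]  # informative candidates outside baseline
    missing_mask: pd.DataFrame | None = None
    complete_values: pd.DataFrame | None = None  # pre-missingness matrix

    def __post_init__(self) -> None:
        if self.true_cluster.nunique() < 1:
            raise ValueError("true_cluster is empty")


def _marker_ids(n: int) -> list[str]:
    return [f"Marker{i:02d}" for i in range(1, n + 1)]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a seeded synthetic cohort under ``config``.

    Identical configs (including seed) give bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_participants, config.n_markers, config.k_true

    marker_ids = _marker_ids(p)
    pathways = [PATHWAYS[(i * len(PATHWAYS)) // p] for i in range(p)]
    panel = ["baseline"] * config.n_baseline + ["candidate"] * (p - config.n_baseline)
    model1_order = [np.nan] * config.n_baseline + list(
        range(config.n_baseline + 1, p + 1)
    )
    marker_meta = pd.DataFrame(
        {"pathway": pathways, "panel": panel, "model1_order": model1_order},
        index=pd.Index(marker_ids, name="marker_id"),
    )

    # latent clusters
    labels = rng.choice(np.arange(1, k + 1), size=n, p=config.cluster_proportions)
    shifts = config.shifts()

    # block-correlated log-scale noise: one shared factor per pathway block
    rho = config.block_correlation
    block_idx = pd.Series(pathways).factorize()[0]
    n_blocks = block_idx.max() + 1
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    z = np.sqrt(rho) * factors[:, block_idx] + np.sqrt(1.0 - rho) * eps

    mu = rng.uniform(0.5, 3.0, size=p)  # baseline log-concentration per marker
    log_values = mu[None, :] + shifts[labels - 1, :] + z

    # multiplicative plate effects (location/scale on the log scale)
    batches = rng.integers(0, config.n_batches, size=n)
    if config.n_batches > 1:
        bshift = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, p))
        bscale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, p)))
        log_values = mu[None, :] + (log_values - mu[None, :]) * bscale[batches, :] + bshift[batches, :]

    values = np.exp(log_values)

    # cohort/site labels, independent of cluster by default
    sites = list(config.cohort_labels)
    site_p = np.asarray(list(config.cohort_labels.values()), dtype=float)
    site_p = site_p / site_p.sum()
    cohort = rng.choice(sites, size=n, p=site_p)

    # clinical covariates
    age = rng.uniform(30, 75, size=n)
    sex = rng.binomial(1, 0.83, size=n)  # 1 = male
    bmi = rng.uniform(18, 40, size=n)
    smoking = rng.choice(["current", "ex", "never"], size=n, p=(0.22, 0.24, 0.54))
    dyslipidaemia = rng.binomial(1, 0.35, size=n)
    smoking_ever = (smoking != "never").astype(float)

    # binary composite vascular phenotype from a logistic model
    eff = config.covariate_effects
    lp = (
        config.outcome_intercept
        + np.asarray(config.outcome_cluster_log_odds)[labels - 1]
        + eff.get("age", 0.0) * (age - 52.0)
        + eff.get("sex", 0.0) * sex
        + eff.get("bmi", 0.0) * (bmi - 26.0)
        + eff.get("smoking_ever", 0.0) * smoking_ever
        + eff.get("dyslipidaemia", 0.0) * dyslipidaemia
    )
    prob = 1.0 / (1.0 + np.exp(-lp))
    cvp = rng.binomial(1, prob)
    # decompose the composite into hypertension and "hard" vascular events
    is_event = rng.binomial(1, 0.2, size=n).astype(bool)
    hypertension = np.where(cvp == 1, (~is_event).astype(int), 0)
    events = np.where(cvp == 1, is_event.astype(int), 0)

    # unitless 10-year risk score: deterministic in risk factors plus noise
    score = np.exp(
        np.log(6.0)
        + 0.06 * (age - 52.0)
        + 0.5 * smoking_ever
        + 0.4 * dyslipidaemia
        + rng.normal(0.0, 0.5, size=n)
    )
    ascvd = np.clip(score, 0.1, 99.9)

    ids = pd.Index([f"P{i:04d}" for i in range(1, n + 1)], name="participant_id")
    participant_meta = pd.DataFrame(
        {
            "cohort": cohort,
            "batch": [f"plate{b + 1}" for b in batches],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "dyslipidaemia": dyslipidaemia,
            "outcome_cvp": cvp,
            "hypertension": hypertension,
            "events": events,
            "ascvd": ascvd,
        },
        index=ids,
    )
    values_df = pd.DataFrame(values, index=ids, columns=marker_ids)
    dataset = BiomarkerDataset(values_df, marker_meta, participant_meta)

    informative = np.flatnonzero(np.abs(shifts).sum(axis=0) > 0)
    true_retained = [marker_ids[j] for j in informative if j >= config.n_baseline]

    cohort_obj = SyntheticCohort(
        dataset=dataset,
        true_cluster=pd.Series(labels, index=ids, name="true_cluster"),
        true_retained_markers=true_retained,
    )
    if config.missing_rate > 0:
        cohort_obj = inject_missingness(
            cohort_obj, config.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return cohort_obj


def inject_missingness(cohort: SyntheticCohort, rate: float, seed: int) -> SyntheticCohort:
    """Set cells missing completely at random, per marker, at ``rate``.

    Rates above 10 % are rejected: markers missing that much data fall
    outside the imputation eligibility rule ("less than 10 % of the overall
    data") applied by the preprocessing stage.  The pre-missingness matrix
    and the boolean mask are kept on the returned cohort so imputation
    accuracy can be scored.
    """
    if not (0.0 <= rate <= 0.10):
        raise ValueError(
            "missingness rate must be <= 0.10: markers with >= 10% missing "
            "data are not eligible for imputation"
        )
    values = cohort.dataset.values
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(
        rng.random(values.shape) < rate, index=values.index, columns=values.columns
    )
    if rate == 0.0:
        mask.loc[:, :] = False
    new_values = values.mask(mask)
    return SyntheticCohort(
        dataset=cohort.dataset.with_values(new_values),
        true_cluster=cohort.true_cluster.copy(),
        true_retained_markers=list(cohort.true_retained_markers),
        missing_mask=mask,
        complete_values=values.copy(),
    )


def headroom_config(seed: int = 0, baseline_magnitude: float = 1.0,
                    candidate_magnitude: float = 4.0,
                    n_informative_candidates: int = 6) -> SyntheticConfig:
    """Cohort for candidate-recovery studies: a moderately informative
    baseline panel (1-SD shifts, held-out separability ~0.9, leaving the
    oracle headroom) plus overwhelmingly informative candidates (4-SD
    shifts).  Under the default cohort the baseline panel alone already
    separates the clusters perfectly, so no candidate can strictly improve
    the oracle; this configuration is the alternative hypothesis for
    selection-frequency studies, with the default cohort as the null.
    """
    shifts = default_shift_matrix(3, 55, 24, 0, baseline_magnitude)
    strong = default_shift_matrix(3, 55, 24, n_informative_candidates,
                                  candidate_magnitude)
    shifts[:, 24:24 + n_informative_candidates] = \
        strong[:, 24:24 + n_informative_candidates]
    return SyntheticConfig(seed=seed, cluster_mean_shifts=shifts)


def expected_prevalence(config: SyntheticConfig, n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo expectation of outcome prevalence under ``config``'s
    logistic model (marginalised over covariates and cluster)."""
    config.validate()
    rng = np.random.default_rng(seed)
    labels = rng.choice(config.k_true, size=n_mc, p=config.cluster_proportions)
    age = rng.uniform(30, 75, size=n_mc)
    sex = rng.binomial(1, 0.83, size=n_mc)
    bmi = rng.uniform(18, 40, size=n_mc)
    smoking_ever = rng.random(n_mc) < 0.46
    dys = rng.binomial(1, 0.35, size=n_mc)
    eff = config.covariate_effects
    lp = (
        config.outcome_intercept
        + np.asarray(config.outcome_cluster_log_odds)[labels]
        + eff.get("age", 0.0) * (age - 52.0)
        + eff.get("sex", 0.0) * sex
        + eff.get("bmi", 0.0) * (bmi - 26.0)
        + eff.get("smoking_ever", 0.0) * smoking_ever
        + eff.get("dyslipidaemia", 0.0) * dys
    )
    return float(np.mean(1.0 / (1.0 + np.exp(-lp))))
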