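"""Association-model contracts: logistic ORs with profile-likelihood CIs,
stratified bootstrap, fold changes and rank tests."""

import numpy as np
import pandas as pd
import pytest

from rfaclust import (compare_clusters_nonparametric, fit_logistic_profile,
                      fold_change_continuous, identify_uninflamed,
                      stratified_bootstrap_or)


def _toy_participants(outcome, extra=None):
    n = len(outcome)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "outcome_cvp": outcome,
        "age": rng.uniform(35, 70, n),
        "sex": rng.binomial(1, 0.8, n),
        "bmi": rng.uniform(19, 35, n),
        "smoking": rng.choice(["current", "ex", "never"], n),
        "dyslipidaemia": rng.binomial(1, 0.3, n),
    }, index=pd.RangeIndex(n))
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestLogisticProfile:
    def test_unadjusted_or_equals_cross_product_ratio(self):
        """Cluster B vs reference with outcome table (30/70, 15/85):
        OR = (30*85)/(70*15) = 2.428571, exactly the contingency identity."""
        outcome = np.concatenate([np.repeat([1, 0], [15, 85]),
                                  np.repeat([1, 0], [30, 70])])
        assignments = pd.Series([1] * 100 + [2] * 100)
        res = fit_logistic_profile(_toy_participants(outcome), assignments,
                                   reference=1)
        assert res.estimates.loc[2, "estimate"] == pytest.approx(
            (30 * 85) / (70 * 15), rel=1e-6)
        assert res.estimates.loc[2, "ci_low"] < res.estimates.loc[2, "estimate"] \
            < res.estimates.loc[2, "ci_high"]

    def test_profile_and_wald_intervals_agree_asymptotically(self):
        """At n = 10,000 and a moderate effect the profile interval matches
        the Wald interval to within 10 % relative width."""
        rng = np.random.default_rng(1)
        n = 10_000
        cluster = rng.integers(1, 3, n)
        lp = -0.5 + 0.7 * (cluster == 2)
        outcome = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        part = _toy_participants(outcome)
        assignments = pd.Series(cluster, index=part.index)
        prof = fit_logistic_profile(part, assignments, reference=1, profile=True)
        wald = fit_logistic_profile(part, assignments, reference=1, profile=False)
        wp = np.log(prof.estimates.loc[2, ["ci_low", "ci_high"]].astype(float))
        ww = np.log(wald.estimates.loc[2, ["ci_low", "ci_high"]].astype(float))
        width_p = wp.iloc[1] - wp.iloc[0]
        width_w = ww.iloc[1] - ww.iloc[0]
        assert abs(width_p - width_w) / width_w < 0.10

    def test_adjusted_model_uses_requested_covariates(self):
        rng = np.random.default_rng(2)
        n = 300
        cluster = rng.integers(1, 4, n)
        outcome = rng.binomial(1, 0.3, n)
        part = _toy_participants(outcome)
        assignments = pd.Series(cluster, index=part.index)
        res = fit_logistic_profile(part, assignments, reference=1,
                                   covariates=["age", "sex", "bmi",
                                               "smoking_ever", "dyslipidaemia"],
                                   profile=False)
        assert res.adjusted and len(res.estimates) == 2

    def test_separation_raises(self):
        outcome = np.array([1] * 20 + [0] * 20)
        assignments = pd.Series([2] * 20 + [1] * 20)
        with pytest.raises(RuntimeError, match="separation|converge"):
            fit_logistic_profile(_toy_participants(outcome), assignments,
                                 reference=1, profile=False)

    def test_non_binary_outcome_rejected(self):
        part = _toy_participants(np.arange(10) % 3)
        with pytest.raises(ValueError):
            fit_logistic_profile(part, pd.Series([1] * 5 + [2] * 5))


class TestStratifiedBootstrap:
    def test_strong_effect_exceeds_unity_in_most_iterations(self):
        rng = np.random.default_rng(3)
        n = 400
        cluster = rng.integers(1, 3, n)
        lp = -1.0 + np.log(3.0) * (cluster == 2)
        outcome = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        part = _toy_participants(outcome)
        rep = stratified_bootstrap_or(part, pd.Series(cluster, index=part.index),
                                      n_iterations=150, seed=0, reference=1)
        assert rep.summary.loc[2, "prop_or_gt_1"] >= 0.95
        s = rep.summary.loc[2]
        assert s["ci_low"] <= s["median_or"] <= s["ci_high"]

    def test_null_effect_centres_near_half_across_seeds(self):
        props = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n = 250
            cluster = rng.integers(1, 3, n)
            outcome = rng.binomial(1, 0.35, n)
            part = _toy_participants(outcome)
            rep = stratified_bootstrap_or(part,
                                          pd.Series(cluster, index=part.index),
                                          n_iterations=60, seed=seed,
                                          reference=1)
            props.append(rep.summary.loc[2, "prop_or_gt_1"])
        assert 0.3 <= np.mean(props) <= 0.7

    def test_prevalence_preserved_within_resamples(self):
        """The stratified scheme keeps the case/control counts of the
        original data in every iteration (tested indirectly: dropping none
        and tight OR spread under zero noise)."""
        outcome = np.repeat([1, 0], [60, 140])
        cluster = np.where(np.arange(200) % 2 == 0, 1, 2)
        part = _toy_participants(outcome)
        rep = stratified_bootstrap_or(part, pd.Series(cluster, index=part.index),
                                      n_iterations=30, seed=1, reference=1)
        assert rep.n_dropped == 0


class TestFoldChange:
    def test_log2_separation_recovers_factor_two(self):
        rng = np.random.default_rng(4)
        n = 400
        cluster = rng.integers(1, 3, n)
        score = np.exp(np.log(5.0) + np.log(2.0) * (cluster == 2)
                       + rng.normal(0, 0.3, n))
        part = _toy_participants(rng.binomial(1, 0.3, n), extra={"ascvd": score})
        res = fold_change_continuous(part, pd.Series(cluster, index=part.index),
                                     reference=1)
        assert 1.8 <= res.estimates.loc[2, "estimate"] <= 2.2

    def test_equal_deterministic_groups_give_fold_change_one(self):
        part = _toy_participants(np.repeat([0, 1], 10),
                                 extra={"ascvd": np.full(20, 7.0)})
        res = fold_change_continuous(part, pd.Series([1] * 10 + [2] * 10),
                                     reference=1)
        assert res.estimates.loc[2, "estimate"] == pytest.approx(1.0)

    def test_nonpositive_outcome_rejected(self):
        part = _toy_participants(np.repeat([0, 1], 5),
                                 extra={"ascvd": [1.0] * 9 + [0.0]})
        with pytest.raises(ValueError, match="nonpositive"):
            fold_change_continuous(part, pd.Series([1] * 5 + [2] * 5))

    def test_null_interval_covers_one_at_nominal_rate(self):
        covered = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 120
            cluster = rng.integers(1, 3, n)
            score = np.exp(rng.normal(1.5, 0.4, n))
            part = _toy_participants(rng.binomial(1, 0.3, n),
                                     extra={"ascvd": score})
            res = fold_change_continuous(part,
                                         pd.Series(cluster, index=part.index))
            est = res.estimates.loc[2]
            covered += est["ci_low"] <= 1.0 <= est["ci_high"]
        assert covered / 60 >= 0.85


class TestKruskal:
    def test_disjoint_support_is_highly_significant(self):
        part = _toy_participants(np.repeat([0, 1], 20),
                                 extra={"ascvd": np.r_[np.linspace(1, 2, 20),
                                                       np.linspace(10, 11, 20)]})
        stat, p = compare_clusters_nonparametric(
            part, pd.Series([1] * 20 + [2] * 20))
        assert p < 1e-4

    def test_all_tied_returns_p_one(self):
        part = _toy_participants(np.repeat([0, 1], 5),
                                 extra={"ascvd": np.full(10, 3.0)})
        stat, p = compare_clusters_nonparametric(part,
                                                 pd.Series([1] * 5 + [2] * 5))
        assert (stat, p) == (0.0, 1.0)

    def test_minimal_two_singletons(self):
        part = _toy_participants(np.array([0, 1]), extra={"ascvd": [2.0, 5.0]})
        stat, p = compare_clusters_nonparametric(part, pd.Series([1, 2]))
        assert np.isfinite(stat) and 0 <= p <= 1


def test_identify_uninflamed_picks_lowest_inflammation_cluster(
        small_cohort, small_solution):
    ref = identify_uninflamed(small_solution.vtest,
                              small_cohort.dataset.marker_meta)
    sub = small_solution.vtest.table
    inflam = small_cohort.dataset.marker_meta.query(
        "pathway == 'Systemic Inflammation'").index
    means = sub[sub["marker"].isin(inflam)].groupby("cluster")["v"].mean()
    assert ref == means.idxmin()
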