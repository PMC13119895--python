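"""End-to-end orchestration: simulate/ingest -> preprocess -> baseline
clustering -> RFA selection -> re-clustering -> stability -> associations,
driven by one serialisable configuration, plus the cross-model comparison
report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import ClusterSolution, PCAWardClusterer, cluster_panel
from .dataset import BiomarkerDataset
from .oracle import OracleConfig
from .outcomes import (fit_logistic_profile, identify_uninflamed,
                       stratified_bootstrap_or)
from .preprocess import preprocess
from .selection import (FrequencyReport, SelectionCriteria, SelectionResult,
                        run_model, selection_frequency)
from .simulate import SyntheticConfig, generate_cohort
from .stability import StabilityReport, bootstrap_cluster_stability


@dataclass
class RunConfig:
    """One config to rule every stage; YAML round-trip is idempotent."""

    seed: int = 0
    out_dir: str = "rfa_out"
    input_dir: str | None = None          # load dataset from CSVs when set
    simulate: dict = field(default_factory=dict)    # SyntheticConfig overrides
    preprocess: dict = field(default_factory=lambda: {"m": 5, "iterations": 50,
                                                      "completion": "first"})
    cluster: dict = field(default_factory=lambda: {"variance_threshold": 0.70,
                                                   "k_min": 2, "k_max": 6,
                                                   "alpha": 0.05})
    oracle: dict = field(default_factory=lambda: {"n_trees": 500,
                                                  "train_fraction": 0.70,
                                                  "cv_folds": 3, "mtry": "cv"})
    criteria: dict = field(default_factory=dict)
    models: list[int] = field(default_factory=lambda: [1, 2, 3])
    stability: dict = field(default_factory=lambda: {"n_boot": 500,
                                                     "n_freq_iterations": 50,
                                                     "run_frequency": False})
    association: dict = field(default_factory=lambda: {"outcome": "outcome_cvp",
                                                       "n_boot": 1000})

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed: entry ``stage`` of the seed stream
        spawned from the master seed."""
        return int(np.random.SeedSequence(self.seed).generate_state(stage + 1)[-1] % (2**31))


@dataclass
class ModelComparison:
    """Cross-model summary: selection size, stability, outcome association."""

    rows: pd.DataFrame        # index model id
    baseline_k: int
    fingerprint: str


def _serialise_solution(sol: ClusterSolution) -> dict:
    return {
        "k": sol.k,
        "n_components": sol.n_components,
        "variance_explained": [float(v) for v in sol.variance_explained],
        "inertia_gain_ratios": {str(k): (None if np.isinf(v) else float(v))
                                for k, v in sol.inertia_gain_ratios.items()},
        "cluster_sizes": {str(k): int(v) for k, v in sol.cluster_sizes.items()},
        "fingerprint": sol.config_fingerprint,
        "panel": sol.panel,
    }


def run_pipeline(config: RunConfig, write: bool = True) -> ModelComparison:
    """Execute every stage under ``config``; byte-identical reruns at a
    fixed config + seed.  Artifacts land in per-stage subdirectories of
    ``config.out_dir`` when ``write`` is true."""
    out = Path(config.out_dir)

    # stage 0: data
    if config.input_dir:
        dataset = BiomarkerDataset.from_csv_dir(config.input_dir)
    else:
        sim_cfg = SyntheticConfig(**{"seed": config.stage_seed(0), **config.simulate})
        cohort = generate_cohort(sim_cfg)
        dataset = cohort.dataset
        if write:
            d = out / "data"
            dataset.to_csv_dir(d)
            truth = {"true_cluster": cohort.true_cluster.astype(int).to_dict(),
                     "true_retained_markers": cohort.true_retained_markers}
            (d / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    # stage 1: preprocessing
    processed, report = preprocess(dataset, seed=config.stage_seed(1),
                                   **config.preprocess)
    matrix = processed.values
    if write:
        (out / "preprocess").mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out / "preprocess" / "processed.csv")

    # stage 2: baseline clustering
    pipeline_params = dict(config.cluster)
    clusterer = PCAWardClusterer(**pipeline_params)
    baseline_panel = dataset.baseline_panel
    baseline = cluster_panel(matrix, baseline_panel, **pipeline_params)
    labels = baseline.assignments.to_numpy()
    if write:
        d = out / "baseline"
        d.mkdir(parents=True, exist_ok=True)
        baseline.assignments.to_csv(d / "clusters.csv")
        baseline.vtest.table.to_csv(d / "vtest.csv", index=False)
        (d / "solution.json").write_text(json.dumps(_serialise_solution(baseline), indent=1))

    oracle_cfg = OracleConfig(seed=config.stage_seed(2), **config.oracle)
    criteria = SelectionCriteria(**config.criteria)
    candidates = dataset.candidates_in_model1_order()

    rows = []
    for model_id in config.models:
        sel = run_model(model_id, matrix, baseline_panel, candidates, labels,
                        criteria, oracle_cfg)
        panel = baseline_panel + sel.retained
        refined = cluster_panel(matrix, panel, **pipeline_params)
        stab = bootstrap_cluster_stability(
            matrix, panel, refined, n_boot=config.stability["n_boot"],
            seed=config.stage_seed(10 + model_id), pipeline=clusterer,
        )
        freq_range = (np.nan, np.nan)
        if config.stability.get("run_frequency"):
            freq = selection_frequency(
                matrix, baseline_panel, candidates, labels, model_id,
                n_iterations=config.stability["n_freq_iterations"],
                criteria=criteria, oracle_config=oracle_cfg,
                seed=config.stage_seed(20 + model_id),
            )
            freq_range = (float(freq.frequencies.min()), float(freq.frequencies.max()))
            if write:
                d = out / f"model{model_id}"
                d.mkdir(parents=True, exist_ok=True)
                freq.frequencies.rename("selection_frequency").to_csv(d / "frequency.csv")

        reference = identify_uninflamed(refined.vtest, dataset.marker_meta)
        inflamed = refined.k  # smallest cluster under size-ordered labelling
        if inflamed == reference:
            inflamed = refined.k - 1
        adjust = ["age", "sex", "bmi", "smoking_ever", "dyslipidaemia"]
        assoc = fit_logistic_profile(
            processed.participant_meta, refined.assignments,
            outcome=config.association["outcome"],
            covariates=adjust, reference=reference,
        )
        boot = stratified_bootstrap_or(
            processed.participant_meta, refined.assignments,
            outcome=config.association["outcome"],
            covariates=adjust, n_iterations=config.association["n_boot"],
            seed=config.stage_seed(30 + model_id), reference=reference,
        )
        est = assoc.estimates.loc[inflamed]
        rows.append({
            "model": model_id,
            "n_retained": len(sel.retained),
            "retained": ",".join(sel.retained),
            "k": refined.k,
            "median_ari": stab.summary["median"],
            "ari_sd": stab.summary["sd"],
            "freq_min": freq_range[0],
            "freq_max": freq_range[1],
            "adjusted_or_inflamed": float(est["estimate"]),
            "or_ci_low": float(est["ci_low"]),
            "or_ci_high": float(est["ci_high"]),
            "prop_or_gt_1": float(boot.summary.loc[inflamed, "prop_or_gt_1"]),
        })
        if write:
            d = out / f"model{model_id}"
            d.mkdir(parents=True, exist_ok=True)
            sel.per_candidate.to_csv(d / "per_candidate.csv")
            (d / "selection.json").write_text(json.dumps(
                {"model": model_id, "retained": sel.retained,
                 "path": [list(p) for p in sel.path],
                 "baseline_accuracy": sel.baseline_metrics.accuracy,
                 "baseline_kappa": sel.baseline_metrics.kappa}, indent=1))
            refined.assignments.to_csv(d / "clusters.csv")
            pd.Series(stab.ari_values, name="ari").to_csv(d / "ari.csv", index=False)
            (d / "stability.json").write_text(json.dumps(
                {**stab.summary, "n_valid": stab.n_valid,
                 "n_failed": stab.n_failed}, indent=1))
            assoc.estimates.to_csv(d / "associations.csv")
            boot.summary.to_csv(d / "bootstrap_or.csv")

    comparison = ModelComparison(
        rows=pd.DataFrame(rows).set_index("model"),
        baseline_k=baseline.k,
        fingerprint=clusterer.fingerprint(),
    )
    if write:
        comparison.rows.to_csv(out / "comparison.csv")
        write_report(comparison, out / "report.md")
    return comparison


def write_report(comparison: ModelComparison, path: str | Path) -> None:
    """Render the cross-model comparison as a markdown table."""
    lines = ["# Model comparison", "",
             f"Baseline clustering: k = {comparison.baseline_k} "
             f"(pipeline fingerprint {comparison.fingerprint})", ""]
    df = comparison.rows
    if len(df):
        metrics = [
            ("Number of additional biomarkers retained", "n_retained", "{:d}"),
            ("Retained markers", "retained", "{}"),
            ("Cluster count after re-clustering", "k", "{:d}"),
            ("Cluster stability (median ARI)", "median_ari", "{:.3f}"),
            ("ARI standard deviation", "ari_sd", "{:.3f}"),
            ("Adjusted OR, inflamed cluster", "adjusted_or_inflamed", "{:.2f}"),
            ("OR 95% CI low", "or_ci_low", "{:.2f}"),
            ("OR 95% CI high", "or_ci_high", "{:.2f}"),
            ("Bootstrap prop(OR > 1)", "prop_or_gt_1", "{:.3f}"),
        ]
        header = "| Metric | " + " | ".join(f"Model {m}" for m in df.index) + " |"
        sep = "|---" * (len(df.index) + 1) + "|"
        lines += [header, sep]
        for label, col, fmt in metrics:
            cells = []
            for m in df.index:
                v = df.loc[m, col]
                try:
                    cells.append(fmt.format(v if fmt != "{:d}" else int(v)))
                except (ValueError, TypeError):
                    cells.append(str(v))
            lines.append("| " + label + " | " + " | ".join(cells) + " |")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
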