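"""Core data container for biomarker cohort analyses.

A :class:`BiomarkerDataset` bundles the participants x markers concentration
matrix with marker-level metadata (pathway membership, baseline vs candidate
panel flag, the fixed candidate ordering used by the cumulative selection
strategy) and participant-level metadata (cohort site, assay batch, clinical
covariates and cardiovascular outcomes).  Every stage of the pipeline reads
and writes this one structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: columns expected in the participant metadata table (extras are allowed)
PARTICIPANT_COLUMNS = (
    "cohort",
    "batch",
    "age",
    "sex",
    "bmi",
    "smoking",
    "dyslipidaemia",
    "outcome_cvp",
    "hypertension",
    "events",
    "ascvd",
)

MARKER_COLUMNS = ("pathway", "panel", "model1_order")


@dataclass
class BiomarkerDataset:
    """Participants x markers matrix plus marker and participant metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Concentration matrix, one row per participant (index = participant
        id), one column per marker (columns = marker ids).  Raw assay units
        before preprocessing; standardised values after.
    marker_meta : pandas.DataFrame
        Indexed by marker id with columns ``pathway`` (functional pathway
        label), ``panel`` (``"baseline"`` or ``"candidate"``) and
        ``model1_order`` (integer rank for the cumulative-addition strategy,
        NaN for baseline markers).
    participant_meta : pandas.DataFrame
        Indexed by participant id; see :data:`PARTICIPANT_COLUMNS`.
    """

    values: pd.DataFrame
    marker_meta: pd.DataFrame
    participant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if self.values.index.duplicated().any():
            raise ValueError("duplicated participant ids in values matrix")
        if not self.values.index.equals(self.participant_meta.index):
            raise ValueError("values and participant_meta indices differ")
        if not self.values.columns.equals(self.marker_meta.index):
            raise ValueError("values columns and marker_meta index differ")
        bad = set(self.marker_meta["panel"]) - {"baseline", "candidate"}
        if bad:
            raise ValueError(f"unknown panel flags: {sorted(bad)}")
        order = self.marker_meta.loc[
            self.marker_meta["panel"] == "candidate", "model1_order"
        ]
        order = order.dropna()
        if order.duplicated().any():
            raise ValueError("model1_order values must be unique")

    # ------------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def baseline_panel(self) -> list[str]:
        """Marker ids flagged as the baseline panel, in matrix order."""
        meta = self.marker_meta
        return list(meta.index[meta["panel"] == "baseline"])

    @property
    def candidate_panel(self) -> list[str]:
        """Candidate marker ids, in matrix order."""
        meta = self.marker_meta
        return list(meta.index[meta["panel"] == "candidate"])

    def candidates_in_model1_order(self) -> list[str]:
        """Candidate marker ids sorted by their fixed cumulative-addition rank."""
        meta = self.marker_meta
        cand = meta[meta["panel"] == "candidate"]
        if cand["model1_order"].isna().any():
            missing = list(cand.index[cand["model1_order"].isna()])
            raise ValueError(f"candidates without model1_order: {missing}")
        return list(cand.sort_values("model1_order").index)

    def copy(self) -> "BiomarkerDataset":
        return BiomarkerDataset(
            self.values.copy(), self.marker_meta.copy(), self.participant_meta.copy()
        )

    def with_values(self, values: pd.DataFrame) -> "BiomarkerDataset":
        """Return a dataset sharing metadata but with a replaced matrix."""
        return BiomarkerDataset(values, self.marker_meta.copy(), self.participant_meta.copy())

    # ------------------------------------------------------------------
    # plain-text round trip: markers.csv / participants.csv / panel.csv
    def to_csv_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("participant_id").to_csv(out / "markers.csv")
        self.participant_meta.rename_axis("participant_id").to_csv(out / "participants.csv")
        self.marker_meta.rename_axis("marker_id").to_csv(out / "panel.csv")

    @classmethod
    def from_csv_dir(cls, in_dir: str | Path) -> "BiomarkerDataset":
        src = Path(in_dir)
        values = pd.read_csv(src / "markers.csv", index_col="participant_id")
        participants = pd.read_csv(src / "participants.csv", index_col="participant_id")
        markers = pd.read_csv(src / "panel.csv", index_col="marker_id")
        return cls(values, markers, participants)
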