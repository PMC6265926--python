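"""Record-level survey container and delimited-table I/O.

One row per woman: binary contraceptive-use outcome, categorical
socio-economic covariates, two continuous age covariates, a district
code and a cluster code.  Simulated datasets additionally carry a
*truth block* — the linear predictor and each of its components per
record — written to a sibling ``*_truth.csv`` file so that recovery
tests can compare estimates against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

OUTCOME = "contraceptive_use"
DISTRICT = "district_id"
CLUSTER = "cluster_id"
AGE = "current_age"
COHAB_AGE = "age_first_cohabitation"

__all__ = ["SurveyDataset", "read_survey", "OUTCOME", "DISTRICT", "CLUSTER",
           "AGE", "COHAB_AGE"]


@dataclass
class SurveyDataset:
    """A record-level survey extract, optionally with simulation truth."""

    df: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if OUTCOME in self.df.columns:
            y = self.df[OUTCOME].to_numpy()
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"{OUTCOME} must be coded 0/1")
        if self.truth is not None and len(self.truth) != len(self.df):
            raise ValueError("truth block length does not match records")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df[OUTCOME].to_numpy(dtype=float)

    @property
    def districts(self) -> np.ndarray:
        return self.df[DISTRICT].to_numpy(dtype=int)

    def validate_districts(self, graph) -> None:
        present = set(np.unique(self.districts))
        known = set(graph.region_ids)
        missing = sorted(present - known)
        if missing:
            raise ValueError(f"district id(s) absent from adjacency graph: {missing}")

    def write(self, path: str | Path) -> None:
        """Write the records as CSV; truth block to a ``*_truth.csv`` sibling."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        if self.truth is not None:
            sib = path.with_name(path.stem + "_truth" + path.suffix)
            self.truth.to_csv(sib, index=False)


def read_survey(path: str | Path, with_truth: bool = False) -> SurveyDataset:
    """Read a survey table written by :meth:`SurveyDataset.write`."""
    path = Path(path)
    df = pd.read_csv(path)
    truth = None
    if with_truth:
        sib = path.with_name(path.stem + "_truth" + path.suffix)
        if sib.exists():
            truth = pd.read_csv(sib)
    return SurveyDataset(df=df, truth=truth)
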