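"""Published descriptive tabulations of the 2014/15 Rwanda DHS.

The survey's record-level file is access-restricted, but its published
descriptive tables are not: the method-type mix over the 6,847
respondents and a set of covariate-by-outcome contingency counts.
These counts are carried here as reference inputs so the descriptive
stage can be exercised and checked against the printed percentages
without any data download.  ``records_from_counts`` expands a count
table into an equivalent record-level dataset (cross-tabulation is
invariant to record order, so the expansion reproduces the published
percentages exactly).

The published living-children row for category "3" is internally
inconsistent in the source table and is not included here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import OUTCOME, SurveyDataset

__all__ = ["METHOD_MIX_COUNTS", "CROSSTAB_COUNTS", "records_from_counts",
           "method_mix_dataset"]

# method -> respondent count (total 6,847)
METHOD_MIX_COUNTS: dict[str, int] = {
    "none": 3237,
    "traditional": 402,
    "modern": 3208,
}

# covariate -> level -> (non-user count, user count)
CROSSTAB_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "education": {
        "no education": (596, 535),
        "primary": (2233, 2592),
        "secondary": (329, 379),
        "tertiary": (79, 104),
    },
    "working": {"yes": (2755, 3183), "no": (481, 426)},
    "radio": {"yes": (1666, 2100), "no": (1571, 1509)},
    "newspapers": {"yes": (150, 265), "no": (3086, 3344)},
    "tv": {"yes": (195, 294), "no": (3042, 3314)},
    "religion": {
        "catholic": (1129, 1489),
        "protestant": (1637, 1482),
        "adventist": (361, 517),
        "other": (103, 118),
    },
    "fp_worker_visit": {"yes": (813, 1184), "no": (2424, 2426)},
    "health_facility_visit": {"yes": (2379, 2539), "no": (858, 1071)},
    "wealth": {
        "poorest": (667, 622),
        "poorer": (730, 719),
        "middle": (654, 774),
        "richer": (599, 760),
        "richest": (586, 735),
    },
}


def records_from_counts(covariate: str) -> SurveyDataset:
    """Expand one published contingency table into record-level rows."""
    levels, vals, ys = [], [], []
    for lev, (n0, n1) in CROSSTAB_COUNTS[covariate].items():
        vals += [lev] * (n0 + n1)
        ys += [0] * n0 + [1] * n1
    return SurveyDataset(pd.DataFrame({covariate: vals, OUTCOME: ys}))


def method_mix_dataset() -> SurveyDataset:
    """Record-level expansion of the published method-type mix."""
    methods = np.repeat(
        list(METHOD_MIX_COUNTS), list(METHOD_MIX_COUNTS.values())
    )
    return SurveyDataset(
        pd.DataFrame(
            {
                "method_type": methods,
                OUTCOME: (methods != "none").astype(int),
            }
        )
    )
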