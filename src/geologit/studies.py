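"""Desk-scale validation studies: shared simulation configurations.

These are the package's standard benchmark conditions for checking that
the sampler recovers known truth and that DIC ranks model structures
sensibly, sized to run on one CPU in minutes.  The covariate set is a
reduced survey-like trio (education, working status, radio exposure)
with moderate reference-coded effects; the smooth truths keep the
study's qualitative shapes (use declining in current age, inverted-U in
age at first cohabitation); the district field is an ICAR draw on the
30-region lattice.  Problem sizes and chain lengths are documented in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .dataset import AGE, COHAB_AGE
from .inference import MCMCSettings, ModelSpec
from .simulate import SimulationSpec

__all__ = [
    "RECOVERY_FIXED_EFFECTS",
    "recovery_sim_spec",
    "recovery_model_spec",
    "recovery_mcmc",
    "dic_sim_spec",
    "dic_mcmc",
]

_MARGINALS = {
    "education": {"no education": 0.2, "primary": 0.5,
                  "secondary": 0.2, "tertiary": 0.1},
    "working": {"no": 0.3, "yes": 0.7},
    "radio": {"no": 0.45, "yes": 0.55},
}

RECOVERY_FIXED_EFFECTS = {
    ("education", "primary"): 0.20,
    ("education", "secondary"): 0.40,
    ("education", "tertiary"): 0.60,
    ("working", "yes"): 0.25,
    ("radio", "yes"): 0.30,
}

_REFERENCES = {"education": "no education", "working": "no", "radio": "no"}


def recovery_sim_spec(seed: int, n_women: int = 3000) -> SimulationSpec:
    """Parameter-recovery conditions: reduced covariates, default smooth
    truths, 30-district lattice ICAR field."""
    return SimulationSpec(
        n_women=n_women,
        n_clusters=90,
        fixed_effects=dict(RECOVERY_FIXED_EFFECTS),
        covariate_marginals={k: dict(v) for k, v in _MARGINALS.items()},
        spatial_tau=4.0,
        seed=seed,
    )


def recovery_model_spec(model_id: int = 4) -> ModelSpec:
    return ModelSpec(
        model_id=model_id,
        fixed_references=dict(_REFERENCES),
        max_grid=25,
    )


def recovery_mcmc(seed: int) -> MCMCSettings:
    return MCMCSettings(iterations=1500, burn_in=500, thinning=2, seed=seed)


def _dic_f_age(x: np.ndarray) -> np.ndarray:
    # monotone decline with saturation at both ends: nonlinear in age
    return -0.6 * np.tanh((x - 33.0) / 8.0)


def _dic_f_cohab(x: np.ndarray) -> np.ndarray:
    # pronounced inverted U peaking at 25
    return 0.6 - 0.006 * (x - 25.0) ** 2


def dic_sim_spec(seed: int, n_women: int = 2000) -> SimulationSpec:
    """Model-comparison conditions: clearly nonlinear smooths plus a
    spatial field, so structure choice matters."""
    return SimulationSpec(
        n_women=n_women,
        n_clusters=90,
        fixed_effects=dict(RECOVERY_FIXED_EFFECTS),
        covariate_marginals={k: dict(v) for k, v in _MARGINALS.items()},
        smooth_functions={AGE: _dic_f_age, COHAB_AGE: _dic_f_cohab},
        spatial_tau=2.0,
        seed=seed,
    )


def dic_mcmc(seed: int) -> MCMCSettings:
    return MCMCSettings(iterations=1200, burn_in=300, thinning=3, seed=seed)
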