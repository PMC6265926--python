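"""Deviance information criterion and model ranking.

DIC = Dbar + pD, where Dbar is the posterior mean of the Bernoulli
deviance over retained draws and pD = Dbar - D(theta_bar) is the
effective number of parameters, with the plug-in deviance evaluated at
the posterior mean of the linear predictor (the predictor is linear in
all coefficients, so the mean of eta over draws equals eta at the
posterior-mean coefficients).  Smaller DIC indicates a better
fit-complexity trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import SurveyDataset
from .graph import AdjacencyGraph
from .inference import (
    MCMCSettings,
    ModelSpec,
    PosteriorDraws,
    _deviance_from_eta,
    fit_model,
)

__all__ = ["dic", "compare_models", "DICReport", "dic_mc_se"]


def dic(draws: PosteriorDraws, dataset: SurveyDataset) -> tuple[float, float, float]:
    """Return ``(Dbar, pD, DIC)`` with ``DIC = Dbar + pD`` by construction."""
    if draws.n_retained < 2:
        raise ValueError("need at least 2 retained draws for DIC")
    dbar = float(draws.deviances.mean())
    d_plug = _deviance_from_eta(dataset.y, draws.eta_mean)
    pd_eff = dbar - d_plug
    return dbar, pd_eff, dbar + pd_eff


def dic_mc_se(draws: PosteriorDraws, n_batches: int = 20) -> float:
    """Batch-means Monte-Carlo standard error of Dbar (scales the
    tolerance for DIC comparisons)."""
    dev = draws.deviances
    nb = min(n_batches, len(dev) // 2)
    if nb < 2:
        return float("inf")
    usable = (len(dev) // nb) * nb
    means = dev[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


@dataclass
class DICReport:
    """Per-model DIC triple plus ascending ranking."""

    table: pd.DataFrame  # model_id, Dbar, pD, DIC, rank
    draws: dict[int, PosteriorDraws]

    @property
    def best_model(self) -> int:
        return int(self.table.sort_values("DIC").iloc[0]["model_id"])

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_models(
    dataset: SurveyDataset,
    graph: AdjacencyGraph | None,
    specs: list[ModelSpec],
    mcmc: MCMCSettings,
) -> DICReport:
    """Fit each spec and rank by DIC ascending.

    Each model gets an independent child seed derived from the common
    settings seed, so a comparison is reproducible end to end.
    """
    if not specs:
        raise ValueError("at least one model spec required")
    rows = []
    all_draws: dict[int, PosteriorDraws] = {}
    for spec in specs:
        child = int(
            np.random.SeedSequence([mcmc.seed, spec.model_id]).generate_state(1)[0]
            % (2**31 - 1)
        )
        settings = replace(mcmc, seed=child)
        try:
            draws = fit_model(dataset, graph, spec, settings)
        except Exception as exc:
            raise RuntimeError(f"model {spec.model_id} failed: {exc}") from exc
        dbar, pd_eff, d = dic(draws, dataset)
        rows.append({"model_id": spec.model_id, "Dbar": dbar, "pD": pd_eff, "DIC": d})
        all_draws[spec.model_id] = draws
    table = pd.DataFrame(rows)
    table["rank"] = table["DIC"].rank(method="first").astype(int)
    return DICReport(table=table, draws=all_draws)
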