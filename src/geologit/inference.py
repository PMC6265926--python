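"""Posterior sampling for the geo-additive Bernoulli-logit model.

The model for woman *i* in district *j* is

    y_i ~ Bernoulli(p_i),
    logit(p_i) = W_i' beta + sum_k f_k(x_ik) + f_spat(d_i),

with a vague Gaussian N(0, 1e6) prior per fixed coefficient (numerically
a flat prior at survey scales), an RW2 smoothness prior per continuous
covariate, and an ICAR Gaussian Markov random field over districts.
Gamma(a, b) hyperpriors sit on each smoothness/spatial precision.

Sampling uses Polya-Gamma data augmentation: given latent
``omega_i ~ PG(1, eta_i)``, the full conditional of the complete
coefficient vector is Gaussian with precision ``Z' Omega Z + P(tau)``
and shift ``Z'(y - 1/2)``, drawn jointly by one Cholesky solve per
iteration (the stacked dimension is small, order 1e2).  Precisions are
then refreshed from their conjugate Gamma full conditionals.  Smooth
and spatial blocks are kept identifiable by sum-to-zero recentring:
each iteration a common constant is moved from the block into the
intercept, which leaves the linear predictor unchanged; for a
disconnected map the per-component recentring happens only when draws
are stored.

The four model structures of interest are

    Model 1  fixed effects only (classical logistic regression,
             the two ages entering linearly),
    Model 2  fixed + RW2 smooths of the two ages,
    Model 3  fixed + ICAR district field,
    Model 4  fixed + smooths + district field,

selected by :class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .dataset import AGE, COHAB_AGE, SurveyDataset
from .design import FixedDesign, SmoothTerm, encode_fixed, smooth_design
from .graph import AdjacencyGraph, connected_components, icar_precision
from .pg import draw_pg_vector

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "FitSummary",
    "fit_model",
    "summarize",
    "deviance",
    "model_spec",
]

_VAGUE_BETA_PRECISION = 1e-6  # N(0, 1e6): numerically flat

# Soft sum-to-zero handling: the constant direction of each smooth/spatial
# block is likelihood-flat (it trades off exactly against the intercept and
# against other blocks' constants), so each block mean gets a proper N(0, 1)
# prior to keep the joint precision positive definite.  Stored draws are
# recentred to mean zero with the level moved into the intercept, and are
# therefore invariant to this choice.
_BLOCK_MEAN_PRECISION = 1.0


@dataclass
class MCMCSettings:
    """Chain length controls; the seed is mandatory."""

    iterations: int = 12_000
    burn_in: int = 2_000
    thinning: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ModelSpec:
    """Which terms enter the linear predictor.

    ``model_id`` follows the four canonical structures (1 fixed only,
    2 + smooths, 3 + spatial, 4 + both); ``fixed_references`` maps each
    categorical covariate to its reference level.  For models without
    smooths the two continuous covariates enter the fixed design
    linearly (standardised), matching the classical-logistic reading.
    """

    model_id: int
    fixed_references: dict[str, str]
    smooth_covariates: list[str] = field(
        default_factory=lambda: [AGE, COHAB_AGE]
    )
    linear_covariates: list[str] = field(
        default_factory=lambda: [AGE, COHAB_AGE]
    )
    max_grid: int = 50
    hyperprior: tuple[float, float] = (1.0, 0.0005)
    iid_district: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1, 2, 3 or 4")

    @property
    def has_smooths(self) -> bool:
        return self.model_id in (2, 4) and bool(self.smooth_covariates)

    @property
    def has_spatial(self) -> bool:
        return self.model_id in (3, 4)


def model_spec(model_id: int, references: dict[str, str], **kw) -> ModelSpec:
    return ModelSpec(model_id=model_id, fixed_references=dict(references), **kw)


@dataclass
class PosteriorDraws:
    """Retained MCMC output for one fitted model."""

    beta: np.ndarray                       # R x p
    beta_labels: list[str]
    smooths: dict[str, np.ndarray]         # name -> R x m
    smooth_grids: dict[str, np.ndarray]
    spatial: np.ndarray | None             # R x D (graph order) or None
    district_ids: list[int] | None
    taus: dict[str, np.ndarray]            # component -> R
    deviances: np.ndarray                  # R
    eta_mean: np.ndarray                   # n, running posterior mean of eta
    model_id: int
    settings: MCMCSettings
    fixed_design: FixedDesign | None = None

    @property
    def n_retained(self) -> int:
        return len(self.deviances)


def deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Bernoulli deviance ``-2 * sum[y log p + (1-y) log(1-p)]``."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ((p <= 0.0) & (y == 1)) | ((p >= 1.0) & (y == 0))
    if bad.any():
        raise ValueError("probability at 0/1 conflicts with outcome: infinite deviance")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y == 1, np.log(p), np.log1p(-p))
    return float(-2.0 * ll.sum())


def _deviance_from_eta(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 sum [y*eta - log(1 + exp(eta))], numerically stable
    return float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))


class _Blocks:
    """Stacked design with block slices and prior penalty builders."""

    def __init__(self, dataset: SurveyDataset,
                 graph: AdjacencyGraph | None, spec: ModelSpec) -> None:
        df = dataset.df
        self.y = dataset.y
        fixed = encode_fixed(dataset, spec.fixed_references)
        x = fixed.matrix
        labels = list(fixed.column_labels)
        if not spec.has_smooths:
            for cov in spec.linear_covariates:
                if cov in df.columns:
                    v = df[cov].to_numpy(dtype=float)
                    x = np.column_stack([x, (v - v.mean()) / v.std()])
                    labels.append(f"{cov} (linear, std)")
        self.fixed = fixed
        self.labels = labels
        parts = [x]
        self.p_beta = x.shape[1]
        pos = self.p_beta

        self.smooth_terms: list[SmoothTerm] = []
        self.smooth_slices: list[slice] = []
        if spec.has_smooths:
            for cov in spec.smooth_covariates:
                term = smooth_design(dataset, cov, max_grid=spec.max_grid)
                a = np.zeros((len(df), term.m))
                a[np.arange(len(df)), term.indices] = 1.0
                parts.append(a)
                self.smooth_terms.append(term)
                self.smooth_slices.append(slice(pos, pos + term.m))
                pos += term.m

        self.spatial_slice: slice | None = None
        self.graph = graph
        self.components: dict[int, int] | None = None
        if spec.has_spatial:
            if graph is None:
                raise ValueError("spatial model requires an adjacency graph")
            dataset.validate_districts(graph)
            d = graph.n_regions
            idx = {rid: i for i, rid in enumerate(graph.region_ids)}
            di = np.array([idx[j] for j in dataset.districts])
            a = np.zeros((len(df), d))
            a[np.arange(len(df)), di] = 1.0
            parts.append(a)
            self.spatial_slice = slice(pos, pos + d)
            self.q_spat = icar_precision(graph)
            self.components = connected_components(graph)
            self.n_components = max(self.components.values()) + 1
            pos += d

        self.iid_slice: slice | None = None
        if spec.iid_district:
            if graph is None:
                raise ValueError("iid district effect requires an adjacency graph")
            d = graph.n_regions
            idx = {rid: i for i, rid in enumerate(graph.region_ids)}
            di = np.array([idx[j] for j in dataset.districts])
            a = np.zeros((len(df), d))
            a[np.arange(len(df)), di] = 1.0
            parts.append(a)
            self.iid_slice = slice(pos, pos + d)
            pos += d

        self.z = np.hstack(parts)
        self.p_total = pos
        self.spec = spec

    def prior_penalty(self, taus: dict[str, float]) -> np.ndarray:
        pen = np.zeros((self.p_total, self.p_total))
        pen[: self.p_beta, : self.p_beta] = np.eye(self.p_beta) * _VAGUE_BETA_PRECISION
        for term, sl in zip(self.smooth_terms, self.smooth_slices):
            m = term.m
            pen[sl, sl] = (
                taus[f"smooth_{term.covariate}"] * term.penalty
                + _BLOCK_MEAN_PRECISION / m**2
            )
        if self.spatial_slice is not None:
            d = self.q_spat.shape[0]
            pen[self.spatial_slice, self.spatial_slice] = (
                taus["spatial"] * self.q_spat + _BLOCK_MEAN_PRECISION / d**2
            )
        if self.iid_slice is not None:
            d = self.iid_slice.stop - self.iid_slice.start
            pen[self.iid_slice, self.iid_slice] = taus["iid"] * np.eye(d)
        return pen

    def tau_names(self) -> list[str]:
        names = [f"smooth_{t.covariate}" for t in self.smooth_terms]
        if self.spatial_slice is not None:
            names.append("spatial")
        if self.iid_slice is not None:
            names.append("iid")
        return names


def fit_model(
    dataset: SurveyDataset,
    graph: AdjacencyGraph | None,
    spec: ModelSpec,
    mcmc: MCMCSettings,
) -> PosteriorDraws:
    """Run the Polya-Gamma Gibbs sampler; reproducible given the seed."""
    blocks = _Blocks(dataset, graph, spec)
    y = blocks.y
    z = blocks.z
    n, p = z.shape
    kappa = z.T @ (y - 0.5)

    a0, b0 = spec.hyperprior
    rng = np.random.default_rng(mcmc.seed)
    taus = {name: 10.0 for name in blocks.tau_names()}
    theta = np.zeros(p)

    ranks: dict[str, int] = {}
    for term in blocks.smooth_terms:
        ranks[f"smooth_{term.covariate}"] = term.m - 2
    if blocks.spatial_slice is not None:
        ranks["spatial"] = (
            blocks.q_spat.shape[0] - blocks.n_components
        )
    if blocks.iid_slice is not None:
        ranks["iid"] = blocks.iid_slice.stop - blocks.iid_slice.start

    n_ret = mcmc.n_retained
    beta_draws = np.empty((n_ret, blocks.p_beta))
    smooth_draws = {
        t.covariate: np.empty((n_ret, t.m)) for t in blocks.smooth_terms
    }
    spat_draws = (
        np.empty((n_ret, blocks.spatial_slice.stop - blocks.spatial_slice.start))
        if blocks.spatial_slice is not None
        else None
    )
    tau_draws = {name: np.empty(n_ret) for name in taus}
    dev_draws = np.empty(n_ret)
    eta_sum = np.zeros(n)

    eta = z @ theta
    r = 0
    for it in range(mcmc.iterations):
        omega = draw_pg_vector(eta, int(rng.integers(0, 2**31 - 1)))

        prec = (z * omega[:, None]).T @ z + blocks.prior_penalty(taus)
        try:
            chol = cholesky(prec, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"precision not PD at iteration {it}") from exc
        mean = cho_solve((chol, True), kappa)
        theta = mean + solve_triangular(
            chol, rng.standard_normal(p), lower=True, trans="T"
        )

        # identifiability: move each block's common level into the intercept
        for sl in blocks.smooth_slices:
            c = theta[sl].mean()
            theta[sl] -= c
            theta[0] += c
        for sl in (blocks.spatial_slice, blocks.iid_slice):
            if sl is not None:
                c = theta[sl].mean()
                theta[sl] -= c
                theta[0] += c

        for term, sl in zip(blocks.smooth_terms, blocks.smooth_slices):
            name = f"smooth_{term.covariate}"
            quad = theta[sl] @ term.penalty @ theta[sl]
            taus[name] = rng.gamma(a0 + 0.5 * ranks[name], 1.0 / (b0 + 0.5 * quad))
        if blocks.spatial_slice is not None:
            f = theta[blocks.spatial_slice]
            quad = f @ blocks.q_spat @ f
            taus["spatial"] = rng.gamma(
                a0 + 0.5 * ranks["spatial"], 1.0 / (b0 + 0.5 * quad)
            )
        if blocks.iid_slice is not None:
            f = theta[blocks.iid_slice]
            taus["iid"] = rng.gamma(
                a0 + 0.5 * ranks["iid"], 1.0 / (b0 + 0.5 * (f @ f))
            )

        eta = z @ theta
        if not np.all(np.isfinite(eta)):
            raise RuntimeError(f"non-finite state at iteration {it}")

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            theta_s = theta.copy()
            # per-component recentring for disconnected maps (storage only)
            if (
                blocks.spatial_slice is not None
                and blocks.n_components > 1
            ):
                sl = blocks.spatial_slice
                labels = np.array(
                    [blocks.components[j] for j in blocks.graph.region_ids]
                )
                shift = 0.0
                for lab in range(blocks.n_components):
                    m_c = theta_s[sl][labels == lab].mean()
                    fblock = theta_s[sl]
                    fblock[labels == lab] -= m_c
                    shift += m_c * np.mean(labels == lab)
                theta_s[0] += shift
            beta_draws[r] = theta_s[: blocks.p_beta]
            for term, sl in zip(blocks.smooth_terms, blocks.smooth_slices):
                smooth_draws[term.covariate][r] = theta_s[sl]
            if spat_draws is not None:
                spat_draws[r] = theta_s[blocks.spatial_slice]
            for name in taus:
                tau_draws[name][r] = taus[name]
            dev_draws[r] = _deviance_from_eta(y, eta)
            eta_sum += eta
            r += 1

    return PosteriorDraws(
        beta=beta_draws[:r],
        beta_labels=blocks.labels,
        smooths={k: v[:r] for k, v in smooth_draws.items()},
        smooth_grids={t.covariate: t.grid for t in blocks.smooth_terms},
        spatial=spat_draws[:r] if spat_draws is not None else None,
        district_ids=list(graph.region_ids) if blocks.spatial_slice is not None else None,
        taus={k: v[:r] for k, v in tau_draws.items()},
        deviances=dev_draws[:r],
        eta_mean=eta_sum / max(r, 1),
        model_id=spec.model_id,
        settings=mcmc,
        fixed_design=blocks.fixed,
    )


@dataclass
class FitSummary:
    """Posterior summaries in the reporting layout of the study tables."""

    fixed: pd.DataFrame          # label, mean, sd, odds_ratio, or_2.5%, or_97.5%
    smooths: dict[str, pd.DataFrame]   # grid, mean, lower, upper
    spatial: pd.DataFrame | None       # district, mean, lower, upper
    dic: tuple[float, float, float] | None = None  # (Dbar, pD, DIC)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fixed.to_csv(outdir / "fixed_effects.csv", index=False)
        for name, tab in self.smooths.items():
            tab.to_csv(outdir / f"smooth_{name}.csv", index=False)
        if self.spatial is not None:
            self.spatial.to_csv(outdir / "spatial_effects.csv", index=False)
        if self.dic is not None:
            pd.DataFrame(
                {"Dbar": [self.dic[0]], "pD": [self.dic[1]], "DIC": [self.dic[2]]}
            ).to_csv(outdir / "dic.csv", index=False)


def summarize(draws: PosteriorDraws, dataset: SurveyDataset | None = None) -> FitSummary:
    """Posterior means/SDs, odds ratios and 95% credible intervals.

    The odds ratio is ``exp`` of the posterior-mean coefficient; its
    interval is ``exp`` of the equal-tailed 2.5%/97.5% coefficient
    quantiles (``exp`` is monotone, so this equals the equal-tailed
    interval of the OR draws).  When a dataset is supplied the DIC block
    is attached.
    """
    if draws.n_retained < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    b = draws.beta
    lo, hi = np.quantile(b, [0.025, 0.975], axis=0)
    fixed = pd.DataFrame(
        {
            "term": draws.beta_labels,
            "mean": b.mean(axis=0),
            "sd": b.std(axis=0, ddof=1),
            "odds_ratio": np.exp(b.mean(axis=0)),
            "or_lower": np.exp(lo),
            "or_upper": np.exp(hi),
        }
    )
    smooths = {}
    for name, f in draws.smooths.items():
        qlo, qhi = np.quantile(f, [0.025, 0.975], axis=0)
        smooths[name] = pd.DataFrame(
            {
                "grid": draws.smooth_grids[name],
                "mean": f.mean(axis=0),
                "lower": qlo,
                "upper": qhi,
            }
        )
    spatial = None
    if draws.spatial is not None:
        qlo, qhi = np.quantile(draws.spatial, [0.025, 0.975], axis=0)
        spatial = pd.DataFrame(
            {
                "district": draws.district_ids,
                "mean": draws.spatial.mean(axis=0),
                "lower": qlo,
                "upper": qhi,
            }
        )
    dic = None
    if dataset is not None:
        from .selection import dic as _dic

        dic = _dic(draws, dataset)
    return FitSummary(fixed=fixed, smooths=smooths, spatial=spatial, dic=dic)
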