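"""DHS-like synthetic survey generation.

The generator emulates the structure of a national household survey of
married women of childbearing age: ~6,850 respondents nested in 492
sampling clusters within 30 districts, a binary current-contraceptive-
use outcome with overall prevalence near 53%, categorical
socio-economic covariates with realistic marginals, and two continuous
age covariates (current age 16–49, age at first cohabitation 10–49).
Outcomes follow a Bernoulli-logit geo-additive model: the success
probability of each record is the inverse logit of

    intercept + fixed-effect sum + f1(current age)
              + f2(age at first cohabitation) + spatial(district),

where the smooth truth functions default to a monotone decline in
current age and an inverted-U of cohabitation age peaking near 25, and
the district field is a single draw from a sum-to-zero ICAR Gaussian
Markov random field on a 5x6 rook lattice (30 regions, standing in for
a real 30-district map without shipping shapefiles).

Every record of a simulated dataset carries a *truth block* with the
linear predictor and each of its components, so parameter-recovery
tests can score estimates against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dataset import AGE, CLUSTER, COHAB_AGE, DISTRICT, OUTCOME, SurveyDataset
from .graph import AdjacencyGraph, connected_components, icar_precision

__all__ = [
    "SimulationSpec",
    "make_lattice_adjacency",
    "draw_icar_effects",
    "simulate_survey",
    "default_spec",
    "DEFAULT_MARGINALS",
    "DEFAULT_FIXED_EFFECTS",
]


def make_lattice_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-neighbour lattice with ``rows * cols`` regions, ids 1..D.

    A connected stand-in for a real district map; the 5x6 default has 30
    regions like Rwanda's districts.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    rid = lambda r, c: r * cols + c + 1
    neighbors: dict[int, set[int]] = {}
    for r in range(rows):
        for c in range(cols):
            nbrs = set()
            if r > 0:
                nbrs.add(rid(r - 1, c))
            if r < rows - 1:
                nbrs.add(rid(r + 1, c))
            if c > 0:
                nbrs.add(rid(r, c - 1))
            if c < cols - 1:
                nbrs.add(rid(r, c + 1))
            neighbors[rid(r, c)] = nbrs
    return AdjacencyGraph(
        region_ids=[rid(r, c) for r in range(rows) for c in range(cols)],
        neighbors=neighbors,
    )


def draw_icar_effects(
    graph: AdjacencyGraph, tau: float, rng_seed: int
) -> np.ndarray:
    """One draw from the sum-to-zero ICAR field with precision ``tau * Q``.

    The intrinsic prior is improper on the full space, so the draw is
    taken spectrally on the sum-to-zero subspace: eigenvectors of the
    ICAR structure matrix with nonzero eigenvalue get independent
    ``N(0, 1/(tau * lambda_i))`` coefficients and the null direction is
    excluded, which makes the result sum to zero by construction.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    comps = connected_components(graph)
    n_comp = max(comps.values()) + 1
    if n_comp > 1:
        sizes: dict[int, list[int]] = {}
        for rid, lab in comps.items():
            sizes.setdefault(lab, []).append(rid)
        raise ValueError(
            f"graph has {n_comp} connected components: "
            + "; ".join(str(sorted(v)) for v in sizes.values())
        )
    q = icar_precision(graph)
    lam, vec = np.linalg.eigh(q)
    keep = lam > 1e-9 * lam.max()
    rng = np.random.default_rng(rng_seed)
    coef = rng.standard_normal(int(keep.sum())) / np.sqrt(tau * lam[keep])
    return vec[:, keep] @ coef


# Covariate marginals approximating the published descriptive table of the
# 2014/15 survey (living-children probabilities renormalised; see docs).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "education": {"no education": 0.165, "primary": 0.705,
                  "secondary": 0.103, "tertiary": 0.027},
    "wealth": {"poorest": 0.188, "poorer": 0.212, "middle": 0.209,
               "richer": 0.199, "richest": 0.192},
    "health_facility_visit": {"no": 0.282, "yes": 0.718},
    "residing_with_husband": {"living with": 0.85, "stays elsewhere": 0.15},
    "living_children": {"0": 0.05, "1": 0.18, "2": 0.20, "3": 0.20,
                        "4 or more": 0.37},
    "religion": {"other": 0.032, "catholic": 0.382, "protestant": 0.456,
                 "adventist": 0.130},
    "working": {"no": 0.132, "yes": 0.868},
    "radio": {"no": 0.45, "yes": 0.55},
    "fp_worker_visit": {"no": 0.708, "yes": 0.292},
    "newspapers": {"no": 0.939, "yes": 0.061},
    "province": {"west": 0.24, "kigali": 0.10, "south": 0.24,
                 "north": 0.17, "east": 0.25},
    "husband_desires": {"same": 0.121, "more": 0.606, "fewer": 0.179,
                        "do not know": 0.094},
}

# Default truth: the study's reported log odds ratios per level (reference
# levels implicit at 0).  Keys are (covariate, level).
DEFAULT_FIXED_EFFECTS: dict[tuple[str, str], float] = {
    ("education", "primary"): 0.1600,
    ("education", "secondary"): 0.3157,
    ("education", "tertiary"): 0.5841,
    ("wealth", "poorer"): 0.0703,
    ("wealth", "middle"): 0.2201,
    ("wealth", "richer"): 0.2998,
    ("wealth", "richest"): 0.3598,
    ("health_facility_visit", "yes"): 0.1960,
    ("residing_with_husband", "stays elsewhere"): -0.5811,
    ("living_children", "3"): -0.1217,
    ("living_children", "2"): -0.3055,
    ("living_children", "1"): -0.8057,
    ("living_children", "0"): -4.9371,
    ("religion", "catholic"): -0.3459,
    ("religion", "protestant"): 0.1338,
    ("religion", "adventist"): 0.0211,
    ("working", "yes"): 0.2394,
    ("radio", "yes"): 0.1109,
    ("fp_worker_visit", "yes"): 0.1960,
    ("newspapers", "yes"): 0.2884,
    ("province", "kigali"): 0.0548,
    ("province", "south"): -0.1224,
    ("province", "north"): 0.3580,
    ("province", "east"): 0.1704,
    ("husband_desires", "more"): 0.2622,
    ("husband_desires", "fewer"): -0.0456,
    ("husband_desires", "do not know"): 0.2073,
}


def _default_f_age(x: np.ndarray) -> np.ndarray:
    # contraceptive use declines with current age
    return -0.035 * (x - 33.0)


def _default_f_cohab(x: np.ndarray) -> np.ndarray:
    # inverted U peaking near 25 years at first cohabitation
    return 0.4 - 0.0035 * (x - 25.0) ** 2


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic survey."""

    n_women: int = 6847
    graph: AdjacencyGraph = field(default_factory=lambda: make_lattice_adjacency(5, 6))
    n_clusters: int = 492
    # None -> calibrated analytically so mean eta = logit(target_prevalence)
    # under the covariate marginals (fixed effects are reference-coded, so
    # their marginal expectation is nonzero and must be offset)
    intercept: float | None = None
    target_prevalence: float = 0.53
    fixed_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    smooth_functions: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(
        default_factory=lambda: {AGE: _default_f_age, COHAB_AGE: _default_f_cohab}
    )
    spatial_tau: float = 4.0
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    cluster_effect_sd: float = 0.0   # optional iid cluster effect, off by default
    modern_share: float = 3208 / 3610  # among users, share on a modern method
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_tau <= 0:
            raise ValueError("spatial_tau must be positive")
        if self.n_women < self.graph.n_regions:
            raise ValueError("need at least one woman per district")
        for cov, marg in self.covariate_marginals.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"marginals for {cov!r} sum to {total:.6f}, not 1"
                )
        for cov, lev in self.fixed_effects:
            if cov not in self.covariate_marginals:
                raise ValueError(f"fixed effect on unknown covariate {cov!r}")
            if lev not in self.covariate_marginals[cov]:
                raise ValueError(
                    f"fixed-effect level {lev!r} absent from marginals of {cov!r}"
                )
        if self.intercept is None:
            self.intercept = self._calibrate_intercept()

    def _calibrate_intercept(self) -> float:
        """Solve for the intercept giving the target mean success probability.

        Uses a fixed-seed Monte-Carlo draw of the non-intercept predictor
        under the spec's own marginals (the predictor distribution is
        skewed whenever effects are reference-coded, so matching the mean
        of the inverse logit, not the mean log odds, is what pins the
        prevalence down).  Deterministic: part of the spec's construction.
        """
        rng = np.random.default_rng(987654321)
        m = 200_000
        eta0 = np.zeros(m)
        for cov, marg in self.covariate_marginals.items():
            levels = list(marg)
            draws = rng.choice(len(levels), size=m,
                               p=np.asarray(list(marg.values())))
            beta = np.array([self.fixed_effects.get((cov, lev), 0.0)
                             for lev in levels])
            eta0 += beta[draws]
        age = np.clip(np.rint(rng.normal(32.8, 8.0, m)), 16, 49)
        cohab = np.minimum(np.clip(np.rint(rng.normal(21.0, 4.0, m)), 10, 49), age)
        samples = {AGE: age, COHAB_AGE: cohab}
        for cov, fn in self.smooth_functions.items():
            v = np.asarray(fn(samples[cov].astype(float)), dtype=float)
            eta0 += v - v.mean()
        target = self.target_prevalence
        lo, hi = -10.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.mean(1.0 / (1.0 + np.exp(-(mid + eta0)))) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def _draw_ages(rng: np.random.Generator, n: int, mean: float, sd: float,
               lo: int, hi: int) -> np.ndarray:
    x = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(x, lo, hi).astype(int)


def simulate_survey(spec: SimulationSpec) -> SurveyDataset:
    """Generate one survey; reproducible given ``spec.seed``.

    Smooth truth functions are centred at their sample mean before
    entering the linear predictor (the centred values are what a
    sum-to-zero-constrained fit estimates); the subtracted means are
    absorbed into the recorded intercept so the truth block's ``eta``
    equals the sum of its recorded components exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_women
    d = spec.graph.n_regions

    cols: dict[str, np.ndarray] = {}
    eta_fixed = np.zeros(n)
    for cov, marg in spec.covariate_marginals.items():
        levels = list(marg)
        draws = rng.choice(len(levels), size=n, p=np.asarray(list(marg.values())))
        vals = np.array(levels, dtype=object)[draws]
        cols[cov] = vals
        for i, lev in enumerate(levels):
            beta = spec.fixed_effects.get((cov, lev), 0.0)
            if beta:
                eta_fixed[draws == i] += beta

    cols[AGE] = _draw_ages(rng, n, 32.8, 8.0, 16, 49)
    cols[COHAB_AGE] = np.minimum(
        _draw_ages(rng, n, 21.0, 4.0, 10, 49), cols[AGE]
    )

    # districts: one guaranteed record each, remainder uniform; clusters
    # are nested within districts, assigned uniformly
    district_ids = np.array(spec.graph.region_ids)
    assign = np.concatenate(
        [np.arange(d), rng.integers(0, d, size=n - d)]
    )
    rng.shuffle(assign)
    cols[DISTRICT] = district_ids[assign]
    clusters_per = max(1, spec.n_clusters // d)
    cols[CLUSTER] = (
        assign * clusters_per + rng.integers(0, clusters_per, size=n) + 1
    )

    smooth_vals: dict[str, np.ndarray] = {}
    for cov, fn in spec.smooth_functions.items():
        v = np.asarray(fn(cols[cov].astype(float)), dtype=float)
        smooth_vals[cov] = v - v.mean()

    spatial = draw_icar_effects(spec.graph, spec.spatial_tau,
                                rng_seed=int(rng.integers(2**31 - 1)))
    eta_spat = spatial[assign]

    eta_cluster = np.zeros(n)
    if spec.cluster_effect_sd > 0:
        n_cl = d * clusters_per
        cl_eff = rng.normal(0.0, spec.cluster_effect_sd, size=n_cl + 1)
        eta_cluster = cl_eff[cols[CLUSTER]]

    eta = (
        spec.intercept
        + eta_fixed
        + sum(smooth_vals.values())
        + eta_spat
        + eta_cluster
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    cols[OUTCOME] = y

    method = np.where(y == 0, "none",
                      np.where(rng.random(n) < spec.modern_share,
                               "modern", "traditional"))
    cols["method_type"] = method

    truth = pd.DataFrame(
        {
            "eta": eta,
            "intercept": np.full(n, spec.intercept),
            "fixed": eta_fixed,
            **{f"smooth_{c}": v for c, v in smooth_vals.items()},
            "spatial": eta_spat,
            "cluster": eta_cluster,
            "p": p,
        }
    )
    truth.attrs["spatial_by_district"] = dict(
        zip(map(int, district_ids), map(float, spatial))
    )
    return SurveyDataset(df=pd.DataFrame(cols), truth=truth)


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The standard survey-like configuration with a chosen seed."""
    return SimulationSpec(seed=seed, **overrides)
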