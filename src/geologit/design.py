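"""Design structures: dummy-coded fixed effects and RW2 smooth terms.

Fixed categorical covariates enter the linear predictor through
treatment (reference-level) coding, so each reported coefficient is a
log odds ratio against a named reference category.  Continuous
covariates modelled non-parametrically enter through a second-order
random walk (RW2): the covariate is mapped onto a sorted grid of
distinct values (or equal-width bin midpoints) and the function values
``f`` over the grid carry a smoothness prior proportional to
``exp(-tau/2 * f' K f)`` with ``K = D2' D2`` built from the
second-difference operator.  ``K`` has rank ``m - 2``; its null space
holds the constant and linear vectors, so an RW2 shrinks towards a
straight line rather than towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["FixedDesign", "SmoothTerm", "encode_fixed", "rw2_penalty", "smooth_design"]


@dataclass
class FixedDesign:
    """Treatment-coded design matrix with an intercept column."""

    matrix: np.ndarray                  # n x (1 + P), float, first column ones
    column_labels: list[str]            # "intercept", then "covariate=level"
    reference_levels: dict[str, str]
    covariates: list[str]
    levels: dict[str, list[str]]        # full level sets seen at build time

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Encode new records with the training coding.

        Raises ``ValueError`` listing any level unseen at build time.
        """
        n = len(data)
        out = np.zeros((n, self.n_columns))
        out[:, 0] = 1.0
        col_of = {lab: i for i, lab in enumerate(self.column_labels)}
        for cov in self.covariates:
            vals = data[cov].astype(str)
            known = set(self.levels[cov])
            unseen = sorted(set(vals) - known)
            if unseen:
                raise ValueError(f"unseen level(s) for {cov!r}: {unseen}")
            for lev in self.levels[cov]:
                if lev == self.reference_levels[cov]:
                    continue
                out[(vals == lev).to_numpy(), col_of[f"{cov}={lev}"]] = 1.0
        return out


def encode_fixed(dataset, references: dict[str, str]) -> FixedDesign:
    """Dummy-code the categorical covariates of a survey dataset.

    Parameters
    ----------
    dataset
        A :class:`~geologit.dataset.SurveyDataset` (or anything with a
        ``df`` attribute holding the record table).
    references
        Map covariate name -> reference level.  The keys define which
        covariates enter the design and in what order; each reference
        level must occur in the data.
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    covariates = list(references)
    levels: dict[str, list[str]] = {}
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels = ["intercept"]
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in dataset")
        vals = df[cov].astype(str)
        seen = sorted(vals.unique())
        ref = str(references[cov])
        if ref not in seen:
            raise ValueError(f"reference level {ref!r} absent from {cov!r}")
        levels[cov] = seen
        for lev in seen:
            if lev == ref:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            labels.append(f"{cov}={lev}")
    return FixedDesign(
        matrix=np.column_stack(cols),
        column_labels=labels,
        reference_levels={c: str(references[c]) for c in covariates},
        covariates=covariates,
        levels=levels,
    )


def rw2_penalty(grid: int | np.ndarray) -> np.ndarray:
    """RW2 penalty matrix ``K = D2' D2`` over a sorted grid.

    ``grid`` may be the grid itself (must be strictly increasing; spacing
    is treated as equal — both survey ages are recorded in whole years)
    or simply the number of grid points.  The result is symmetric,
    positive semidefinite, of rank ``m - 2``, and annihilates the
    constant and linear vectors.
    """
    if np.ndim(grid) == 0:
        m = int(grid)
    else:
        g = np.asarray(grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        m = g.size
    if m < 3:
        raise ValueError(f"RW2 penalty needs at least 3 grid points, got {m}")
    d2 = np.zeros((m - 2, m))
    for i in range(m - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2


@dataclass
class SmoothTerm:
    """An RW2-smoothed effect of one continuous covariate."""

    covariate: str
    grid: np.ndarray            # sorted distinct values or bin midpoints, size m
    indices: np.ndarray         # record -> grid-point index, int, length n
    penalty: np.ndarray         # m x m RW2 penalty
    tau_prior: tuple[float, float] = (1.0, 0.0005)

    @property
    def m(self) -> int:
        return len(self.grid)

    @property
    def incidence(self) -> sparse.csr_matrix:
        """n x m 0/1 incidence matrix (one 1 per row)."""
        n = len(self.indices)
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), self.indices)), shape=(n, self.m)
        )

    def counts(self) -> np.ndarray:
        """Records per grid point (column sums of the incidence)."""
        return np.bincount(self.indices, minlength=self.m)


def smooth_design(dataset, covariate: str, max_grid: int = 50) -> SmoothTerm:
    """Build the RW2 smooth-term structure for one numeric covariate.

    The grid is the sorted distinct values when there are at most
    ``max_grid`` of them, else ``max_grid`` equal-width bin midpoints.
    """
    if max_grid < 3:
        raise ValueError("max_grid must be at least 3")
    df = dataset.df if hasattr(dataset, "df") else dataset
    x = np.asarray(df[covariate], dtype=float)
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError(f"covariate {covariate!r} is constant; no smooth possible")
    if distinct.size <= max_grid:
        grid = distinct
        indices = np.searchsorted(grid, x)
    else:
        edges = np.linspace(x.min(), x.max(), max_grid + 1)
        grid = 0.5 * (edges[:-1] + edges[1:])
        indices = np.clip(np.digitize(x, edges[1:-1]), 0, max_grid - 1)
    if grid.size < 3:
        raise ValueError(f"covariate {covariate!r} yields fewer than 3 grid points")
    return SmoothTerm(
        covariate=covariate,
        grid=grid,
        indices=indices.astype(np.intp),
        penalty=rw2_penalty(grid.size),
    )
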