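"""Truncated bivariate-normal selection-surface estimation.

The model: the probability of observing a substitution at a particular
(ΔΔG_fold, ΔΔG_bind) is proportional to the density of mutationally
accessible substitutions in that stability region multiplied by a
selection function evaluated there. The selection function is a bivariate
normal with parameters (μ_fold, μ_bind, σ_fold, σ_bind, ρ), truncated to
the square [−3, +3]² kcal/mol and renormalized over it. The accessible
density is an empirical histogram on a 0.25-kcal/mol grid of the same
square. Fitting is an exhaustive scan over a parameter lattice; the score
of a parameter combination is the (optionally experiment-weighted) sum of
log(accessible mass × selection probability) over the observed
substitutions, and the lattice point with the largest score is the
estimate.

Numerical policy (the data and the model both leave these open):

* selection cell probabilities are the bivariate-normal density at cell
  centers, renormalized to sum to 1 over the truncated square — without
  renormalization scores would not be comparable across σ;
* the fit maximizes, by default, the exact likelihood of the stated
  observation model: because the probability of observing a substitution
  is *proportional to* accessible mass × selection probability, the
  per-observation log probability subtracts log Σ_c acc(c)·sel(c). The
  historical scan that sums raw log products without this normalizer
  (``normalization="selection"``) is also provided; it is a
  pseudo-likelihood whose argmax is pulled toward the mean of the
  accessible pool when that pool is asymmetric, and simulation shows it
  fails to recover known surface parameters that the exact likelihood
  recovers;
* observations falling outside the square are clamped to the nearest
  boundary cell and counted in ``n_clamped``;
* accessible cells with zero mass that nevertheless contain an
  observation are floored at 1/(2·|pool|) so a single stray observation
  cannot drive every score to −∞;
* lattice ties are broken by the first maximum in lexicographic order
  (μ_fold, μ_bind, σ_fold, σ_bind, ρ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionSurfaceParams:
    """Parameters of the truncated bivariate-normal selection function."""

    mu_fold: float
    mu_bind: float
    sigma_fold: float
    sigma_bind: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma_fold <= 0 or self.sigma_bind <= 0:
            raise ValueError("sigma_fold and sigma_bind must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.mu_fold, self.mu_bind, self.sigma_fold, self.sigma_bind, self.rho)


@dataclass
class DensityGrid:
    """Empirical accessible-substitution density on a square grid.

    Cells are half-open [x, x+cell) × [y, y+cell) except the last row and
    column, which close at ``hi``. ``proportions[i, j]`` is the fraction
    of the pool in fold-cell i, bind-cell j; pool points outside the
    square carry no mass, so the total is ≤ 1.
    """

    lo: float
    hi: float
    cell: float
    proportions: np.ndarray
    n_pool: int

    @property
    def n_cells(self) -> int:
        return self.proportions.shape[0]

    def centers(self) -> np.ndarray:
        return self.lo + self.cell * (np.arange(self.n_cells) + 0.5)

    def cell_index(self, x: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to cell indices; returns (index, inside_mask).

        With ``clamp``, out-of-range coordinates map to the nearest
        boundary cell instead of being dropped.
        """
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.lo) / self.cell).astype(int)
        inside = (x >= self.lo) & (x <= self.hi)
        idx = np.where(x == self.hi, self.n_cells - 1, idx)  # hi belongs to last cell
        if clamp:
            idx = np.clip(idx, 0, self.n_cells - 1)
        return idx, inside


@dataclass(frozen=True)
class LatticeSpec:
    """The parameter lattice scanned by the fit.

    Defaults cover μ ∈ [−1, 1] step 0.1, σ ∈ [0.25, 1.5] step 0.0625 and
    ρ ∈ [−0.9, 0.9] step 0.1 (ρ = ±1 is a singular covariance and is
    excluded).
    """

    mu_fold: tuple[float, ...] = field(default_factory=lambda: _steps(-1.0, 1.0, 0.1))
    mu_bind: tuple[float, ...] = field(default_factory=lambda: _steps(-1.0, 1.0, 0.1))
    sigma_fold: tuple[float, ...] = field(default_factory=lambda: _steps(0.25, 1.5, 0.0625))
    sigma_bind: tuple[float, ...] = field(default_factory=lambda: _steps(0.25, 1.5, 0.0625))
    rho: tuple[float, ...] = field(default_factory=lambda: _steps(-0.9, 0.9, 0.1))

    def __post_init__(self) -> None:
        for name in ("mu_fold", "mu_bind", "sigma_fold", "sigma_bind", "rho"):
            if not getattr(self, name):
                raise ValueError(f"empty lattice axis {name}")
        if any(s <= 0 for s in self.sigma_fold + self.sigma_bind):
            raise ValueError("sigma lattice values must be positive")
        if any(abs(r) >= 1 for r in self.rho):
            raise ValueError("rho lattice values must satisfy |rho| < 1")

    @property
    def size(self) -> int:
        return (
            len(self.mu_fold)
            * len(self.mu_bind)
            * len(self.sigma_fold)
            * len(self.sigma_bind)
            * len(self.rho)
        )

    @classmethod
    def coarse(cls) -> "LatticeSpec":
        """A down-scaled lattice for tests and quick exploratory fits."""
        return cls(
            mu_fold=_steps(-1.0, 1.0, 0.25),
            mu_bind=_steps(-1.0, 1.0, 0.25),
            sigma_fold=(0.5, 0.75, 1.0, 1.25),
            sigma_bind=(0.5, 0.75, 1.0, 1.25),
            rho=(-0.5, 0.0, 0.5),
        )


def _steps(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(round(lo + i * step, 10) for i in range(n + 1))


@dataclass(frozen=True)
class SelectionSurfaceFit:
    best: SelectionSurfaceParams
    log_score: float
    n_clamped: int
    scan_size: int
    floored_cells: int = 0


def grid_accessible_density(
    pool: pd.DataFrame, lo: float = -3.0, hi: float = 3.0, cell: float = 0.25
) -> DensityGrid:
    """Histogram the accessible pool's (ΔΔG_fold, ΔΔG_bind) onto the grid.

    Mass in each square is count/|pool|; pool points outside the square
    are excluded from the numerator but not the denominator.
    """
    if len(pool) == 0:
        raise ValueError("empty accessible pool")
    if cell <= 0:
        raise ValueError("cell must be positive")
    n = (hi - lo) / cell
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"cell {cell} does not evenly divide [{lo}, {hi}]")
    n = int(round(n))
    x = pool["ddg_fold"].to_numpy(float)
    y = pool["ddg_bind"].to_numpy(float)
    grid = DensityGrid(lo=lo, hi=hi, cell=cell, proportions=np.zeros((n, n)), n_pool=len(pool))
    ix, in_x = grid.cell_index(x)
    iy, in_y = grid.cell_index(y)
    keep = in_x & in_y
    np.add.at(grid.proportions, (ix[keep], iy[keep]), 1.0)
    grid.proportions /= len(pool)
    return grid


def _log_bvn_kernel(
    dx: np.ndarray, dy: np.ndarray, sigma_fold: float, sigma_bind: float, rho: float
) -> np.ndarray:
    """Log bivariate-normal density up to an additive constant.

    The normalization constant cancels when cell probabilities are
    renormalized over the truncated square, so it is omitted.
    """
    u = dx / sigma_fold
    v = dy / sigma_bind
    return -(u * u - 2.0 * rho * u * v + v * v) / (2.0 * (1.0 - rho * rho))


def truncated_bvn_cell_densities(params: SelectionSurfaceParams, grid: DensityGrid) -> np.ndarray:
    """Cell probabilities of the truncated bivariate normal on the grid.

    The density is evaluated at cell centers and renormalized so the
    probabilities over the truncated square sum to 1.
    """
    c = grid.centers()
    dx = (c - params.mu_fold)[:, None]
    dy = (c - params.mu_bind)[None, :]
    logp = _log_bvn_kernel(dx, dy, params.sigma_fold, params.sigma_bind, params.rho)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def _prepare_observations(
    grid: DensityGrid, obs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Map observations to grid cells and fetch floored accessible log-mass.

    Returns (ix, iy, weights, n_clamped, floored_cells).
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    x = obs["ddg_fold"].to_numpy(float)
    y = obs["ddg_bind"].to_numpy(float)
    w = obs["weight"].to_numpy(float) if "weight" in obs.columns else np.ones(len(obs))
    if (w <= 0).any():
        raise ValueError("observation weights must be positive")
    ix, in_x = grid.cell_index(x, clamp=True)
    iy, in_y = grid.cell_index(y, clamp=True)
    n_clamped = int((~(in_x & in_y)).sum())
    floored = int((grid.proportions[ix, iy] == 0).sum())
    return ix, iy, w, n_clamped, floored


def _floored_log_mass(grid: DensityGrid, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
    mass = grid.proportions[ix, iy]
    floor = 1.0 / (2.0 * grid.n_pool)
    return np.log(np.maximum(mass, floor))


def score_params(
    params: SelectionSurfaceParams, accessible_density: DensityGrid, obs: pd.DataFrame
) -> float:
    """Weighted log-score of one parameter combination.

    Σ_i w_i · log(accessible_mass(cell_i) · selection_prob(cell_i)), with
    the clamping and flooring policies described in the module docstring.
    """
    ix, iy, w, _, _ = _prepare_observations(accessible_density, obs)
    sel = truncated_bvn_cell_densities(params, accessible_density)
    log_acc = _floored_log_mass(accessible_density, ix, iy)
    return float(np.sum(w * (log_acc + np.log(sel[ix, iy]))))


def fit_selection_surface(
    pool: pd.DataFrame | DensityGrid,
    obs: pd.DataFrame,
    scan: LatticeSpec | None = None,
    weighting: bool = True,
    normalization: str = "joint",
) -> SelectionSurfaceFit:
    """Exhaustive lattice scan for the best-scoring selection surface.

    Parameters
    ----------
    pool
        Accessible substitutions (DataFrame with ddg_fold/ddg_bind) or a
        pre-computed :class:`DensityGrid`.
    obs
        Observed substitutions; a ``weight`` column is honoured when
        ``weighting`` is True and ignored otherwise.
    scan
        Parameter lattice; defaults to the full lattice in
        :class:`LatticeSpec`.
    normalization
        ``"joint"`` (default) maximizes the exact likelihood of the
        observation model, whose per-cell probability is
        acc(c)·sel(c) / Σ_c acc(c)·sel(c); ``"selection"`` maximizes the
        raw Σ w·log(acc·sel) score (see module docstring).
    """
    if normalization not in ("joint", "selection"):
        raise ValueError(f"unknown normalization {normalization!r}")
    grid = pool if isinstance(pool, DensityGrid) else grid_accessible_density(pool)
    if scan is None:
        scan = LatticeSpec()
    if not weighting and "weight" in obs.columns:
        obs = obs.drop(columns=["weight"])
    ix, iy, w, n_clamped, floored = _prepare_observations(grid, obs)
    acc_term = float(np.sum(w * _floored_log_mass(grid, ix, iy)))

    c = grid.centers()
    mf = np.asarray(scan.mu_fold)
    mb = np.asarray(scan.mu_bind)
    # Aggregate observation weight per occupied cell to shrink the gather.
    flat = ix * grid.n_cells + iy
    uniq, inv = np.unique(flat, return_inverse=True)
    w_cell = np.zeros(len(uniq))
    np.add.at(w_cell, inv, w)
    ux, uy = uniq // grid.n_cells, uniq % grid.n_cells
    w_total = w.sum()
    acc_flat = grid.proportions.reshape(-1)

    scores = np.empty((len(mf), len(mb), len(scan.sigma_fold), len(scan.sigma_bind), len(scan.rho)))
    dx_all = c[None, :] - mf[:, None]  # (n_mf, n_cells)
    dy_all = c[None, :] - mb[:, None]
    with np.errstate(divide="ignore"):
        for i_sf, sf in enumerate(scan.sigma_fold):
            for i_sb, sb in enumerate(scan.sigma_bind):
                for i_r, r in enumerate(scan.rho):
                    u = dx_all / sf  # (n_mf, n_cells)
                    v = dy_all / sb  # (n_mb, n_cells)
                    denom = 2.0 * (1.0 - r * r)
                    # logp[mf, mb, fold_cell, bind_cell], unnormalized
                    logp = (
                        -(u * u)[:, None, :, None] / denom
                        - (v * v)[None, :, None, :] / denom
                        + (2.0 * r / denom) * u[:, None, :, None] * v[None, :, None, :]
                    )
                    p = np.exp(logp.reshape(len(mf), len(mb), -1))
                    if normalization == "joint":
                        # Z = Σ_c acc(c)·exp(q_c); truncation constant cancels
                        log_z = np.log(p @ acc_flat)
                    else:
                        log_z = np.log(p.sum(axis=-1))
                    obs_logp = logp[:, :, ux, uy]  # (n_mf, n_mb, n_obs_cells)
                    scores[:, :, i_sf, i_sb, i_r] = (
                        np.tensordot(obs_logp, w_cell, axes=([2], [0])) - w_total * log_z + acc_term
                    )
    flat_best = int(np.argmax(scores))  # first max == lexicographic tie-break
    idx = np.unravel_index(flat_best, scores.shape)
    best = SelectionSurfaceParams(
        mu_fold=scan.mu_fold[idx[0]],
        mu_bind=scan.mu_bind[idx[1]],
        sigma_fold=scan.sigma_fold[idx[2]],
        sigma_bind=scan.sigma_bind[idx[3]],
        rho=scan.rho[idx[4]],
    )
    return SelectionSurfaceFit(
        best=best,
        log_score=float(scores[idx]),
        n_clamped=n_clamped,
        scan_size=scan.size,
        floored_cells=floored,
    )


def surface_grid_table(params: SelectionSurfaceParams, grid: DensityGrid) -> pd.DataFrame:
    """Fitted-surface cell probabilities as a long (x, y, density) table."""
    sel = truncated_bvn_cell_densities(params, grid)
    c = grid.centers()
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return pd.DataFrame(
        {"ddg_fold": xx.ravel(), "ddg_bind": yy.ravel(), "density": sel.ravel()}
    )
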