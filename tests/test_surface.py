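"""Accessible-density gridding and truncated bivariate-normal surface fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phagestab.surface import (
    DensityGrid,
    LatticeSpec,
    SelectionSurfaceParams,
    fit_selection_surface,
    grid_accessible_density,
    score_params,
    surface_grid_table,
    truncated_bvn_cell_densities,
)


def frame(pairs, weights=None):
    df = pd.DataFrame(pairs, columns=["ddg_fold", "ddg_bind"])
    if weights is not None:
        df["weight"] = weights
    return df


class TestDensityGrid:
    def test_geometry(self):
        grid = grid_accessible_density(frame([(0, 0)] * 4), -3, 3, 0.25)
        assert grid.proportions.shape == (24, 24)
        assert grid.n_cells == 24

    def test_single_cell_mass(self):
        grid = grid_accessible_density(frame([(0.1, 0.1)] * 4))
        assert grid.proportions.max() == 1.0
        assert grid.proportions.sum() == 1.0

    def test_point_outside_bounds_carries_no_mass(self):
        grid = grid_accessible_density(frame([(0, 0), (1, 1), (3.26, 0)]))
        assert grid.proportions.sum() == pytest.approx(2 / 3)

    def test_hi_boundary_belongs_to_last_cell(self):
        grid = grid_accessible_density(frame([(3.0, 3.0), (0, 0)]))
        assert grid.proportions[23, 23] == 0.5

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            grid_accessible_density(frame([]))

    def test_uneven_cell_errors(self):
        with pytest.raises(ValueError):
            grid_accessible_density(frame([(0, 0)]), -3, 3, 0.37)


class TestTruncatedBvn:
    def grid(self):
        return grid_accessible_density(frame([(0, 0)]))

    def test_normalization_and_symmetry(self):
        sel = truncated_bvn_cell_densities(SelectionSurfaceParams(0, 0, 1, 1, 0), self.grid())
        assert sel.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(sel, sel.T)
        # maximum at the four central cells around the origin
        imax = np.unravel_index(sel.argmax(), sel.shape)
        assert imax[0] in (11, 12) and imax[1] in (11, 12)

    def test_matches_direct_bvn_evaluation(self):
        params = SelectionSurfaceParams(-0.4, 0.3, 0.8, 1.2, 0.35)
        grid = self.grid()
        c = grid.centers()
        xx, yy = np.meshgrid(c, c, indexing="ij")
        cov = np.array(
            [
                [0.8**2, 0.35 * 0.8 * 1.2],
                [0.35 * 0.8 * 1.2, 1.2**2],
            ]
        )
        ref = multivariate_normal(mean=[-0.4, 0.3], cov=cov).pdf(np.dstack([xx, yy]))
        ref = ref / ref.sum()
        got = truncated_bvn_cell_densities(params, grid)
        assert np.allclose(got, ref, atol=1e-12)

    def test_rho_sign_mirrors_across_bind_axis(self):
        grid = self.grid()
        pos = truncated_bvn_cell_densities(SelectionSurfaceParams(0, 0, 1, 1, 0.5), grid)
        neg = truncated_bvn_cell_densities(SelectionSurfaceParams(0, 0, 1, 1, -0.5), grid)
        assert np.allclose(pos, neg[:, ::-1], atol=1e-12)

    def test_singular_rho_rejected(self):
        with pytest.raises(ValueError):
            SelectionSurfaceParams(0, 0, 1, 1, 1.0)


def naive_score(params, grid, obs):
    """Independent per-observation loop oracle for score_params."""
    c = grid.centers()
    xx, yy = np.meshgrid(c, c, indexing="ij")
    cov = np.array(
        [
            [params.sigma_fold**2, params.rho * params.sigma_fold * params.sigma_bind],
            [params.rho * params.sigma_fold * params.sigma_bind, params.sigma_bind**2],
        ]
    )
    dens = multivariate_normal(mean=[params.mu_fold, params.mu_bind], cov=cov).pdf(
        np.dstack([xx, yy])
    )
    sel = dens / dens.sum()
    floor = 1.0 / (2 * grid.n_pool)
    total = 0.0
    for row in obs.itertuples(index=False):
        w = getattr(row, "weight", 1.0)
        ix = min(max(int(np.floor((row.ddg_fold - grid.lo) / grid.cell)), 0), grid.n_cells - 1)
        iy = min(max(int(np.floor((row.ddg_bind - grid.lo) / grid.cell)), 0), grid.n_cells - 1)
        if row.ddg_fold == grid.hi:
            ix = grid.n_cells - 1
        if row.ddg_bind == grid.hi:
            iy = grid.n_cells - 1
        acc = max(grid.proportions[ix, iy], floor)
        total += w * np.log(acc * sel[ix, iy])
    return total


class TestScoreParams:
    @pytest.fixture
    def setup(self, synth_small):
        table, _ = synth_small
        grid = grid_accessible_density(table.accessible)
        obs = table.accessible.iloc[:30][["ddg_fold", "ddg_bind"]].copy()
        obs["weight"] = np.arange(1.0, 31.0) % 3 + 1
        return grid, obs

    def test_agrees_with_naive_loop_oracle(self, setup):
        grid, obs = setup
        for params in [
            SelectionSurfaceParams(0, 0, 1, 1, 0),
            SelectionSurfaceParams(-0.5, 0.5, 0.75, 0.75, 0),
            SelectionSurfaceParams(0.3, -0.2, 0.5, 1.25, -0.4),
        ]:
            assert score_params(params, grid, obs) == pytest.approx(
                naive_score(params, grid, obs), abs=1e-9
            )

    def test_single_observation_single_cell(self):
        grid = grid_accessible_density(frame([(0.1, 0.1)] * 4))
        obs = frame([(0.1, 0.1)])
        flat = SelectionSurfaceParams(0, 0, 50.0, 50.0, 0)
        sel = truncated_bvn_cell_densities(flat, grid)
        ix, _ = grid.cell_index(np.array([0.1]))
        expected = np.log(1.0 * sel[ix[0], ix[0]])
        assert score_params(flat, grid, obs) == pytest.approx(expected, abs=1e-12)

    def test_linear_in_weights(self, setup):
        grid, obs = setup
        params = SelectionSurfaceParams(0.2, 0.1, 1, 1, 0)
        doubled = obs.copy()
        doubled["weight"] = 2 * doubled["weight"]
        assert score_params(params, grid, doubled) == pytest.approx(
            2 * score_params(params, grid, obs), rel=1e-12
        )

    def test_score_difference_is_selection_log_ratio(self, setup):
        """Accessible-mass terms cancel between two parameter settings."""
        grid, obs = setup
        a = SelectionSurfaceParams(0, 0, 1, 1, 0)
        b = SelectionSurfaceParams(0.5, -0.5, 0.75, 1.25, 0.3)
        sel_a = truncated_bvn_cell_densities(a, grid)
        sel_b = truncated_bvn_cell_densities(b, grid)
        ix, _ = grid.cell_index(obs["ddg_fold"].to_numpy(), clamp=True)
        iy, _ = grid.cell_index(obs["ddg_bind"].to_numpy(), clamp=True)
        w = obs["weight"].to_numpy()
        expected = np.sum(w * (np.log(sel_a[ix, iy]) - np.log(sel_b[ix, iy])))
        got = score_params(a, grid, obs) - score_params(b, grid, obs)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_obs_errors(self, setup):
        grid, _ = setup
        with pytest.raises(ValueError):
            score_params(SelectionSurfaceParams(0, 0, 1, 1, 0), grid, frame([]))


class TestFit:
    def test_deterministic_and_lattice_membership(self, synth_small):
        table, _ = synth_small
        obs = table.accessible.iloc[:40][["ddg_fold", "ddg_bind"]]
        scan = LatticeSpec.coarse()
        a = fit_selection_surface(table.accessible, obs, scan=scan)
        b = fit_selection_surface(table.accessible, obs, scan=scan)
        assert a.best == b.best and a.log_score == b.log_score
        assert a.best.mu_fold in scan.mu_fold and a.best.rho in scan.rho
        assert a.scan_size == scan.size

    def test_weight_one_equals_unweighted(self, synth_small):
        table, _ = synth_small
        obs = table.accessible.iloc[:40][["ddg_fold", "ddg_bind"]].copy()
        weighted = obs.copy()
        weighted["weight"] = 1.0
        scan = LatticeSpec.coarse()
        a = fit_selection_surface(table.accessible, weighted, scan=scan, weighting=True)
        b = fit_selection_surface(table.accessible, obs, scan=scan, weighting=False)
        assert a.best == b.best
        assert a.log_score == pytest.approx(b.log_score)

    def test_selection_mode_matches_score_params_at_argmax(self, synth_small):
        table, _ = synth_small
        grid = grid_accessible_density(table.accessible)
        obs = table.accessible.iloc[:40][["ddg_fold", "ddg_bind"]]
        scan = LatticeSpec.coarse()
        fit = fit_selection_surface(grid, obs, scan=scan, normalization="selection")
        assert fit.log_score == pytest.approx(score_params(fit.best, grid, obs), abs=1e-8)

    def test_all_observations_at_one_point(self, synth_small):
        """Point mass at (-0.6, 0.4): best μ is the nearest lattice point
        and σ collapses to the lattice minimum (checked against a
        brute-force scan over the same lattice)."""
        table, _ = synth_small
        grid = grid_accessible_density(table.accessible)
        obs = frame([(-0.6, 0.4)] * 25)
        scan = LatticeSpec.coarse()
        fit = fit_selection_surface(grid, obs, scan=scan, normalization="selection")
        # the occupied cell's center is (-0.625, 0.375): μ must land on a
        # lattice point within half a lattice step of it (ties possible)
        assert abs(fit.best.mu_fold - (-0.625)) <= 0.125 + 1e-9
        assert abs(fit.best.mu_bind - 0.375) <= 0.125 + 1e-9
        assert fit.best.sigma_fold == min(scan.sigma_fold)
        assert fit.best.sigma_bind == min(scan.sigma_bind)
        # brute-force oracle over the full lattice
        best = max(
            (
                score_params(SelectionSurfaceParams(mf, mb, sf, sb, r), grid, obs),
                (mf, mb, sf, sb, r),
            )
            for mf in scan.mu_fold
            for mb in scan.mu_bind
            for sf in scan.sigma_fold
            for sb in scan.sigma_bind
            for r in scan.rho
        )
        assert best[1] == fit.best.as_tuple()

    def test_clamping_counted(self, synth_small):
        table, _ = synth_small
        obs = frame([(3.26, 0.0), (0.0, 0.0)])
        fit = fit_selection_surface(table.accessible, obs, scan=LatticeSpec.coarse())
        assert fit.n_clamped == 1

    def test_symmetric_null_recovers_origin(self):
        """Uniform draws from a symmetric pool fit μ within one step of (0,0)."""
        rng = np.random.default_rng(31)
        pool = frame(rng.normal(0, 1.2, size=(3000, 2)))
        obs = pool.iloc[rng.choice(3000, 150, replace=False)]
        fit = fit_selection_surface(pool, obs, scan=LatticeSpec.coarse())
        assert abs(fit.best.mu_fold) <= 0.25 + 1e-9
        assert abs(fit.best.mu_bind) <= 0.25 + 1e-9


def test_surface_grid_table_shape(synth_small):
    table, _ = synth_small
    grid = grid_accessible_density(table.accessible)
    tbl = surface_grid_table(SelectionSurfaceParams(0, 0, 1, 1, 0), grid)
    assert len(tbl) == 576
    assert tbl["density"].sum() == pytest.approx(1.0)
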