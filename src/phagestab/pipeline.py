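"""End-to-end analysis orchestration.

``run_full_analysis`` ties the stages together: descriptive statistics
over the substitution table, zone/randomization tests for each stability
zone and observed dataset, selection-surface fits per dataset filter,
cumulative trajectories from the experiment registry, and a manifest
recording the seed and every numerical policy in force. All randomness
flows from one top-level seed; per-stage seeds are derived
deterministically from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddg_io import DdgTable, read_ddg_table
from .observed import (
    Experiment,
    experiment_weights,
    individual_effect_radius,
    read_experiment_registry,
    trajectory_table,
    weighted_observations,
)
from .randomization import randomization_test, results_table
from .stats import (
    StabilityZone,
    correlation_fold_bind,
    fraction_destabilizing,
    max_abs_deviation,
    median_effects_table,
    zone_counts,
)
from .surface import LatticeSpec, fit_selection_surface, grid_accessible_density, surface_grid_table

log = logging.getLogger("phagestab")


@dataclass
class AnalysisConfig:
    """Configuration for a full analysis run."""

    ddg_table: str
    registry: str | None = None
    cds: str | None = None
    homologs: str | None = None
    out_dir: str = "phagestab_out"
    zones: list[tuple[float, float]] = field(default_factory=lambda: [(-2.0, 2.0), (-3.5, 3.5)])
    reps: int = 10_000
    seed: int = 0
    lattice: str = "coarse"  # "coarse" | "full"
    strict: bool = False
    add_one_correction: bool = False

    def lattice_spec(self) -> LatticeSpec:
        if self.lattice == "full":
            return LatticeSpec()
        if self.lattice == "coarse":
            return LatticeSpec.coarse()
        raise ValueError(f"unknown lattice {self.lattice!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "zones" in doc:
            doc["zones"] = [tuple(z) for z in doc["zones"]]
        return cls(**doc)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n deterministic 31-bit stage seeds from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage the inputs allow and write the report bundle.

    Missing optional inputs skip their stage with a logged notice. The
    return value is the manifest (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "reps": config.reps,
        "zones": [list(z) for z in config.zones],
        "lattice": config.lattice,
        "add_one_correction": config.add_one_correction,
        "policies": {
            "zone_membership": "closed interval",
            "two_sided_p": "doubled upper-tail proportion, capped at 1",
            "surface_truncation": "renormalized over [-3,3]^2",
            "out_of_grid_observations": "clamped to nearest boundary cell",
            "zero_mass_cells": "floored at 1/(2*pool size)",
            "tie_break": "lexicographic (mu_fold, mu_bind, sigma_fold, sigma_bind, rho)",
        },
        "stages": {},
    }

    table = read_ddg_table(config.ddg_table, strict=config.strict)
    log.info("loaded ΔΔG table: %d rows, %d accessible", len(table), len(table.accessible))

    registry: list[Experiment] | None = None
    if config.registry:
        registry = read_experiment_registry(config.registry)
        log.info("loaded registry: %d experiments", len(registry))
    else:
        log.info("no experiment registry supplied; trajectory stage skipped")

    # --- summary statistics -------------------------------------------------
    acc = table.accessible
    obs = table.observed
    summary: dict = {
        "n_rows": len(table),
        "protein_length": table.protein_length,
        "n_accessible": len(acc),
        "n_observed": len(obs),
        "n_wild_phage": len(table.wild_phage),
        "n_lab_experiment": len(table.lab_experiment),
        "frac_destabilizing_fold_accessible": fraction_destabilizing(acc["ddg_fold"]),
        "frac_destabilizing_bind_accessible": fraction_destabilizing(acc["ddg_bind"]),
    }
    r, r2, pval = correlation_fold_bind(acc)
    summary.update({"r_fold_bind_accessible": r, "r2_fold_bind_accessible": r2, "p_r": pval})
    if len(obs):
        summary["max_abs_deviation_observed"] = max_abs_deviation(obs)
        summary["individual_effect_radius"] = individual_effect_radius(obs)
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest["stages"]["summary"] = summary

    median_effects_table(table).to_csv(out / "median_effects.tsv", sep="\t", index=False)

    # --- zone counts and randomization tests --------------------------------
    datasets = {}
    if len(table.wild_phage):
        datasets["wild_phage"] = table.wild_phage
    if len(table.lab_experiment):
        datasets["lab_experiment"] = table.lab_experiment
    if len(obs):
        datasets["combined"] = obs
    seeds = _stage_seeds(config.seed, len(config.zones) * max(len(datasets), 1) + 8)
    seed_iter = iter(seeds)
    rand_results: dict[str, "object"] = {}
    zone_blocks = []
    for lo, hi in config.zones:
        zone = StabilityZone(lo, hi)
        # accessible reference row first, mirroring the accessible-vs-observed
        # layout of the zone-count table
        zc = zone_counts(acc, zone)
        zone_blocks.append(
            pd.DataFrame(
                [
                    {
                        "dataset": "accessible",
                        "zone": str(zone),
                        "n": zc.n_total,
                        "prop_fold": zc.prop_fold,
                        "p_fold": np.nan,
                        "prop_bind": zc.prop_bind,
                        "p_bind": np.nan,
                        "prop_joint": zc.prop_joint,
                        "p_joint": np.nan,
                    }
                ]
            )
        )
        per_zone = {}
        for name, ds in datasets.items():
            res = randomization_test(
                ds, acc, zone, reps=config.reps, seed=next(seed_iter),
                add_one_correction=config.add_one_correction,
            )
            per_zone[name] = res
            rand_results[f"{name} {zone}"] = res
        if per_zone:
            zone_blocks.append(results_table(per_zone))
    if rand_results:
        tbl = pd.concat(zone_blocks, ignore_index=True)
        tbl.to_csv(out / "zone_tests.tsv", sep="\t", index=False)
        manifest["stages"]["randomization"] = {
            k: {"p_fold": r.p_fold, "p_bind": r.p_bind, "p_joint": r.p_joint, "seed": r.seed}
            for k, r in rand_results.items()
        }
    else:
        log.info("no observed substitutions flagged; randomization stage skipped")

    # --- selection-surface fits ----------------------------------------------
    fits: dict[str, dict] = {}
    if len(obs):
        lattice = config.lattice_spec()
        grid = grid_accessible_density(acc)
        fit_sets: dict[str, pd.DataFrame] = {}
        for name, ds in datasets.items():
            fit_sets[f"{name}_unweighted"] = ds[["ddg_fold", "ddg_bind"]].copy()
        if registry:
            for tclass in ("high", "normal"):
                w = experiment_weights(registry, temperature_class=tclass, ancestor_only=True)
                w = {k: v for k, v in w.items() if _in_table(table, k)}
                if w:
                    wo = weighted_observations(w, table)
                    fit_sets[f"{tclass}T_ancestor_weighted"] = wo
                    fit_sets[f"{tclass}T_ancestor_unweighted"] = wo.drop(columns=["weight"])
        fit_rows = []
        for name, ds in fit_sets.items():
            fit = fit_selection_surface(grid, ds, scan=lattice, weighting=True)
            fits[name] = {
                "mu_fold": fit.best.mu_fold,
                "mu_bind": fit.best.mu_bind,
                "sigma_fold": fit.best.sigma_fold,
                "sigma_bind": fit.best.sigma_bind,
                "rho": fit.best.rho,
                "log_score": fit.log_score,
                "n_clamped": fit.n_clamped,
                "floored_cells": fit.floored_cells,
                "scan_size": fit.scan_size,
            }
            fit_rows.append({"dataset": name, **fits[name]})
            surface_grid_table(fit.best, grid).to_csv(
                out / f"surface_{name}.tsv", sep="\t", index=False
            )
            log.info("surface fit %s: %s", name, fit.best)
        pd.DataFrame(fit_rows).to_csv(out / "surface_fits.tsv", sep="\t", index=False)
        manifest["stages"]["surface_fits"] = fits

    # --- trajectories ---------------------------------------------------------
    if registry:
        traj = trajectory_table(registry, table)
        traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        manifest["stages"]["trajectories"] = {
            "n_experiments": len(registry),
            "n_points": len(traj),
        }
        if len(obs):
            manifest["stages"]["trajectories"]["individual_effect_radius"] = (
                individual_effect_radius(obs)
            )

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("analysis complete in %.1fs; outputs in %s", manifest["elapsed_s"], out)
    return manifest


def _in_table(table: DdgTable, key) -> bool:
    try:
        table.lookup(key)
        return True
    except KeyError:
        return False
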