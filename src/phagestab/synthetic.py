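"""Synthetic ΔΔG tables, observed sets, and experiment registries.

The generator emulates the statistical shape of the coat-protein
substitution data so that every pipeline stage can be exercised without
the real structure-based calculations:

* a complete 19·L substitution table whose *accessible* flags come from a
  simulated coding sequence run through the single-nucleotide
  enumeration — accessibility is genetically coherent (≤ 9 targets per
  site, genetic-code transition structure), not random;
* ΔΔG_fold and ΔΔG_bind drawn independently per axis from two-component
  normal mixtures (a narrow near-zero core plus a long destabilizing
  tail), shifted so the realized destabilizing fractions among accessible
  substitutions hit their targets — defaults 0.73 (fold) and 0.70 (bind),
  matching the majority-destabilizing pattern of the real pool;
* observed sets drawn from the accessible pool with probability
  proportional to a known truncated bivariate-normal selection function,
  i.e. exactly the generative model the surface fit assumes;
* experiment registries with linear or branching segment topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddg_io import DdgTable
from .neighborhood import (
    AMINO_ACIDS,
    GENETIC_CODE,
    SubstitutionKey,
    enumerate_accessible,
)
from .observed import Experiment, Segment, TemperatureClass
from .surface import SelectionSurfaceParams, _log_bvn_kernel

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

#: Temperature mix of the laboratory-adaptation corpus this generator
#: emulates: 12 high-, 13 normal- and 4 variable-temperature experiments.
DEFAULT_TEMPERATURE_MIX: dict[str, float] = {
    "high": 12 / 29,
    "normal": 13 / 29,
    "variable": 4 / 29,
}


@dataclass(frozen=True)
class Mixture:
    """Two-component normal location-scale mixture."""

    weight: float  # mixing weight of the first (core) component
    means: tuple[float, float]
    scales: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 < self.weight < 1:
            raise ValueError("mixing weight must be in (0, 1)")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) >= self.weight  # False -> core, True -> tail
        means = np.where(comp, self.means[1], self.means[0])
        scales = np.where(comp, self.scales[1], self.scales[0])
        return rng.normal(means, scales)


@dataclass(frozen=True)
class PoolModel:
    """Generative model for a synthetic substitution pool.

    ``frac_accessible`` is the approximate accessible fraction implied by
    the genetic code (a random coding sequence reaches roughly a third of
    the 19 alternatives per site within one base change); it documents
    the expectation and is checked loosely, not enforced, because the
    flags are derived from a simulated CDS rather than drawn.
    """

    L: int = 426
    frac_accessible: float = 0.32
    fold_mixture: Mixture = field(
        default_factory=lambda: Mixture(weight=0.8, means=(0.3, 2.0), scales=(1.1, 3.2))
    )
    bind_mixture: Mixture = field(
        default_factory=lambda: Mixture(weight=0.85, means=(0.2, 1.2), scales=(0.8, 2.8))
    )
    target_frac_destabilizing_fold: float = 0.73
    target_frac_destabilizing_bind: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for t in (
            self.frac_accessible,
            self.target_frac_destabilizing_fold,
            self.target_frac_destabilizing_bind,
        ):
            if not 0 < t < 1:
                raise ValueError("proportions must lie strictly in (0, 1)")


def synth_cds(L: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG + L random sense codons."""
    codons = rng.choice(SENSE_CODONS, size=L)
    return "ATG" + "".join(codons)


def _shift_to_target(values: np.ndarray, mask: np.ndarray, target: float) -> np.ndarray:
    """Additive shift so the fraction of ``values[mask] > 0`` hits ``target``.

    The shift places the empirical (1 − target) quantile of the masked
    subset at zero, so the realized fraction matches the target to within
    one rank (≪ 2% for the pool sizes used here).
    """
    sub = np.sort(values[mask])
    n = len(sub)
    k = int(round((1 - target) * n))  # number of non-destabilizing values wanted
    if k <= 0 or k >= n:
        raise ValueError(f"target fraction {target} infeasible for n={n}")
    # place zero between the k-th and (k+1)-th order statistic
    cut = 0.5 * (sub[k - 1] + sub[k])
    return values - cut


def synth_ddg_table(model: PoolModel) -> tuple[DdgTable, str]:
    """Generate a complete synthetic 19·L table and its simulated CDS.

    Deterministic in ``model.seed``. The destabilizing fractions among
    accessible substitutions match the model targets to within ±2%.
    """
    rng = np.random.default_rng(model.seed)
    cds = synth_cds(model.L, rng)
    accessible = enumerate_accessible(cds, remove_initial_met=True)

    rows = []
    for site in range(1, model.L + 1):
        aa_from = GENETIC_CODE[cds[3 * site : 3 * site + 3]]
        for aa_to in AMINO_ACIDS:
            if aa_to == aa_from:
                continue
            rows.append(
                {
                    "site": site,
                    "aa_from": aa_from,
                    "aa_to": aa_to,
                    "accessible": int(SubstitutionKey(site, aa_from, aa_to) in accessible),
                    "wild_phage": 0,
                    "lab_experiment": 0,
                }
            )
    df = pd.DataFrame(rows)
    acc_mask = df["accessible"].to_numpy() == 1
    n = len(df)
    fold = model.fold_mixture.sample(n, rng)
    bind = model.bind_mixture.sample(n, rng)
    df["ddg_fold"] = _shift_to_target(fold, acc_mask, model.target_frac_destabilizing_fold)
    df["ddg_bind"] = _shift_to_target(bind, acc_mask, model.target_frac_destabilizing_bind)
    table = DdgTable(df, reference_id=f"synthetic-L{model.L}-seed{model.seed}")
    table.validate(strict=True)
    return table, cds


def selection_density_at(params: SelectionSurfaceParams, x: np.ndarray, y: np.ndarray,
                         lo: float = -3.0, hi: float = 3.0) -> np.ndarray:
    """Un-normalized truncated-bivariate-normal density at points; 0 outside the square."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    logp = _log_bvn_kernel(x - params.mu_fold, y - params.mu_bind,
                           params.sigma_fold, params.sigma_bind, params.rho)
    dens = np.exp(logp - logp.max())
    inside = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    return np.where(inside, dens, 0.0)


def synth_observed_under_selection(
    table: DdgTable,
    params: SelectionSurfaceParams,
    n: int,
    seed: int = 0,
    weighted: bool = False,
) -> pd.DataFrame:
    """Sample observed substitutions under a known selection surface.

    Accessible substitutions are drawn without replacement with
    probability proportional to the (truncated) selection density at
    their (ΔΔG_fold, ΔΔG_bind); optional integer weights emulate a
    substitution recurring in several experiments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    acc = table.accessible.reset_index(drop=True)
    if acc.empty:
        raise ValueError("table has no accessible substitutions")
    dens = selection_density_at(
        params, acc["ddg_fold"].to_numpy(float), acc["ddg_bind"].to_numpy(float)
    )
    positive = int((dens > 0).sum())
    if n > positive:
        raise ValueError(
            f"requested {n} draws but only {positive} accessible substitutions "
            "have positive selection density"
        )
    rng = np.random.default_rng(seed)
    p = dens / dens.sum()
    idx = rng.choice(len(acc), size=n, replace=False, p=p)
    out = acc.iloc[np.sort(idx)].reset_index(drop=True).copy()
    if weighted:
        out["weight"] = 1 + rng.poisson(0.6, size=n)
    else:
        out["weight"] = 1
    return out


def flag_observed(table: DdgTable, obs: pd.DataFrame, which: str = "wild_phage") -> DdgTable:
    """Return a copy of the table with the given flag set on the obs rows."""
    if which not in ("wild_phage", "lab_experiment"):
        raise ValueError("which must be 'wild_phage' or 'lab_experiment'")
    df = table.data.copy()
    key_cols = ["site", "aa_from", "aa_to"]
    keys = set(map(tuple, obs[key_cols].itertuples(index=False)))
    mask = df[key_cols].apply(tuple, axis=1).isin(keys)
    df.loc[mask, which] = 1
    return DdgTable(df, reference_id=table.reference_id)


@dataclass(frozen=True)
class BranchingSpec:
    """Segment topology of a synthetic experiment.

    ``n_splits = 0`` gives a linear chain of ``n_segments`` segments;
    ``n_splits = s`` gives a complete binary tree with 2^s leaves
    (each split doubles every current leaf).
    """

    n_segments: int = 3
    n_splits: int = 0
    subs_per_segment: int = 1


def synth_experiments(
    n_exp: int,
    table: DdgTable,
    seed: int = 0,
    temperature_mix: dict[str, float] | None = None,
    branching: BranchingSpec | None = None,
    selection: SelectionSurfaceParams | None = None,
) -> list[Experiment]:
    """Generate a registry of synthetic laboratory adaptations.

    Substitution lists are drawn per experiment by observed-style
    (selection-weighted) sampling from the accessible pool; temperature
    classes follow ``temperature_mix`` (default: the 12/13/4
    high/normal/variable composition of the emulated corpus).
    """
    if temperature_mix is None:
        temperature_mix = DEFAULT_TEMPERATURE_MIX
    if branching is None:
        branching = BranchingSpec()
    if selection is None:
        selection = SelectionSurfaceParams(0.0, 0.0, 1.0, 1.0, 0.0)
    classes = list(temperature_mix)
    probs = np.asarray([temperature_mix[c] for c in classes], float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    experiments = []
    for i in range(n_exp):
        tclass: TemperatureClass = classes[rng.choice(len(classes), p=probs)]  # type: ignore[assignment]
        if branching.n_splits == 0:
            seg_parents: list[tuple[str, str | None]] = [
                (f"s{j}", None if j == 0 else f"s{j - 1}")
                for j in range(branching.n_segments)
            ]
        else:
            seg_parents = [("s0", None)]
            leaves = ["s0"]
            counter = 1
            for _ in range(branching.n_splits):
                new_leaves = []
                for leaf in leaves:
                    for _ in range(2):
                        sid = f"s{counter}"
                        counter += 1
                        seg_parents.append((sid, leaf))
                        new_leaves.append(sid)
                leaves = new_leaves
        n_subs = branching.subs_per_segment * len(seg_parents)
        draws = synth_observed_under_selection(
            table, selection, n=n_subs, seed=int(rng.integers(2**31))
        )
        keys = [
            SubstitutionKey(int(r.site), r.aa_from, r.aa_to)
            for r in draws.itertuples(index=False)
        ]
        rng.shuffle(keys)  # type: ignore[arg-type]
        segments = []
        for j, (sid, parent) in enumerate(seg_parents):
            chunk = keys[j * branching.subs_per_segment : (j + 1) * branching.subs_per_segment]
            segments.append(Segment(id=sid, parent=parent, substitutions=list(chunk)))
        experiments.append(
            Experiment(
                id=f"exp{i + 1}",
                temperature_class=tclass,
                ancestor_start=bool(rng.random() < 0.6),
                source_label=chr(ord("a") + i % 26),
                segments=segments,
            )
        )
    return experiments
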