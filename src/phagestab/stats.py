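"""Descriptive statistics over ΔΔG tables.

Covers the destabilizing fractions, stability-zone membership counts,
the fold–bind correlation, per-residue median absolute effects, and the
thermodynamic-cycle arithmetic relating pentamer interaction energies to
binding stability (ΔG_bind = ΔG_interaction − n·ΔG_fold with n = 5 copies
of the coat protein per pentamer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ddg_io import DdgTable


@dataclass(frozen=True)
class StabilityZone:
    """A closed interval [lo, hi] on ΔΔG (kcal/mol) used for membership counting."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"zone requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, x: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(x) >= self.lo) & (np.asarray(x) <= self.hi)

    def __str__(self) -> str:
        return f"[{self.lo:g}, {self.hi:g}]"


@dataclass(frozen=True)
class ZoneCounts:
    """Counts of substitutions inside a zone by fold, bind, and both jointly."""

    n_total: int
    n_fold_in: int
    n_bind_in: int
    n_joint_in: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_joint_in <= min(self.n_fold_in, self.n_bind_in) <= self.n_total):
            raise ValueError(f"inconsistent zone counts: {self}")

    @property
    def prop_fold(self) -> float:
        return self.n_fold_in / self.n_total

    @property
    def prop_bind(self) -> float:
        return self.n_bind_in / self.n_total

    @property
    def prop_joint(self) -> float:
        return self.n_joint_in / self.n_total


@dataclass(frozen=True)
class FoldXEnergies:
    """Raw free energies for a reference/substituted pair of structures.

    ``dG_fold_*`` are per-monomer folding free energies and
    ``dG_interaction_*`` the pentamer interaction energies; ``n_copies``
    is the number of monomers in the complex (5 for the coat-protein
    pentamer).
    """

    dG_interaction_ref: float
    dG_interaction_sub: float
    dG_fold_ref: float
    dG_fold_sub: float
    n_copies: int = 5


def fraction_destabilizing(values) -> float:
    """Fraction of ΔΔG values strictly greater than zero.

    Values exactly at 0 count as non-destabilizing.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ΔΔG collection")
    return float(np.mean(arr > 0.0))


def zone_counts(subs: pd.DataFrame, zone: StabilityZone) -> ZoneCounts:
    """Count zone membership by ΔΔG_fold, ΔΔG_bind, and both jointly.

    ``subs`` is any DataFrame with ``ddg_fold`` and ``ddg_bind`` columns
    (e.g. ``table.accessible`` or ``table.observed``). Membership is
    closed-interval on both ends.
    """
    fold_in = zone.contains(subs["ddg_fold"].to_numpy(float))
    bind_in = zone.contains(subs["ddg_bind"].to_numpy(float))
    return ZoneCounts(
        n_total=len(subs),
        n_fold_in=int(fold_in.sum()),
        n_bind_in=int(bind_in.sum()),
        n_joint_in=int((fold_in & bind_in).sum()),
    )


def correlation_fold_bind(subs: pd.DataFrame) -> tuple[float, float, float]:
    """Pearson correlation between ΔΔG_fold and ΔΔG_bind.

    Returns ``(r, r_squared, p_value)``; the p-value uses the standard
    t-approximation for Pearson r.
    """
    x = subs["ddg_fold"].to_numpy(float)
    y = subs["ddg_bind"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 substitutions for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ddg_fold or ddg_bind")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def residue_median_effects(
    table: DdgTable,
    which: Literal["fold", "bind"] = "fold",
    pool: Literal["accessible", "all"] = "accessible",
) -> pd.Series:
    """Median |ΔΔG| per residue over the chosen substitution pool.

    Returns a Series indexed by every site 1..L; sites with no
    substitution in the pool are NaN. Medians of even-sized sets are the
    mean of the two middle values.
    """
    if not len(table.data):
        raise ValueError("empty table")
    df = table.accessible if pool == "accessible" else table.data
    col = f"ddg_{which}"
    med = df.groupby("site")[col].apply(lambda s: float(np.median(np.abs(s))))
    return med.reindex(pd.RangeIndex(1, table.protein_length + 1, name="site"))


def median_effects_table(table: DdgTable, pool: Literal["accessible", "all"] = "accessible") -> pd.DataFrame:
    """Per-site median |ΔΔG| for fold and bind, ready for TSV export."""
    return pd.DataFrame(
        {
            "median_abs_ddg_fold": residue_median_effects(table, "fold", pool),
            "median_abs_ddg_bind": residue_median_effects(table, "bind", pool),
        }
    ).reset_index()


def ddg_bind_from_cycle(e: FoldXEnergies) -> tuple[float, float]:
    """ΔΔG_fold and ΔΔG_bind from raw monomer/pentamer free energies.

    The binding free energy of one complex is
    ΔG_bind = ΔG_interaction − n_copies·ΔG_fold, and each ΔΔG is the
    substituted value minus the reference value.
    """
    ddg_fold = e.dG_fold_sub - e.dG_fold_ref
    g_bind_ref = e.dG_interaction_ref - e.n_copies * e.dG_fold_ref
    g_bind_sub = e.dG_interaction_sub - e.n_copies * e.dG_fold_sub
    return ddg_fold, g_bind_sub - g_bind_ref


def max_abs_deviation(subs: pd.DataFrame) -> float:
    """Largest |ΔΔG| over both axes — the furthest any substitution strays from 0."""
    vals = np.concatenate(
        [subs["ddg_fold"].to_numpy(float), subs["ddg_bind"].to_numpy(float)]
    )
    if vals.size == 0:
        raise ValueError("empty substitution set")
    return float(np.max(np.abs(vals)))
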