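"""Read, validate, and write ΔΔG substitution tables.

The on-disk dialect is a tab-separated file with header::

    site  aa.from  aa.to  within.1.DNA.change  wild.phg.sub  lab.exp.sub  ddG.fold  ddG.bind

``site`` is the 1-based residue index (mature-protein numbering), the three
flag columns are 0/1, and the two ΔΔG columns are free energies in kcal/mol
with the convention that positive values destabilize. In memory the columns
are normalized to ``site, aa_from, aa_to, accessible, wild_phage,
lab_experiment, ddg_fold, ddg_bind``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neighborhood import (
    AMINO_ACIDS,
    SubstitutionKey,
    enumerate_accessible,
    translate_cds,
)

#: Table dialect: file column name -> internal column name, in file order.
COLUMNS: dict[str, str] = {
    "site": "site",
    "aa.from": "aa_from",
    "aa.to": "aa_to",
    "within.1.DNA.change": "accessible",
    "wild.phg.sub": "wild_phage",
    "lab.exp.sub": "lab_experiment",
    "ddG.fold": "ddg_fold",
    "ddG.bind": "ddg_bind",
}

FLAG_COLUMNS = ("accessible", "wild_phage", "lab_experiment")


class DdgTableError(ValueError):
    """Format or validation problem in a ΔΔG table."""


@dataclass
class DdgTable:
    """A table of single amino-acid substitutions with paired ΔΔG values.

    ``data`` holds one row per substitution with normalized column names.
    A *complete* table has all 19·L rows for a protein of length L. The
    rows flagged ``accessible`` form the mutationally accessible pool; the
    union of ``wild_phage`` and ``lab_experiment`` rows forms the observed
    set.
    """

    data: pd.DataFrame
    reference_id: str = ""
    protein_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.protein_length == 0 and len(self.data):
            self.protein_length = int(self.data["site"].max())

    def __len__(self) -> int:
        return len(self.data)

    @property
    def accessible(self) -> pd.DataFrame:
        return self.data[self.data["accessible"] == 1]

    @property
    def observed(self) -> pd.DataFrame:
        return self.data[(self.data["wild_phage"] == 1) | (self.data["lab_experiment"] == 1)]

    @property
    def wild_phage(self) -> pd.DataFrame:
        return self.data[self.data["wild_phage"] == 1]

    @property
    def lab_experiment(self) -> pd.DataFrame:
        return self.data[self.data["lab_experiment"] == 1]

    def is_complete(self) -> bool:
        return len(self.data) == 19 * self.protein_length

    def keys(self) -> set[SubstitutionKey]:
        return {
            SubstitutionKey(int(r.site), r.aa_from, r.aa_to)
            for r in self.data.itertuples(index=False)
        }

    def lookup(self, key: SubstitutionKey) -> pd.Series:
        hit = self.data[
            (self.data["site"] == key.site)
            & (self.data["aa_from"] == key.aa_from)
            & (self.data["aa_to"] == key.aa_to)
        ]
        if hit.empty:
            raise KeyError(f"substitution {key.site}{key.aa_from}>{key.aa_to} not in table")
        return hit.iloc[0]

    def aa_from_by_site(self) -> dict[int, str]:
        """Reference amino acid per site; errors on conflicting aa_from."""
        out: dict[int, str] = {}
        for r in self.data.itertuples(index=False):
            prev = out.setdefault(int(r.site), r.aa_from)
            if prev != r.aa_from:
                raise DdgTableError(
                    f"site {r.site} has conflicting aa.from values {prev!r} and {r.aa_from!r}"
                )
        return out

    def validate(self, strict: bool = False) -> "DdgTable":
        df = self.data
        dup = df.duplicated(subset=["site", "aa_to"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DdgTableError(
                f"duplicate (site, aa.to) pair: site {row['site']}, aa.to {row['aa_to']}"
            )
        if len(df):
            if (df["site"] < 1).any() or (df["site"] > self.protein_length).any():
                raise DdgTableError("site out of range 1..protein_length")
            for col in ("aa_from", "aa_to"):
                bad = ~df[col].isin(list(AMINO_ACIDS))
                if bad.any():
                    raise DdgTableError(f"invalid amino acid in {col}: {df[col][bad].iloc[0]!r}")
            if (df["aa_from"] == df["aa_to"]).any():
                raise DdgTableError("row with aa.from == aa.to")
            for col in FLAG_COLUMNS:
                if not df[col].isin((0, 1)).all():
                    raise DdgTableError(f"flag column {col} contains values other than 0/1")
            for col in ("ddg_fold", "ddg_bind"):
                if not np.isfinite(df[col].to_numpy(float)).all():
                    raise DdgTableError(f"non-finite value in {col}")
        self.aa_from_by_site()
        if strict:
            if not self.is_complete():
                raise DdgTableError(
                    f"table has {len(df)} rows; a complete table for L="
                    f"{self.protein_length} needs {19 * self.protein_length}"
                )
            per_site = df.groupby("site").size()
            if (per_site != 19).any():
                site = int(per_site[per_site != 19].index[0])
                raise DdgTableError(f"site {site} has {per_site[site]} rows, expected 19")
        return self


def read_ddg_table(path: str, strict: bool = False, reference_id: str = "") -> DdgTable:
    """Parse a ΔΔG TSV file.

    In strict mode the table must be complete (19 rows per site) and all
    flag/value invariants are enforced; non-strict accepts partial tables
    such as observed-only lists.
    """
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in COLUMNS if c not in header.columns]
    if missing:
        raise DdgTableError(f"missing required column(s): {', '.join(missing)}")
    df = pd.read_csv(path, sep="\t", dtype={"site": "int64", "aa.from": str, "aa.to": str})
    for col in ("ddG.fold", "ddG.bind"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad[bad.isna() & df[col].notna()].index[0]) + 2  # header is line 1
            raise DdgTableError(f"non-numeric {col} value at line {line}") from exc
    df = df[list(COLUMNS)].rename(columns=COLUMNS)
    table = DdgTable(df, reference_id=reference_id)
    return table.validate(strict=strict)


def write_ddg_table(table: DdgTable, path: str) -> None:
    """Write a table in the TSV dialect; round-trips through read_ddg_table.

    ΔΔG values are written with 6 significant digits.
    """
    df = table.data.rename(columns={v: k for k, v in COLUMNS.items()})
    df = df[list(COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def cross_check_accessibility(table: DdgTable, cds: str) -> list[SubstitutionKey]:
    """Compare the table's accessibility flags with codon-level enumeration.

    Returns the substitution keys whose ``within.1.DNA.change`` flag
    disagrees with :func:`enumerate_accessible` run on ``cds``. The CDS
    must translate (after initiator-Met removal) to the table's reference
    protein.
    """
    protein = translate_cds(cds)
    if protein.endswith("*"):
        protein = protein[:-1]
    if not protein.startswith("M"):
        raise DdgTableError("CDS does not begin with an initiator methionine")
    mature = protein[1:]
    if len(mature) != table.protein_length:
        raise DdgTableError(
            f"CDS encodes {len(mature)} mature residues but table has L={table.protein_length}"
        )
    for site, aa in table.aa_from_by_site().items():
        if mature[site - 1] != aa:
            raise DdgTableError(
                f"aa.from mismatch at site {site}: table {aa!r}, CDS {mature[site - 1]!r}"
            )
    expected = enumerate_accessible(cds, remove_initial_met=True)
    discrepancies: list[SubstitutionKey] = []
    for r in table.data.itertuples(index=False):
        key = SubstitutionKey(int(r.site), r.aa_from, r.aa_to)
        if bool(r.accessible) != (key in expected):
            discrepancies.append(key)
    return sorted(discrepancies)
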