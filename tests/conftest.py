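import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phagestab.ddg_io import DdgTable
from phagestab.neighborhood import AMINO_ACIDS, enumerate_accessible, translate_cds
from phagestab.synthetic import PoolModel, synth_ddg_table

TOY_CDS = "ATGGCATGG"  # Met + Ala + Trp -> mature protein "AW"


def build_table_from_cds(cds: str, rng: np.random.Generator) -> DdgTable:
    """Complete 19·L table with accessibility flags derived from the CDS."""
    protein = translate_cds(cds)
    mature = protein[1:].rstrip("*")
    accessible = enumerate_accessible(cds, remove_initial_met=True)
    rows = []
    for site, aa_from in enumerate(mature, start=1):
        for aa_to in AMINO_ACIDS:
            if aa_to == aa_from:
                continue
            rows.append(
                {
                    "site": site,
                    "aa_from": aa_from,
                    "aa_to": aa_to,
                    "accessible": int((site, aa_from, aa_to) in accessible),
                    "wild_phage": 0,
                    "lab_experiment": 0,
                    "ddg_fold": float(np.round(rng.normal(0.5, 1.5), 4)),
                    "ddg_bind": float(np.round(rng.normal(0.3, 1.0), 4)),
                }
            )
    return DdgTable(pd.DataFrame(rows)).validate(strict=True)


@pytest.fixture
def toy_table() -> DdgTable:
    return build_table_from_cds(TOY_CDS, np.random.default_rng(42))


@pytest.fixture(scope="session")
def synth_small():
    """L=60 synthetic table + CDS; small enough for per-test reuse."""
    return synth_ddg_table(PoolModel(L=60, seed=7))


@pytest.fixture(scope="session")
def synth_large():
    """Full-scale synthetic table (L=426), the generator's default conditions."""
    return synth_ddg_table(PoolModel(L=426, seed=11))
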