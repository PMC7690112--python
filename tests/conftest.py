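import numpy as np
import pandas as pd
import pytest

from binqtl import sim
from binqtl.core import BinGenotypeMatrix, PhenotypeTable


@pytest.fixture
def toy_geno():
    """3 bins x 4 lines, hand-written, with one AB call."""
    bins = pd.DataFrame(
        {
            "bin": ["bin1", "bin2", "bin3"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1, 100001, 200001],
            "end": [100000, 200000, 300000],
        }
    )
    calls = pd.DataFrame(
        [
            ["AA", "AA", "BB"],
            ["BB", "BB", "BB"],
            ["AA", "AB", "AA"],
            ["BB", "BB", "AA"],
        ],
        index=["L1", "L2", "L3", "L4"],
        columns=["bin1", "bin2", "bin3"],
    )
    return BinGenotypeMatrix(bins=bins, calls=calls)


@pytest.fixture
def toy_pheno():
    rows = []
    for line, base in [("L1", 10.0), ("L2", 12.0), ("L3", 9.0), ("L4", 11.0)]:
        for rep in ("R1", "R2"):
            rows.append(
                {
                    "line": line, "trait": "SH", "density": "LD",
                    "experiment": "Ex1", "replicate": rep, "block": "B1",
                    "value": base + (0.5 if rep == "R2" else -0.5),
                }
            )
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def two_chrom_map():
    return sim.SimMapSpec(
        [sim.ChromSpec("chr1", 30, 0.05), sim.ChromSpec("chr2", 30, 0.05)]
    )


@pytest.fixture(scope="session")
def small_study(two_chrom_map):
    """One-QTL study reused by read-only tests (seeded)."""
    model = sim.TraitModel(
        "SH", mu=18.0, qtls=[sim.QtlEffect(10, 0.6)], sigma_e=1.0
    )
    return sim.make_study(
        two_chrom_map, [model], n_lines=160, n_reps=2,
        experiments=("Ex1",), seed=11,
    )


def balanced_xy(rng, n_per_cell=5, sd=1.0):
    """Random balanced 2x2 layout: (xi, xj, y) arrays."""
    xi, xj, y = [], [], []
    for si in (1, -1):
        for sj in (1, -1):
            xi += [si] * n_per_cell
            xj += [sj] * n_per_cell
            y += list(rng.normal(rng.normal(0, 2), sd, size=n_per_cell))
    return np.array(xi, float), np.array(xj, float), np.array(y)
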