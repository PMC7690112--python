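"""Core data containers shared across the package.

The analysis unit is the *bin*: a genomic segment within which all
recombinant inbred lines (RILs) share a recombination-free genotype, so a
bin behaves as a single genetic marker.  Genotype calls use the two-letter
parental codes ``AA`` ('Nipponbare' homozygote), ``BB`` ('9311' homozygote),
``AB`` (residual heterozygote) and ``NA`` (missing).  The numeric coding
used by every scan is AA = +1, BB = -1, AB/NA = NaN, so a positive additive
effect always means the Nipponbare allele increases the trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = ("SH", "FLSL", "FLL", "SLL", "RDW", "SDW")
DENSITIES = ("LD", "MD", "HD")
GENO_CODES = ("AA", "BB", "AB", "NA")

#: numeric coding used by all scans; heterozygous/missing drop out as NaN
CODE_TO_NUM = {"AA": 1.0, "BB": -1.0, "AB": np.nan, "NA": np.nan}

PHENO_KEY = ("line", "trait", "density", "experiment", "replicate")
PHENO_COLUMNS = PHENO_KEY + ("block", "value")


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Sort chromosomes numerically when labels end in digits, else lexically."""
    digits = chrom.astype(str).str.extract(r"(\d+)$", expand=False)
    if digits.notna().all():
        return digits.astype(int)
    return chrom.astype(str)


@dataclass
class BinGenotypeMatrix:
    """Ordered bins with per-line genotype calls.

    Parameters
    ----------
    bins:
        One row per bin with columns ``bin``, ``chrom``, ``start``, ``end``
        (physical coordinates, 1-based inclusive), sorted by chromosome then
        position.
    calls:
        ``lines x bins`` DataFrame of codes from :data:`GENO_CODES`; the
        index holds line ids and the columns match ``bins['bin']``.
    """

    bins: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"bin", "chrom", "start", "end"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValidationError(f"bins table missing columns: {sorted(missing)}")
        if self.bins["bin"].duplicated().any():
            dups = self.bins.loc[self.bins["bin"].duplicated(), "bin"].tolist()
            raise ValidationError(f"duplicate bin ids: {dups}")
        order = self.bins.assign(_ck=_chrom_sort_key(self.bins["chrom"]))
        sorted_idx = order.sort_values(["_ck", "start"], kind="stable").index
        if not sorted_idx.equals(self.bins.index):
            warnings.warn("bins were not sorted by chromosome/position; sorting")
            self.bins = self.bins.loc[sorted_idx].reset_index(drop=True)
            self.calls = self.calls.loc[:, self.bins["bin"]]
        if list(self.calls.columns) != list(self.bins["bin"]):
            raise ValidationError("calls columns do not match bins table")
        bad = ~self.calls.isin(GENO_CODES)
        if bad.to_numpy().any():
            rows, cols = np.nonzero(bad.to_numpy())
            cells = [
                f"(line={self.calls.index[r]}, bin={self.calls.columns[c]}, "
                f"code={self.calls.iat[r, c]!r})"
                for r, c in zip(rows[:10], cols[:10])
            ]
            raise ValidationError(
                f"unknown genotype codes at {len(rows)} cells, e.g. {', '.join(cells)}"
            )

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_bins(self) -> int:
        return self.calls.shape[1]

    @property
    def lines(self) -> list:
        return list(self.calls.index)

    @property
    def bin_ids(self) -> list:
        return list(self.bins["bin"])

    def numeric(self) -> np.ndarray:
        """Return the lines x bins matrix coded +1 (AA), -1 (BB), NaN (AB/NA)."""
        arr = self.calls.to_numpy()
        out = np.full(arr.shape, np.nan)
        out[arr == "AA"] = 1.0
        out[arr == "BB"] = -1.0
        return out

    def chrom_slices(self) -> dict:
        """Map chromosome id -> contiguous ``slice`` of bin indices."""
        out: dict = {}
        chroms = self.bins["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


@dataclass
class PhenotypeTable:
    """Long-format replicated trait observations.

    One record per (line, trait, density, experiment, replicate); ``block``
    identifies the field block the replicate sat in and ``value`` is the
    observation (cm for lengths, mg for dry weights).
    """

    df: pd.DataFrame
    traits: tuple = TRAITS
    densities: tuple = DENSITIES

    def __post_init__(self) -> None:
        missing = set(PHENO_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        bad_traits = set(self.df["trait"]) - set(self.traits)
        if bad_traits:
            raise ValidationError(f"unknown trait labels: {sorted(bad_traits)}")
        bad_dens = set(self.df["density"]) - set(self.densities)
        if bad_dens:
            raise ValidationError(f"unknown density labels: {sorted(bad_dens)}")
        vals = pd.to_numeric(self.df["value"], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            n_bad = int((~np.isfinite(vals.to_numpy(dtype=float))).sum())
            raise ValidationError(f"{n_bad} non-finite/non-numeric phenotype values")
        self.df = self.df.assign(value=vals.astype(float)).reset_index(drop=True)
        key = list(PHENO_KEY)
        if self.df.duplicated(subset=key).any():
            dup = self.df.loc[self.df.duplicated(subset=key), key].iloc[0].tolist()
            raise ValidationError(f"duplicate phenotype key, first offender: {dup}")

    @property
    def lines(self) -> list:
        return sorted(self.df["line"].unique())

    def stratum(self, trait: str, density: str | None = None,
                experiment=None) -> pd.DataFrame:
        """Subset records for one trait and optional density/experiment."""
        m = self.df["trait"] == trait
        if density is not None:
            m &= self.df["density"] == density
        if experiment is not None:
            m &= self.df["experiment"] == experiment
        return self.df.loc[m]


@dataclass
class GeneticMap:
    """Per-bin genetic positions plus per-interval recombination estimates.

    ``table`` has one row per bin: ``bin``, ``chrom``, ``cm`` (cumulative
    position within chromosome), and for each bin after the first on its
    chromosome the interval back to the previous bin: observed RIL
    recombination fraction ``R``, corrected meiotic fraction ``r`` and map
    distance ``d_cm``.
    """

    table: pd.DataFrame
    map_function: str = "haldane"

    @property
    def total_cm(self) -> float:
        return float(self.chrom_lengths().sum())

    def chrom_lengths(self) -> pd.Series:
        return self.table.groupby("chrom", sort=False)["cm"].max()


@dataclass
class ScanResult:
    """Per-bin LOD track from a composite-interval-mapping scan."""

    lod: np.ndarray
    trait: str = ""
    density: str = ""
    experiment: str = ""
    cofactors: list = field(default_factory=list)
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.lod = np.asarray(self.lod, dtype=float)
        if not np.all(np.isfinite(self.lod)) or np.any(self.lod < -1e-9):
            raise ValidationError("LOD track must be finite and non-negative")
        self.lod = np.maximum(self.lod, 0.0)
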