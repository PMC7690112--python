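"""Synthetic RIL study generator.

Emulates the design of a biparental rice RIL experiment: ~213 recombinant
inbred lines genotyped on a dense 12-chromosome bin map, phenotyped for six
seedling traits at three seeding densities (LD/MD/HD) in replicated
experiments arranged as a split-plot.  Every generated study carries its
ground truth (QTL positions, per-density additive and additive-by-additive
effects, noise levels) so downstream scans can be verified for recovery.

Genotypes are drawn as a first-order Markov chain over {AA, BB} along each
chromosome.  For selfed RILs the expected two-point recombination fraction
at meiotic fraction r is R = 2r / (1 + 2r) (Haldane-Waddington), which the
chain uses as its switch probability; this matches every two-point
expectation the downstream scans rely on without simulating generations of
selfing.

Phenotypes follow

    y = mu_d + sum_q a_q(d) * x_q + sum_p aa_p(d) * x_i * x_j
        + replicate + block + eps,

with x = +1 for AA ('Nipponbare'), -1 for BB ('9311'), 0 for AB/missing,
eps ~ N(0, sigma_e^2), and independent Normal replicate/block draws.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DENSITIES, BinGenotypeMatrix, PhenotypeTable, ValidationError

__all__ = [
    "ChromSpec",
    "SimMapSpec",
    "QtlEffect",
    "EpistaticPair",
    "TraitModel",
    "SimulatedStudy",
    "default_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "simulate_variance_components",
    "make_study",
]

EXPERIMENTS = ("Ex1", "Ex2", "Ex3")


@dataclass(frozen=True)
class ChromSpec:
    """One chromosome: number of bins and meiotic recombination per interval."""

    chrom: str
    n_bins: int
    r: float | Sequence[float]

    def interval_r(self) -> np.ndarray:
        r = np.asarray(self.r, dtype=float)
        if r.ndim == 0:
            r = np.full(self.n_bins - 1, float(r))
        if r.shape != (self.n_bins - 1,):
            raise ValidationError(
                f"{self.chrom}: need {self.n_bins - 1} interval r values, got {r.shape}"
            )
        if np.any(r < 0) or np.any(r >= 0.5):
            raise ValidationError(f"{self.chrom}: meiotic r must lie in [0, 0.5)")
        return r


@dataclass
class SimMapSpec:
    """Bin-map layout for simulation: chromosomes, bins and inter-bin r."""

    chromosomes: list[ChromSpec]
    bin_bp: int = 100_000

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("need at least one chromosome")
        for c in self.chromosomes:
            if c.n_bins < 2:
                raise ValidationError(f"{c.chrom}: need at least 2 bins")
            c.interval_r()

    @property
    def n_bins(self) -> int:
        return sum(c.n_bins for c in self.chromosomes)

    def bins_table(self) -> pd.DataFrame:
        rows = []
        k = 0
        for c in self.chromosomes:
            for j in range(c.n_bins):
                k += 1
                rows.append(
                    {
                        "bin": f"bin{k}",
                        "chrom": c.chrom,
                        "start": j * self.bin_bp + 1,
                        "end": (j + 1) * self.bin_bp,
                    }
                )
        return pd.DataFrame(rows)


def default_map(r: float = 0.005625) -> SimMapSpec:
    """12-chromosome, 2778-bin map at the scale of a dense rice RIL bin map.

    The default inter-bin meiotic fraction (0.005625, ~0.566 cM under
    Haldane) puts the genome-wide map length near 1565 cM.
    """
    sizes = [232] * 6 + [231] * 6
    return SimMapSpec(
        [ChromSpec(f"chr{i + 1}", n, r) for i, n in enumerate(sizes)]
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ril_genotypes(
    map_spec: SimMapSpec,
    n_lines: int,
    seed=None,
    het_rate: float = 0.0,
) -> BinGenotypeMatrix:
    """Draw RIL genotypes as per-chromosome Markov chains over {AA, BB}.

    Switch probability between adjacent bins is R = 2r/(1+2r); marginal
    frequencies are P(AA) = P(BB) = 0.5.  ``het_rate`` overwrites calls with
    AB independently at the given rate (default 0: fully inbred).
    """
    if n_lines < 2:
        raise ValidationError("n_lines must be >= 2")
    if not 0 <= het_rate < 1:
        raise ValidationError("het_rate must lie in [0, 1)")
    rng = _rng(seed)
    blocks = []
    for c in map_spec.chromosomes:
        r = c.interval_r()
        R = 2 * r / (1 + 2 * r)
        start = rng.integers(0, 2, size=n_lines)  # 0 -> AA, 1 -> BB
        switches = rng.random((n_lines, c.n_bins - 1)) < R[None, :]
        states = np.empty((n_lines, c.n_bins), dtype=np.int8)
        states[:, 0] = start
        np.cumsum(switches, axis=1, out=states[:, 1:], dtype=np.int8)
        states[:, 1:] = (states[:, 1:] + start[:, None]) % 2
        blocks.append(states)
    states = np.concatenate(blocks, axis=1)
    codes = np.where(states == 0, "AA", "BB").astype(object)
    if het_rate > 0:
        het = rng.random(codes.shape) < het_rate
        codes[het] = "AB"
    bins = map_spec.bins_table()
    calls = pd.DataFrame(
        codes,
        index=[f"RIL{i + 1:03d}" for i in range(n_lines)],
        columns=bins["bin"].tolist(),
    )
    return BinGenotypeMatrix(bins=bins, calls=calls)


def _per_density(value, densities, what: str) -> dict:
    """Expand a scalar or per-density mapping into a dict over densities."""
    if isinstance(value, Mapping):
        extra = set(value) - set(densities)
        if extra:
            raise ValidationError(f"{what}: unknown density labels {sorted(extra)}")
        return {d: float(value.get(d, 0.0)) for d in densities}
    return {d: float(value) for d in densities}


@dataclass
class QtlEffect:
    """Additive QTL: genome-wide bin index and effect a per density."""

    bin: int
    a: Mapping[str, float] | float


@dataclass
class EpistaticPair:
    """Additive-by-additive pair: two bin indices and aa effect per density."""

    bin_i: int
    bin_j: int
    aa: Mapping[str, float] | float


@dataclass
class TraitModel:
    """Generative model for one trait across densities."""

    trait: str
    mu: Mapping[str, float] | float = 0.0
    qtls: list[QtlEffect] = field(default_factory=list)
    epistasis: list[EpistaticPair] = field(default_factory=list)
    sigma_e: float = 1.0
    sigma_rep: float = 0.0
    sigma_block: float = 0.0

    def __post_init__(self) -> None:
        for s in (self.sigma_e, self.sigma_rep, self.sigma_block):
            if s < 0:
                raise ValidationError("noise SDs must be non-negative")


def simulate_phenotypes(
    geno: BinGenotypeMatrix,
    model: TraitModel,
    densities: Sequence[str] = DENSITIES,
    experiments: Sequence[str] = EXPERIMENTS,
    n_reps: int = 3,
    seed=None,
) -> PhenotypeTable:
    """Simulate replicated observations of one trait for all lines.

    Replicate effects are drawn per (experiment, replicate) and block
    effects per (experiment, density, replicate); the ``block`` column
    mirrors the replicate label, the simplest layout consistent with a
    split-plot randomization.
    """
    rng = _rng(seed)
    x = geno.numeric()
    x = np.nan_to_num(x, nan=0.0)  # heterozygous/missing contributes 0
    n = geno.n_lines
    for q in model.qtls + [p for p in model.epistasis]:
        idx = (q.bin,) if isinstance(q, QtlEffect) else (q.bin_i, q.bin_j)
        for b in idx:
            if not 0 <= b < geno.n_bins:
                raise ValidationError(f"truth bin index {b} outside the map")
            if np.all(x[:, b] == 0):
                warnings.warn(
                    f"truth bin {b} is heterozygous/missing in every line; "
                    "its effect is inestimable"
                )
    mu = _per_density(model.mu, densities, f"{model.trait} mu")
    genetic = {}
    for d in densities:
        g = np.full(n, mu[d])
        for q in model.qtls:
            g += _per_density(q.a, densities, "a")[d] * x[:, q.bin]
        for p in model.epistasis:
            g += _per_density(p.aa, densities, "aa")[d] * x[:, p.bin_i] * x[:, p.bin_j]
        genetic[d] = g
    rows = []
    for e in experiments:
        rep_eff = rng.normal(0.0, model.sigma_rep, size=n_reps)
        for d in densities:
            block_eff = rng.normal(0.0, model.sigma_block, size=n_reps)
            for k in range(n_reps):
                eps = rng.normal(0.0, model.sigma_e, size=n)
                vals = genetic[d] + rep_eff[k] + block_eff[k] + eps
                rows.append(
                    pd.DataFrame(
                        {
                            "line": geno.lines,
                            "trait": model.trait,
                            "density": d,
                            "experiment": e,
                            "replicate": f"R{k + 1}",
                            "block": f"B{k + 1}",
                            "value": vals,
                        }
                    )
                )
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


def simulate_variance_components(
    n_lines: int,
    n_experiments: int = 3,
    n_reps: int = 3,
    sigma2_g: float = 4.0,
    sigma2_ge: float = 2.0,
    sigma2_e: float = 3.0,
    mu: float = 0.0,
    trait: str = "SH",
    density: str = "LD",
    seed=None,
) -> PhenotypeTable:
    """Simulate y_ijk = mu + g_i + (ge)_ij + eps_ijk for heritability checks.

    Line effects g ~ N(0, sigma2_g), line-by-experiment effects
    ge ~ N(0, sigma2_ge), residuals eps ~ N(0, sigma2_e); balanced with
    ``n_reps`` replicates per line per experiment, all at one density.
    """
    rng = _rng(seed)
    g = rng.normal(0.0, np.sqrt(sigma2_g), size=n_lines)
    rows = []
    for j in range(n_experiments):
        ge = rng.normal(0.0, np.sqrt(sigma2_ge), size=n_lines)
        for k in range(n_reps):
            eps = rng.normal(0.0, np.sqrt(sigma2_e), size=n_lines)
            rows.append(
                pd.DataFrame(
                    {
                        "line": [f"RIL{i + 1:03d}" for i in range(n_lines)],
                        "trait": trait,
                        "density": density,
                        "experiment": f"Ex{j + 1}",
                        "replicate": f"R{k + 1}",
                        "block": f"B{k + 1}",
                        "value": mu + g + ge + eps,
                    }
                )
            )
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


@dataclass
class SimulatedStudy:
    """A genotype matrix, its replicated phenotypes, and the ground truth."""

    genotypes: BinGenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict

    def __post_init__(self) -> None:
        pheno_lines = set(self.phenotypes.df["line"])
        geno_lines = set(self.genotypes.lines)
        if not pheno_lines <= geno_lines:
            raise ValidationError("phenotype lines missing from genotype matrix")


def make_study(
    map_spec: SimMapSpec,
    trait_models: Sequence[TraitModel],
    n_lines: int = 213,
    densities: Sequence[str] = DENSITIES,
    experiments: Sequence[str] = EXPERIMENTS,
    n_reps: int = 3,
    seed=None,
    het_rate: float = 0.0,
) -> SimulatedStudy:
    """Bundle genotypes, multi-trait phenotypes and ground truth, seeded."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child = ss.spawn(len(trait_models) + 1)
    geno = simulate_ril_genotypes(
        map_spec, n_lines, seed=np.random.default_rng(child[0]), het_rate=het_rate
    )
    tables = []
    additive_var = {}
    for m, cs in zip(trait_models, child[1:]):
        tables.append(
            simulate_phenotypes(
                geno, m, densities=densities, experiments=experiments,
                n_reps=n_reps, seed=np.random.default_rng(cs),
            ).df
        )
        additive_var[m.trait] = {
            d: sum(_per_density(q.a, densities, "a")[d] ** 2 for q in m.qtls)
            for d in densities
        }
    pheno = PhenotypeTable(pd.concat(tables, ignore_index=True))
    truth = {
        "models": list(trait_models),
        "additive_variance": additive_var,
        "densities": list(densities),
        "experiments": list(experiments),
        "n_reps": n_reps,
    }
    return SimulatedStudy(genotypes=geno, phenotypes=pheno, truth=truth)
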