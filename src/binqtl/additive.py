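"""Genome-wide single-locus additive-effect scan.

At each bin the additive effect is half the difference between the two
homozygote class means, a = (mean_AA - mean_BB) / 2, so a positive value
means the 'Nipponbare' allele increases the trait.  Heterozygous calls are
treated as missing.  Significance is a two-stage rule: a one-way ANOVA
screen at a fixed F threshold (3.89, i.e. P <= 0.05 at df (1, 211)),
followed by per-bin permutation confirmation — a screened bin stands iff
no more than alpha * n_perm of the permuted F values exceed the observed F.
Bins are classed NIP / 9311 / NA (positive significant / negative
significant / not significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinGenotypeMatrix, ValidationError

__all__ = [
    "AdditiveScanResult",
    "f_screen_threshold",
    "additive_scan",
    "permutation_confirm",
    "classify",
    "venn_counts",
    "pae_nae",
]

F_SCREEN_DEFAULT = 3.89  # P <= 0.05 at df (1, 211), i.e. 213 lines


def f_screen_threshold(n_lines: int, alpha: float = 0.05) -> float:
    """Exact F critical value for the two-class ANOVA at df (1, n_lines - 2)."""
    return float(stats.f.ppf(1.0 - alpha, 1, n_lines - 2))


@dataclass
class AdditiveScanResult:
    """Per-bin additive effects and F statistics for one stratum."""

    table: pd.DataFrame  # bin, a, f, n_AA, n_BB, tested, screened
    trait: str = ""
    density: str = ""
    experiment: str = ""
    f_threshold: float = F_SCREEN_DEFAULT

    @property
    def screened_bins(self) -> np.ndarray:
        return self.table.index[self.table["screened"]].to_numpy()


def _as_xy(geno_or_x, trait_means):
    if isinstance(geno_or_x, BinGenotypeMatrix):
        X = geno_or_x.numeric()
        y = (
            trait_means.reindex(geno_or_x.lines).to_numpy(dtype=float)
            if isinstance(trait_means, pd.Series)
            else np.asarray(trait_means, dtype=float)
        )
    else:
        X = np.asarray(geno_or_x, dtype=float)
        y = np.asarray(trait_means, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("genotype rows and trait means are misaligned")
    return X, y


def _two_class_f(maskA, maskB, Y):
    """Vectorized two-group one-way ANOVA over bins (rows) x trait vectors.

    maskA/maskB: bins x lines boolean; Y: lines (1-D) or lines x m.
    Returns (a, F, nA, nB) with shapes bins[, m].
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    A = maskA.astype(float)
    B = maskB.astype(float)
    nA = A.sum(axis=1)[:, None]
    nB = B.sum(axis=1)[:, None]
    sA = A @ Y
    sB = B @ Y
    q = (A + B) @ (Y**2)
    n = nA + nB
    with np.errstate(divide="ignore", invalid="ignore"):
        ssb = sA**2 / nA + sB**2 / nB - (sA + sB) ** 2 / n
        ssw = q - sA**2 / nA - sB**2 / nB
        msw = ssw / (n - 2)
        f = np.where(msw > 0, ssb / msw, np.where(ssb > 0, np.inf, 0.0))
        a = (sA / nA - sB / nB) / 2.0
    if squeeze:
        return a[:, 0], f[:, 0], nA[:, 0].astype(int), nB[:, 0].astype(int)
    return a, f, nA[:, 0].astype(int), nB[:, 0].astype(int)


def additive_scan(
    geno_or_x,
    trait_means,
    f_threshold: float = F_SCREEN_DEFAULT,
    min_class: int = 2,
    trait: str = "",
    density: str = "",
    experiment: str = "",
) -> AdditiveScanResult:
    """Per-bin half-difference additive effect with the F screen applied.

    Bins with fewer than ``min_class`` lines in either homozygote class
    (including monomorphic bins) are skipped and flagged untested.
    """
    X, y = _as_xy(geno_or_x, trait_means)
    ok = np.isfinite(y)
    maskA = (X.T == 1) & ok[None, :]
    maskB = (X.T == -1) & ok[None, :]
    a, f, nA, nB = _two_class_f(maskA, maskB, np.where(ok, y, 0.0))
    tested = (nA >= min_class) & (nB >= min_class)
    a = np.where(tested, a, np.nan)
    f = np.where(tested, f, np.nan)
    table = pd.DataFrame(
        {
            "a": a,
            "f": f,
            "n_AA": nA,
            "n_BB": nB,
            "tested": tested,
            "screened": tested & (f >= f_threshold),
        }
    )
    return AdditiveScanResult(
        table=table, trait=trait, density=density, experiment=experiment,
        f_threshold=f_threshold,
    )


def permutation_confirm(
    geno_or_x,
    trait_means,
    candidates,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Permutation confirmation of screened bins (shared shuffle stream).

    Trait means are permuted over lines ``n_perm`` times; every candidate
    bin is evaluated against the same shuffle stream.  A bin is confirmed
    iff the number of permuted F values exceeding its observed F is at most
    ``alpha * n_perm``.  Returns a DataFrame indexed by candidate bin with
    columns exceed, confirmed.
    """
    X, y = _as_xy(geno_or_x, trait_means)
    candidates = np.asarray(list(candidates), dtype=int)
    if candidates.size == 0:
        return pd.DataFrame(columns=["exceed", "confirmed"])
    rng = np.random.default_rng(seed)
    ok = np.isfinite(y)
    Xv, yv = X[ok], y[ok]  # permute over lines with a trait mean only
    n = len(yv)
    maskA = Xv.T[candidates] == 1
    maskB = Xv.T[candidates] == -1
    _, f_obs, _, _ = _two_class_f(maskA, maskB, yv)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = yv[perms].T  # lines x n_perm
    _, f_perm, _, _ = _two_class_f(maskA, maskB, Yp)
    exceed = (f_perm > f_obs[:, None]).sum(axis=1)
    confirmed = exceed <= alpha * n_perm
    return pd.DataFrame(
        {"exceed": exceed, "confirmed": confirmed}, index=candidates
    )


def classify(scan: AdditiveScanResult, confirmation: pd.DataFrame) -> pd.Series:
    """Per-bin verdict: NIP (significant, a > 0), 9311 (significant, a < 0), NA."""
    verdict = pd.Series("NA", index=scan.table.index, dtype=object)
    confirmed = confirmation.index[confirmation["confirmed"]]
    pos = scan.table.loc[confirmed, "a"] > 0
    verdict.loc[confirmed[pos]] = "NIP"
    verdict.loc[confirmed[~pos.to_numpy()]] = "9311"
    return verdict


def venn_counts(ld: set, md: set, hd: set) -> dict:
    """Exclusive seven-region Venn counts of significant-bin sets."""
    ld, md, hd = set(ld), set(md), set(hd)
    return {
        "LD_only": len(ld - md - hd),
        "MD_only": len(md - ld - hd),
        "HD_only": len(hd - ld - md),
        "LD_MD": len((ld & md) - hd),
        "LD_HD": len((ld & hd) - md),
        "MD_HD": len((md & hd) - ld),
        "LD_MD_HD": len(ld & md & hd),
    }


def pae_nae(verdicts: pd.Series) -> dict:
    """Counts of bins with positive (NIP) and negative (9311) significant effects."""
    return {
        "PAE": int((verdicts == "NIP").sum()),
        "NAE": int((verdicts == "9311").sum()),
    }
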