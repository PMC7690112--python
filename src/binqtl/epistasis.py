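"""All-pairs two-locus epistasis scan (additive-by-additive interactions).

Only the four double-homozygote cells of a bin pair enter the test; AB or
missing calls at either locus exclude the line.  The interaction statistic
is the unweighted-cell-means two-way ANOVA F with sums of squares scaled by
the harmonic mean of the cell sizes:

    I      = m11 - m12 - m21 + m22          (cell-mean interaction contrast)
    n_h    = 4 / sum(1 / n_kl)              (harmonic mean cell size)
    SS_int = n_h * I^2 / 4                  (df 1)
    F      = SS_int / MSE,  MSE = pooled within-cell SS / (N_used - 4)
    aa     = I / 4

where cell 11 is (AA, AA) and 22 is (BB, BB), so a positive aa means the
parental-type combinations exceed the recombinant ones.  With balanced
cells this F is exactly the textbook two-way ANOVA interaction F.

Screening uses a fixed F threshold (11.13, P <= 0.001 near df (1, 209));
survivors are confirmed by trait permutations: a pair stands iff no more
than ``max_exceed`` (default 1) of the permuted F values beat the observed
one — with 10,000 permutations that is the P <= 1e-4 rule.  One shuffle
stream per trait is reused for every surviving pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinGenotypeMatrix, ValidationError

__all__ = [
    "EpistasisRecord",
    "PairScanResult",
    "f_pair_threshold",
    "pair_interaction_test",
    "genome_pair_scan",
    "summarize_epistasis",
]

F_PAIR_DEFAULT = 11.13  # P <= 0.001 near df (1, 209), i.e. 213 usable lines


def f_pair_threshold(n_used: int, alpha: float = 0.001) -> float:
    """Exact interaction-F critical value at df (1, n_used - 4)."""
    return float(stats.f.ppf(1.0 - alpha, 1, n_used - 4))


@dataclass
class EpistasisRecord:
    bin_i: int
    bin_j: int
    means: tuple  # (m11, m12, m21, m22); 1 = AA, 2 = BB at each locus
    counts: tuple  # (n11, n12, n21, n22)
    n_h: float
    contrast: float  # I = m11 - m12 - m21 + m22
    f: float
    aa: float
    var_pct: float
    tested: bool = True
    screened: bool = False
    exceed: int | None = None
    confirmed: bool = False

    @property
    def sign(self) -> str:
        return "positive" if self.aa > 0 else "negative"


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


def _cells(xi, xj, y):
    """Cell masks for the four double-homozygote classes."""
    ok = np.isfinite(xi) & np.isfinite(xj) & np.isfinite(y)
    return [
        ok & (xi == si) & (xj == sj)
        for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1))
    ]


def pair_interaction_test(xi, xj, y, min_cell: int = 3) -> EpistasisRecord:
    """Unweighted-cell-means interaction test for one bin pair."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    y = np.asarray(y, dtype=float)
    masks = _cells(xi, xj, y)
    counts = tuple(int(m.sum()) for m in masks)
    if min(counts) < min_cell:
        return EpistasisRecord(
            bin_i=-1, bin_j=-1, means=(np.nan,) * 4, counts=counts,
            n_h=np.nan, contrast=np.nan, f=np.nan, aa=np.nan,
            var_pct=np.nan, tested=False,
        )
    means = tuple(float(y[m].mean()) for m in masks)
    n_h = 4.0 / sum(1.0 / c for c in counts)
    contrast = means[0] - means[1] - means[2] + means[3]
    ss_int = n_h * contrast**2 / 4.0
    ssw = sum(float(((y[m] - y[m].mean()) ** 2).sum()) for m in masks)
    n_used = sum(counts)
    mse = ssw / (n_used - 4)
    if mse <= 0:
        f = np.inf if ss_int > 0 else 0.0
    else:
        f = ss_int / mse
    used = masks[0] | masks[1] | masks[2] | masks[3]
    ss_tot = float(((y[used] - y[used].mean()) ** 2).sum())
    var_pct = 100.0 * ss_int / ss_tot if ss_tot > 0 else np.nan
    return EpistasisRecord(
        bin_i=-1, bin_j=-1, means=means, counts=counts, n_h=n_h,
        contrast=contrast, f=float(f), aa=contrast / 4.0,
        var_pct=float(min(var_pct, 100.0)) if np.isfinite(var_pct) else np.nan,
    )


def _screen_all_pairs(X, y, idx, min_cell):
    """Vectorized unweighted-means interaction F for every bin pair in idx.

    Returns dict of upper-triangle matrices (F, aa, counts min, ...).
    """
    ok = np.isfinite(y)
    Xs = X[:, idx]
    A = ((Xs == 1) & ok[:, None]).T.astype(float)  # m x n indicators of AA
    B = ((Xs == -1) & ok[:, None]).T.astype(float)
    yv = np.where(ok, y, 0.0)
    y2 = yv**2

    def cell(P, Q):
        return P @ Q.T, (P * yv) @ Q.T, (P * y2) @ Q.T

    N11, S11, Q11 = cell(A, A)
    N12, S12, Q12 = cell(A, B)
    N21, S21, Q21 = cell(B, A)
    N22, S22, Q22 = cell(B, B)
    N = (N11, N12, N21, N22)
    S = (S11, S12, S21, S22)
    Q = (Q11, Q12, Q21, Q22)
    n_used = sum(N)
    min_count = np.minimum.reduce(N)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = [s / n for s, n in zip(S, N)]
        contrast = M[0] - M[1] - M[2] + M[3]
        n_h = 4.0 / sum(1.0 / n for n in N)
        ss_int = n_h * contrast**2 / 4.0
        ssw = sum(Q) - sum(s**2 / n for s, n in zip(S, N))
        mse = ssw / (n_used - 4)
        f = np.where(mse > 0, ss_int / mse, np.where(ss_int > 0, np.inf, 0.0))
        s_tot = sum(S)
        ss_tot = sum(Q) - s_tot**2 / n_used
        var_pct = np.where(ss_tot > 0, 100.0 * ss_int / ss_tot, np.nan)
    m = len(idx)
    upper = np.triu(np.ones((m, m), dtype=bool), k=1)
    tested = upper & (min_count >= min_cell) & (n_used - 4 >= 1)
    return {
        "f": f, "aa": contrast / 4.0, "contrast": contrast, "n_h": n_h,
        "means": M, "counts": N, "var_pct": var_pct,
        "tested": tested, "untested": upper & ~tested,
    }


@dataclass
class PairScanResult:
    records: list  # screened pairs as EpistasisRecord, with verdicts
    n_pairs_tested: int
    untested_pairs: list  # (bin_i, bin_j) failing the min_cell rule
    f_threshold: float
    n_perm: int
    max_exceed: int
    trait: str = ""
    density: str = ""
    experiment: str = ""


def genome_pair_scan(
    geno_or_x,
    trait_means,
    f_threshold: float = F_PAIR_DEFAULT,
    min_cell: int = 3,
    thin: int = 1,
    n_perm: int = 10_000,
    max_exceed: int = 1,
    seed=None,
    trait: str = "",
    density: str = "",
    experiment: str = "",
) -> PairScanResult:
    """Screen every retained bin pair, then permutation-confirm survivors.

    ``thin`` subsamples the bin universe with the given stride (thin = 1
    scans all pairs).  The screen is fully vectorized; confirmation shuffles
    the trait once per permutation and reuses the shuffle for every
    surviving pair.
    """
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    X, y = _as_xy(geno_or_x, trait_means)
    idx = np.arange(X.shape[1])[::thin]
    res = _screen_all_pairs(X, y, idx, min_cell)
    tested = res["tested"]
    screened = tested & (res["f"] >= f_threshold)
    si, sj = np.nonzero(screened)
    records = []
    for a, b in zip(si, sj):
        records.append(
            EpistasisRecord(
                bin_i=int(idx[a]),
                bin_j=int(idx[b]),
                means=tuple(float(m[a, b]) for m in res["means"]),
                counts=tuple(int(n[a, b]) for n in res["counts"]),
                n_h=float(res["n_h"][a, b]),
                contrast=float(res["contrast"][a, b]),
                f=float(res["f"][a, b]),
                aa=float(res["aa"][a, b]),
                var_pct=float(min(res["var_pct"][a, b], 100.0)),
                screened=True,
            )
        )
    if records and n_perm > 0:
        _confirm(X, y, records, n_perm, max_exceed, seed)
    ui, uj = np.nonzero(res["untested"])
    return PairScanResult(
        records=records,
        n_pairs_tested=int(tested.sum()),
        untested_pairs=[(int(idx[a]), int(idx[b])) for a, b in zip(ui, uj)],
        f_threshold=f_threshold,
        n_perm=n_perm,
        max_exceed=max_exceed,
        trait=trait,
        density=density,
        experiment=experiment,
    )


def _confirm(X, y, records, n_perm, max_exceed, seed) -> None:
    """Permutation confirmation, one shuffle stream shared by all pairs."""
    rng = np.random.default_rng(seed)
    ok = np.isfinite(y)
    yv = y[ok]
    n = len(yv)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = yv[perms].T  # n x n_perm
    Yp2 = Yp**2
    Xok = X[ok]
    Z = []  # per cell: pairs x n indicator
    for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        Z.append(
            np.array(
                [
                    (Xok[:, r.bin_i] == si) & (Xok[:, r.bin_j] == sj)
                    for r in records
                ],
                dtype=float,
            )
        )
    counts = [z.sum(axis=1)[:, None] for z in Z]
    S = [z @ Yp for z in Z]
    Q = sum(z @ Yp2 for z in Z)
    n_used = sum(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = [s / c for s, c in zip(S, counts)]
        contrast = M[0] - M[1] - M[2] + M[3]
        n_h = 4.0 / sum(1.0 / c for c in counts)
        ss_int = n_h * contrast**2 / 4.0
        ssw = Q - sum(s**2 / c for s, c in zip(S, counts))
        mse = ssw / (n_used - 4)
        f_perm = np.where(mse > 0, ss_int / mse, np.where(ss_int > 0, np.inf, 0.0))
    for i, rec in enumerate(records):
        exceed = int((f_perm[i] > rec.f).sum())
        rec.exceed = exceed
        rec.confirmed = exceed <= max_exceed


def summarize_epistasis(result_or_records, qtl_calls=None) -> dict:
    """PEE/NEE counts of confirmed pairs, QTL-interval links, multi-partner loci."""
    records = (
        result_or_records.records
        if isinstance(result_or_records, PairScanResult)
        else list(result_or_records)
    )
    confirmed = [r for r in records if r.confirmed]
    pee = sum(1 for r in confirmed if r.aa > 0)
    nee = sum(1 for r in confirmed if r.aa < 0)
    links = []
    if qtl_calls:
        for r in confirmed:
            for call in qtl_calls:
                hit = [
                    b for b in (r.bin_i, r.bin_j)
                    if call.ci_lo_index <= b <= call.ci_hi_index
                ]
                if hit:
                    links.append(
                        {"qtl": call.name, "bin_i": r.bin_i, "bin_j": r.bin_j,
                         "qtl_bin": hit[0], "aa": r.aa}
                    )
    partner_counts: dict = {}
    for r in confirmed:
        for b in (r.bin_i, r.bin_j):
            partner_counts[b] = partner_counts.get(b, 0) + 1
    multi = {b: c for b, c in sorted(partner_counts.items()) if c >= 2}
    return {"PEE": pee, "NEE": nee, "links": links, "multi_partner_loci": multi}
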