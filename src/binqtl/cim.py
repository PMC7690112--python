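"""Composite interval mapping on a dense bin map.

Because every bin already behaves as a marker, CIM reduces to
marker-cofactor regression: at each bin b the model

    trait_mean ~ x_b + cofactors (minus any cofactor collinear with x_b)

is compared with the cofactor-only model on the same lines, and

    LOD(b) = (n_used / 2) * log10(RSS_reduced / RSS_full).

The scan window is zero: only a cofactor identical (collinear) to the
tested bin is dropped at that position.  Cofactors are chosen by forward
selection on residual sum of squares; permutation thresholds shuffle the
trait over lines and, by default, re-select cofactors inside each
permutation so the genome-wide null is preserved.

QTL calling follows the LOD-peak rule with 1.5-LOD-drop support intervals;
a call is classed "main-effect" when LOD > 3.0 and the variance explained
exceeds 10%, otherwise "minor".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinGenotypeMatrix, ScanResult, ValidationError

__all__ = [
    "QTLCall",
    "Hotspot",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "call_qtls",
    "detect_hotspots",
]

_EPS = 1e-10


def _as_xy(geno_or_x, trait_means):
    """Accept (BinGenotypeMatrix, Series) or raw (ndarray, ndarray)."""
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


def _project_out(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residual of each column of M after least squares on C."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def select_cofactors(geno_or_x, trait_means, k: int = 3) -> list[int]:
    """Forward-select k cofactor bins by single-bin RSS reduction.

    Ties break toward the lowest bin index; selection stops early if no
    remaining bin reduces the RSS.
    """
    X, y = _as_xy(geno_or_x, trait_means)
    n, p = X.shape
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k > n // 2:
        raise ValidationError(f"k = {k} exceeds half the line count ({n // 2})")
    if np.isnan(X).any() or np.isnan(y).any():
        return _select_cofactors_masked(X, y, k)
    sel: list[int] = []
    for _ in range(k):
        C = np.column_stack([np.ones(n)] + [X[:, c] for c in sel])
        ey = _project_out(C, y[:, None])[:, 0]
        EX = _project_out(C, X)
        sxx = np.einsum("ij,ij->j", EX, EX)
        sxy = EX.T @ ey
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(sxx > _EPS * n, sxy**2 / sxx, 0.0)
        score[sel] = 0.0
        b = int(np.argmax(score))
        if score[b] <= _EPS:
            break
        sel.append(b)
    return sel


def _select_cofactors_masked(X, y, k) -> list[int]:
    """Casewise-deletion forward selection (slow path for AB/missing calls)."""
    n, p = X.shape
    sel: list[int] = []
    for _ in range(k):
        best, best_score = None, _EPS
        for b in range(p):
            if b in sel:
                continue
            cols = X[:, [b] + sel]
            mask = np.isfinite(y) & np.all(np.isfinite(cols), axis=1)
            m = int(mask.sum())
            if m < len(sel) + 3:
                continue
            C0 = np.column_stack([np.ones(m)] + [X[mask, c] for c in sel])
            C1 = np.column_stack([C0, X[mask, b]])
            r0 = y[mask] - C0 @ np.linalg.lstsq(C0, y[mask], rcond=None)[0]
            r1 = y[mask] - C1 @ np.linalg.lstsq(C1, y[mask], rcond=None)[0]
            score = (r0 @ r0 - r1 @ r1) / max(r0 @ r0, _EPS)
            if score > best_score:
                best, best_score = b, score
        if best is None:
            break
        sel.append(best)
    return sel


def _lod_pair(rss_red: float, rss_full: float, n: int) -> float:
    rss_full = max(rss_full, _EPS * max(rss_red, 1.0))
    return max(0.0, (n / 2.0) * np.log10(rss_red / rss_full))


def _scan_dense(X, y, cof: list[int]) -> np.ndarray:
    """Vectorized scan when there are no missing calls."""
    n, p = X.shape
    lod = np.zeros(p)

    def scan_with(cset: list[int], targets) -> None:
        C = np.column_stack([np.ones(n)] + [X[:, c] for c in cset])
        ey = _project_out(C, y[:, None])[:, 0]
        EX = _project_out(C, X[:, targets])
        rss0 = float(ey @ ey)
        sxx = np.einsum("ij,ij->j", EX, EX)
        sxy = EX.T @ ey
        with np.errstate(divide="ignore", invalid="ignore"):
            red = np.where(sxx > _EPS * n, sxy**2 / sxx, 0.0)
        rss_full = np.maximum(rss0 - red, _EPS * max(rss0, 1.0))
        vals = np.maximum(0.0, (n / 2.0) * np.log10(rss0 / rss_full))
        vals[sxx <= _EPS * n] = 0.0  # collinear with the conditioning set
        lod[np.atleast_1d(targets)] = vals

    others = np.setdiff1d(np.arange(p), cof)
    scan_with(cof, others)
    # at a cofactor's own position (window 0) drop that cofactor; likewise at
    # any bin collinear with a cofactor, drop the offending cofactor there
    for c in cof:
        reduced = [c2 for c2 in cof if c2 != c]
        dup = np.nonzero(np.all(X == X[:, [c]], axis=0))[0]
        scan_with(reduced, dup)
    return lod


def _scan_masked(X, y, cof: list[int]) -> np.ndarray:
    """Casewise-deletion scan (slow path for AB/missing calls)."""
    n, p = X.shape
    lod = np.zeros(p)
    dropped_note = 0
    for b in range(p):
        cset = [c for c in cof if c != b]
        cols = X[:, [b] + cset]
        mask = np.isfinite(y) & np.all(np.isfinite(cols), axis=1)
        m = int(mask.sum())
        if m < len(cset) + 3:
            continue
        xb = X[mask, b]
        C0 = np.column_stack([np.ones(m)] + [X[mask, c] for c in cset])
        # drop a cofactor collinear with the tested bin (zero residual variance)
        exb = _project_out(C0, xb[:, None])[:, 0]
        if exb @ exb <= _EPS * m:
            keep = []
            for c in cset:
                corr = np.corrcoef(xb, X[mask, c])[0, 1]
                if np.isfinite(corr) and abs(corr) > 1 - 1e-9:
                    dropped_note += 1
                    continue
                keep.append(c)
            cset = keep
            C0 = np.column_stack([np.ones(m)] + [X[mask, c] for c in cset])
        C1 = np.column_stack([C0, xb])
        r0 = y[mask] - C0 @ np.linalg.lstsq(C0, y[mask], rcond=None)[0]
        r1 = y[mask] - C1 @ np.linalg.lstsq(C1, y[mask], rcond=None)[0]
        lod[b] = _lod_pair(float(r0 @ r0), float(r1 @ r1), m)
    if dropped_note:
        warnings.warn(
            f"dropped a collinear cofactor at {dropped_note} scan position(s)"
        )
    return lod


def cim_scan(
    geno_or_x,
    trait_means,
    cofactors: list[int] | None = None,
    window_cm: float = 0.0,
    trait: str = "",
    density: str = "",
    experiment: str = "",
) -> ScanResult:
    """LOD profile of the marker-cofactor scan over all bins.

    ``window_cm`` other than 0 is not supported: on a dense bin map the
    scan positions are the markers themselves and the study design drops
    only a cofactor coincident with the tested bin.
    """
    if window_cm != 0.0:
        raise ValidationError("only window_cm = 0 is supported on a bin map")
    X, y = _as_xy(geno_or_x, trait_means)
    cof = list(cofactors) if cofactors else []
    if np.isnan(X).any() or np.isnan(y).any():
        lod = _scan_masked(X, y, cof)
    else:
        lod = _scan_dense(X, y, cof)
    return ScanResult(
        lod=lod, trait=trait, density=density, experiment=experiment, cofactors=cof
    )


def permutation_threshold(
    geno_or_x,
    trait_means,
    alpha: float = 0.05,
    n_perm: int = 1000,
    k: int = 3,
    reselect: bool = True,
    seed=None,
) -> float:
    """Genome-wide LOD threshold: (1-alpha) quantile of permuted max LOD.

    Trait means are shuffled over lines; with ``reselect`` (default) the
    cofactors are re-chosen inside every permutation, preserving the null
    of the full procedure.  The quantile uses linear (type-7) interpolation.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable threshold quantile")
    X, y = _as_xy(geno_or_x, trait_means)
    rng = np.random.default_rng(seed)
    fixed = select_cofactors(X, y, k) if not reselect else None
    maxs = np.empty(n_perm)
    dense = not (np.isnan(X).any() or np.isnan(y).any())
    for i in range(n_perm):
        yp = rng.permutation(y)
        cof = select_cofactors(X, yp, k) if reselect else fixed
        lod = _scan_dense(X, yp, cof) if dense else _scan_masked(X, yp, cof)
        maxs[i] = lod.max()
    return float(np.quantile(maxs, 1.0 - alpha))


@dataclass
class QTLCall:
    name: str
    trait: str
    density: str
    experiment: str
    chrom: str
    peak_index: int
    peak_bin: str
    position: int
    lod: float
    additive_effect: float
    var_pct: float
    ci_lo_index: int
    ci_hi_index: int
    ci_lo_bin: str
    ci_hi_bin: str
    klass: str

    def __post_init__(self) -> None:
        if not self.ci_lo_index <= self.peak_index <= self.ci_hi_index:
            raise ValidationError("support interval must contain the peak")


def _peak_effect(x: np.ndarray, y: np.ndarray):
    """Additive effect and PVE from the single-bin model at a peak."""
    mask = np.isfinite(x) & np.isfinite(y)
    xm, ym = x[mask], y[mask]
    a = (ym[xm == 1].mean() - ym[xm == -1].mean()) / 2.0
    r = np.corrcoef(xm, ym)[0, 1]
    pve = 100.0 * r**2
    return float(a), float(min(pve, 100.0))


def call_qtls(
    scan: ScanResult,
    threshold: float,
    geno: BinGenotypeMatrix,
    trait_means,
    lod_drop: float = 1.5,
    main_lod: float = 3.0,
    main_pve: float = 10.0,
) -> list[QTLCall]:
    """Call QTLs from a LOD track: peaks above threshold, 1.5-LOD intervals.

    Peaks lying inside an already-accepted call's support interval (or
    whose interval contains an accepted peak) are merged into that call.
    The additive effect and Var% come from the single-bin model at the
    peak; names follow q<TRAIT>_<chr>.<k> ordered by position.
    """
    X, y = _as_xy(geno, trait_means)
    lod = scan.lod
    chrom_of = geno.bins["chrom"].to_numpy()
    slices = geno.chrom_slices()
    candidates = []
    for chrom, sl in slices.items():
        seg = lod[sl]
        for j in range(len(seg)):
            if seg[j] <= threshold:
                continue
            left = seg[j - 1] if j > 0 else -np.inf
            right = seg[j + 1] if j + 1 < len(seg) else -np.inf
            if seg[j] > left and seg[j] >= right:  # plateau ties -> lowest index
                candidates.append(sl.start + j)
    accepted: list[dict] = []
    for b in sorted(candidates, key=lambda i: (-lod[i], i)):
        sl = slices[chrom_of[b]]
        floor = lod[b] - lod_drop
        lo = b
        while lo - 1 >= sl.start and lod[lo - 1] >= floor:
            lo -= 1
        hi = b
        while hi + 1 < sl.stop and lod[hi + 1] >= floor:
            hi += 1
        merged = any(
            (a["lo"] <= b <= a["hi"] or lo <= a["peak"] <= hi)
            and chrom_of[a["peak"]] == chrom_of[b]
            for a in accepted
        )
        if merged:
            continue
        accepted.append({"peak": b, "lo": lo, "hi": hi})
    calls = []
    per_chrom_counter: dict = {}
    for a in sorted(accepted, key=lambda d: d["peak"]):
        b = a["peak"]
        chrom = chrom_of[b]
        eff, pve = _peak_effect(X[:, b], y)
        k = per_chrom_counter.get(chrom, 0) + 1
        per_chrom_counter[chrom] = k
        chrnum = re.sub(r"\D", "", str(chrom)) or str(chrom)
        klass = "main-effect" if (lod[b] > main_lod and pve > main_pve) else "minor"
        calls.append(
            QTLCall(
                name=f"q{scan.trait or 'TRAIT'}_{chrnum}.{k}",
                trait=scan.trait,
                density=scan.density,
                experiment=scan.experiment,
                chrom=str(chrom),
                peak_index=b,
                peak_bin=geno.bins.at[b, "bin"],
                position=int(geno.bins.at[b, "start"]),
                lod=float(lod[b]),
                additive_effect=eff,
                var_pct=pve,
                ci_lo_index=a["lo"],
                ci_hi_index=a["hi"],
                ci_lo_bin=geno.bins.at[a["lo"], "bin"],
                ci_hi_bin=geno.bins.at[a["hi"], "bin"],
                klass=klass,
            )
        )
    return calls


@dataclass
class Hotspot:
    chrom: str
    lo_index: int
    hi_index: int
    traits: set = field(default_factory=set)
    members: list = field(default_factory=list)


def detect_hotspots(calls: list[QTLCall]) -> list[Hotspot]:
    """Clusters of overlapping support intervals carrying >= 2 distinct traits."""
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    hotspots = []
    for chrom, cs in by_chrom.items():
        cs = sorted(cs, key=lambda c: c.ci_lo_index)
        cluster: list[QTLCall] = []
        hi = -1
        for c in cs + [None]:
            if c is not None and (not cluster or c.ci_lo_index <= hi):
                cluster.append(c)
                hi = max(hi, c.ci_hi_index)
                continue
            if cluster:
                traits = {m.trait for m in cluster}
                if len(traits) >= 2:
                    hotspots.append(
                        Hotspot(
                            chrom=chrom,
                            lo_index=min(m.ci_lo_index for m in cluster),
                            hi_index=max(m.ci_hi_index for m in cluster),
                            traits=traits,
                            members=list(cluster),
                        )
                    )
            if c is not None:
                cluster = [c]
                hi = c.ci_hi_index
    return hotspots
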