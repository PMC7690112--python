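"""Two-point recombination estimation and genetic-map construction.

For selfed RILs the observed two-point recombination fraction R between
linked loci exceeds the meiotic fraction r because recombinants accumulate
over generations: R = 2r / (1 + 2r) (Haldane-Waddington).  The map inverts
this (r = R / (2(1 - R))) before applying a map function.  Marker order is
taken from physical bin order; no ordering algorithm is run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BinGenotypeMatrix, GeneticMap, ValidationError

__all__ = ["estimate_rf", "rf_to_cm", "build_map"]


def _ril_to_meiotic(R: np.ndarray | float):
    """Invert R = 2r/(1+2r); capped at 0.5 (unlinked)."""
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(R < 1.0, R / (2.0 * (1.0 - R)), np.inf)
    return np.minimum(r, 0.5)


def estimate_rf(geno: BinGenotypeMatrix, bin_i: int, bin_j: int):
    """Observed RIL recombination fraction between two bins and corrected r.

    R = discordant homozygote pairs / informative lines (AB and missing
    calls are excluded).  Returns ``(R, r)``.
    """
    x = geno.numeric()
    xi, xj = x[:, bin_i], x[:, bin_j]
    informative = np.isfinite(xi) & np.isfinite(xj)
    n = int(informative.sum())
    if n == 0:
        raise ValidationError(
            f"no line is homozygous at both bins {bin_i} and {bin_j}"
        )
    R = float(np.sum(xi[informative] != xj[informative]) / n)
    return R, float(_ril_to_meiotic(R))


def rf_to_cm(r: float, map_function: str = "haldane") -> float:
    """Convert a meiotic recombination fraction to map distance in cM.

    Haldane: d = -50 ln(1 - 2r).  Kosambi: d = 25 ln((1+2r)/(1-2r)).
    """
    if not 0 <= r < 0.5:
        raise ValidationError(f"r = {r} is unlinked or invalid; need r in [0, 0.5)")
    if map_function == "haldane":
        return float(-50.0 * np.log1p(-2.0 * r))
    if map_function == "kosambi":
        return float(25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r)))
    raise ValidationError(f"unknown map function {map_function!r}")


def build_map(
    geno: BinGenotypeMatrix,
    map_function: str = "haldane",
    max_cm: float = 50.0,
) -> GeneticMap:
    """Genetic map from adjacent-interval recombination, cumulative per chromosome.

    Adjacent bins whose corrected r reaches 0.5 (apparently unlinked) are
    flagged and their interval capped at ``max_cm`` with a warning.
    """
    x = geno.numeric()
    # vectorized adjacent-interval R over informative (double-homozygote) lines
    left, right = x[:, :-1], x[:, 1:]
    informative = np.isfinite(left) & np.isfinite(right)
    n_inf = informative.sum(axis=0)
    if np.any(n_inf == 0):
        bad = int(np.argmax(n_inf == 0))
        raise ValidationError(f"no informative lines for interval before bin {bad + 1}")
    R_adj = np.sum((left != right) & informative, axis=0) / n_inf
    r_adj = _ril_to_meiotic(R_adj)
    rows = []
    capped = 0
    for chrom, sl in geno.chrom_slices().items():
        cm = 0.0
        for k, b in enumerate(range(sl.start, sl.stop)):
            rec = {
                "bin": geno.bins.at[b, "bin"],
                "chrom": chrom,
                "cm": cm,
                "R": np.nan,
                "r": np.nan,
                "d_cm": np.nan,
            }
            if k > 0:
                R, r = float(R_adj[b - 1]), float(r_adj[b - 1])
                if r >= 0.5:
                    d = max_cm
                    capped += 1
                else:
                    d = min(rf_to_cm(r, map_function), max_cm)
                cm += d
                rec.update({"R": R, "r": r, "d_cm": d, "cm": cm})
            rows.append(rec)
    if capped:
        warnings.warn(
            f"{capped} adjacent interval(s) looked unlinked (r capped at 0.5); "
            f"interval length capped at {max_cm} cM"
        )
    return GeneticMap(table=pd.DataFrame(rows), map_function=map_function)
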