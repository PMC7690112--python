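"""Trait statistics: line means, G x E ANOVA, heritability, correlations.

Broad-sense heritability uses the classical expected-mean-squares method on
the balanced line x experiment ANOVA:

    sigma2_e  = MSE
    sigma2_ge = (MS_GE - MSE) / r
    sigma2_g  = (MS_G - MS_GE) / (r * n)
    H = sigma2_g / (sigma2_g + sigma2_ge / n + sigma2_e / (r * n))

with r replicates per experiment and n experiments; negative component
estimates are truncated at zero, so H always lands in [0, 1].

Line means are best linear unbiased estimates from a fixed-effects least
squares fit (line + sum-coded replicate + sum-coded block); under a
balanced design these coincide with arithmetic per-line means.  This is a
deliberate fixed-effects approximation of a mixed model with random
replicates/blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PhenotypeTable, ValidationError

__all__ = [
    "VarianceComponents",
    "HeritabilityResult",
    "GxEResult",
    "line_means",
    "line_mean_matrix",
    "gxe_anova",
    "heritability",
    "trait_correlations",
    "summarize_traits",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    r: int
    n: int

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValidationError("variance components must be >= 0")
        if self.r < 1 or self.n < 1:
            raise ValidationError("r and n must be >= 1")

    def heritability(self) -> float:
        denom = self.sigma2_g + self.sigma2_ge / self.n + self.sigma2_e / (self.r * self.n)
        return 0.0 if denom == 0 else self.sigma2_g / denom


@dataclass
class HeritabilityResult:
    H: float
    components: VarianceComponents


@dataclass
class GxEResult:
    f: float
    p: float
    df_num: int
    df_den: int
    degenerate: bool = False


def _balanced_cells(df: pd.DataFrame, a: str, b: str):
    """Cell means/counts of value over factors a x b; error if unbalanced."""
    g = df.groupby([a, b], observed=True)["value"]
    counts = g.size().unstack()
    if counts.isna().any().any() or counts.stack().nunique() != 1:
        raise ValidationError(
            f"unbalanced {a} x {b} layout; balanced replication is required"
        )
    means = g.mean().unstack()
    return means, int(counts.iat[0, 0])


def _twoway_ss(df: pd.DataFrame, a: str, b: str):
    """Balanced two-way ANOVA sums of squares for value ~ a * b."""
    means, r = _balanced_cells(df, a, b)
    if r < 2:
        raise ValidationError("interaction is not testable without replication")
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    m = means.to_numpy()
    na, nb = m.shape
    row = m.mean(axis=1)
    col = m.mean(axis=0)
    ss_a = r * nb * np.sum((row - grand) ** 2)
    ss_b = r * na * np.sum((col - grand) ** 2)
    ss_ab = r * np.sum((m - row[:, None] - col[None, :] + grand) ** 2)
    cell = df.merge(
        means.stack().rename("cell_mean").reset_index(), on=[a, b], how="left"
    )
    ss_e = float(np.sum((cell["value"] - cell["cell_mean"]) ** 2))
    return {
        "ss": (ss_a, ss_b, ss_ab, ss_e),
        "df": (na - 1, nb - 1, (na - 1) * (nb - 1), na * nb * (r - 1)),
        "levels": (na, nb),
        "r": r,
    }


def line_means(
    pheno: PhenotypeTable, trait: str, density: str, experiment
) -> pd.Series:
    """Adjusted per-line means in one trait x density x experiment stratum.

    Fits value ~ line + replicate + block by least squares with sum-to-zero
    coding for replicate and block, so each line coefficient is its mean
    averaged evenly over replicate/block levels.  The block term is dropped
    when it is aliased with replicate.
    """
    df = pheno.stratum(trait, density, experiment)
    if df.empty:
        raise ValidationError(f"no records for {trait}/{density}/{experiment}")
    lines = np.sort(df["line"].unique())
    counts = df.groupby("line").size()
    if counts.nunique() == 1 and df["block"].nunique() <= 1:
        return df.groupby("line")["value"].mean().reindex(lines)
    line_idx = pd.Categorical(df["line"], categories=lines).codes
    X = [np.zeros((len(df), len(lines)))]
    X[0][np.arange(len(df)), line_idx] = 1.0

    def sum_code(col: pd.Series) -> np.ndarray | None:
        levels = np.sort(col.unique())
        if len(levels) < 2:
            return None
        codes = pd.Categorical(col, categories=levels).codes
        Z = np.zeros((len(col), len(levels) - 1))
        for j in range(1, len(levels)):
            Z[codes == j, j - 1] = 1.0
        Z[codes == 0, :] = -1.0
        return Z

    Zr = sum_code(df["replicate"])
    if Zr is not None:
        X.append(Zr)
    aliased = (
        df.groupby("replicate")["block"].nunique().max() == 1
        and df.groupby("block")["replicate"].nunique().max() == 1
    )
    if not aliased:
        Zb = sum_code(df["block"])
        if Zb is not None:
            X.append(Zb)
    design = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(design, df["value"].to_numpy(dtype=float), rcond=None)
    return pd.Series(beta[: len(lines)], index=lines)


def line_mean_matrix(
    pheno: PhenotypeTable, density: str, experiment, traits=None
) -> pd.DataFrame:
    """Lines x traits matrix of adjusted line means for one stratum."""
    traits = traits if traits is not None else sorted(pheno.df["trait"].unique())
    cols = {}
    for t in traits:
        if not pheno.stratum(t, density, experiment).empty:
            cols[t] = line_means(pheno, t, density, experiment)
    return pd.DataFrame(cols)


def gxe_anova(pheno: PhenotypeTable, trait: str, experiment) -> GxEResult:
    """Line x density interaction F-test on replicate-level data."""
    df = pheno.stratum(trait, experiment=experiment)
    if df["density"].nunique() < 2 or df["line"].nunique() < 2:
        raise ValidationError("G x E needs >= 2 densities and >= 2 lines")
    res = _twoway_ss(df, "line", "density")
    ss_ab, ss_e = res["ss"][2], res["ss"][3]
    df_ab, df_e = res["df"][2], res["df"][3]
    if ss_e + ss_ab == 0 or df["value"].nunique() == 1:
        return GxEResult(np.nan, np.nan, df_ab, df_e, degenerate=True)
    mse = ss_e / df_e
    if mse == 0:
        return GxEResult(np.inf, 0.0, df_ab, df_e, degenerate=True)
    f = (ss_ab / df_ab) / mse
    return GxEResult(float(f), float(stats.f.sf(f, df_ab, df_e)), df_ab, df_e)


def heritability(pheno: PhenotypeTable, trait: str, density: str) -> HeritabilityResult:
    """Broad-sense heritability for one trait x density, pooling experiments."""
    df = pheno.stratum(trait, density)
    n = df["experiment"].nunique()
    if n < 2:
        raise ValidationError(
            "heritability needs >= 2 experiments to separate sigma2_ge"
        )
    res = _twoway_ss(df, "line", "experiment")
    ss_g, ss_ge, ss_e = res["ss"][0], res["ss"][2], res["ss"][3]
    df_g, df_ge, df_e = res["df"][0], res["df"][2], res["df"][3]
    r = res["r"]
    ms_g, ms_ge, mse = ss_g / df_g, ss_ge / df_ge, ss_e / df_e
    comp = VarianceComponents(
        sigma2_g=max((ms_g - ms_ge) / (r * n), 0.0),
        sigma2_ge=max((ms_ge - mse) / r, 0.0),
        sigma2_e=mse,
        r=r,
        n=n,
    )
    return HeritabilityResult(H=comp.heritability(), components=comp)


def trait_correlations(mean_matrix: pd.DataFrame):
    """Pearson correlations among trait line means, with significance stars.

    Returns (r, p, stars) DataFrames; pairwise-complete observations.
    Zero-variance traits yield NaN correlations and empty stars.
    """
    traits = list(mean_matrix.columns)
    if len(mean_matrix) < 3:
        raise ValidationError("need >= 3 lines for correlations")
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            sub = mean_matrix[[traits[i], traits[j]]].dropna()
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.iat[i, j] = r.iat[j, i] = rij
            p.iat[i, j] = p.iat[j, i] = pij
    stars = p.map(
        lambda v: "**" if v <= 0.01 else ("*" if v <= 0.05 else "")
    ).where(p.notna(), "")
    np.fill_diagonal(stars.values, "")
    return r, p, stars


def summarize_traits(
    pheno: PhenotypeTable, parents: tuple = ("NIP", "9311")
) -> pd.DataFrame:
    """Range / mean +- SD of RIL line means per trait x density x experiment,
    with parent means and a Welch t-test on replicate-level parent values."""
    rows = []
    df = pheno.df
    for (trait, density, experiment), sub in df.groupby(
        ["trait", "density", "experiment"], observed=True
    ):
        ril = sub[~sub["line"].isin(parents)]
        lm = ril.groupby("line")["value"].mean()
        row = {
            "trait": trait,
            "density": density,
            "experiment": experiment,
            "min": lm.min(),
            "max": lm.max(),
            "mean": lm.mean(),
            "sd": lm.std(ddof=1),
        }
        p1 = sub.loc[sub["line"] == parents[0], "value"]
        p2 = sub.loc[sub["line"] == parents[1], "value"]
        row[f"mean_{parents[0]}"] = p1.mean() if len(p1) else np.nan
        row[f"mean_{parents[1]}"] = p2.mean() if len(p2) else np.nan
        if len(p1) >= 2 and len(p2) >= 2:
            t, pv = stats.ttest_ind(p1, p2, equal_var=False)
            row["parent_t"], row["parent_p"] = float(t), float(pv)
        else:
            row["parent_t"], row["parent_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)
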