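"""Readers and writers for all tabular artifacts.

Readers accept tab- or comma-separated files (the delimiter is sniffed from
the header line); writers always emit tab-separated output with a fixed
column order so results are bit-stable across runs.  Physical coordinates
on disk are 1-based inclusive; all in-memory indexing is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GENO_CODES,
    PHENO_COLUMNS,
    BinGenotypeMatrix,
    GeneticMap,
    PhenotypeTable,
    ValidationError,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_map",
    "write_map",
    "write_results",
]

_GENO_META_ALIASES = {
    "bin": "bin",
    "bin_id": "bin",
    "chrom": "chrom",
    "chr": "chrom",
    "chromosome": "chrom",
    "start": "start",
    "position": "start",
    "pos": "start",
    "end": "end",
    "stop": "end",
}

VERDICTS = ("NA", "NIP", "9311")


def _sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_genotypes(path) -> BinGenotypeMatrix:
    """Read a bin-genotype table: metadata columns + one column per line.

    Metadata columns are recognized by name (bin/chrom/start[/end], any
    order, case-insensitive); every remaining column is a line.  Codes must
    come from {AA, BB, AB, NA}; empty fields parse as NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    meta_cols = {}
    line_cols = []
    for col in df.columns:
        key = _GENO_META_ALIASES.get(col.strip().lower())
        if key is not None and key not in meta_cols:
            meta_cols[key] = col
        else:
            line_cols.append(col)
    for need in ("bin", "chrom", "start"):
        if need not in meta_cols:
            raise ValidationError(f"genotype file lacks a '{need}' column")
    if not line_cols:
        raise ValidationError("genotype file has no line columns")
    bins = pd.DataFrame(
        {
            "bin": df[meta_cols["bin"]],
            "chrom": df[meta_cols["chrom"]],
            "start": pd.to_numeric(df[meta_cols["start"]]).astype(int),
        }
    )
    if "end" in meta_cols:
        bins["end"] = pd.to_numeric(df[meta_cols["end"]]).astype(int)
    else:
        bins["end"] = bins["start"]
    calls = df[line_cols].T
    calls.columns = bins["bin"].tolist()
    calls = calls.replace("", "NA")
    bad = ~calls.isin(GENO_CODES)
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        offenders = [
            f"(line={calls.index[r]}, bin={calls.columns[c]}, code={calls.iat[r, c]!r})"
            for r, c in zip(rows[:10], cols[:10])
        ]
        raise ValidationError(
            f"unknown genotype symbols at {len(rows)} cells: {', '.join(offenders)}"
        )
    return BinGenotypeMatrix(bins=bins, calls=calls)


def write_genotypes(geno: BinGenotypeMatrix, path) -> None:
    out = geno.bins.copy()
    mat = geno.calls.T  # bins x lines
    mat.index = range(len(mat))
    out = pd.concat([out.reset_index(drop=True), mat.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, traits=None, densities=None) -> PhenotypeTable:
    """Read a long-format phenotype table with the six key columns + value."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype file missing columns: {sorted(missing)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        i = int(vals.isna().idxmax())
        raise ValidationError(
            f"non-numeric phenotype value {df['value'].iloc[i]!r} at row {i + 2}"
        )
    df = df.assign(value=vals)
    kwargs = {}
    if traits is not None:
        kwargs["traits"] = tuple(traits)
    if densities is not None:
        kwargs["densities"] = tuple(densities)
    return PhenotypeTable(df[list(PHENO_COLUMNS)], **kwargs)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df[list(PHENO_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    for need in ("bin", "chrom", "cm"):
        if need not in df.columns:
            raise ValidationError(f"map file lacks a '{need}' column")
    return GeneticMap(table=df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


_QTL_COLUMNS = [
    "qtl", "trait", "density", "experiment", "chrom", "peak_bin", "position",
    "ci_lo_bin", "ci_hi_bin", "lod", "additive_effect", "var_pct", "class",
]
_ADDITIVE_COLUMNS = [
    "bin", "chrom", "trait", "density", "experiment",
    "a", "f", "n_AA", "n_BB", "verdict",
]
_EPISTASIS_COLUMNS = [
    "trait", "density", "experiment", "bin_i", "bin_j",
    "aa", "f", "var_pct", "confirmed", "sign",
]


def _check_var_pct(df: pd.DataFrame, col: str, table: str) -> None:
    if col in df.columns and len(df):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.notna() & ((v < 0) | (v > 100))
        if bad.any():
            raise ValidationError(
                f"{table}: variance-explained outside [0, 100] at rows "
                f"{df.index[bad].tolist()[:5]}"
            )


def write_results(tables: dict, out_dir, metadata: dict | None = None) -> dict:
    """Write result tables (one TSV per kind) plus a run-metadata JSON.

    ``tables`` maps a kind from {'qtl_calls', 'additive_scan', 'epistasis',
    'heritability', 'gxe', 'trait_summary', 'correlations', 'venn',
    'summary_counts'} to a DataFrame.  Known kinds are validated and written
    in a fixed column order; unknown kinds are written as-is.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layouts = {
        "qtl_calls": _QTL_COLUMNS,
        "additive_scan": _ADDITIVE_COLUMNS,
        "epistasis": _EPISTASIS_COLUMNS,
    }
    written = {}
    for kind, df in tables.items():
        df = pd.DataFrame(df)
        _check_var_pct(df, "var_pct", kind)
        if kind == "additive_scan" and len(df):
            bad = ~df["verdict"].isin(VERDICTS)
            if bad.any():
                raise ValidationError(
                    f"additive_scan: verdicts outside {VERDICTS}: "
                    f"{sorted(df.loc[bad, 'verdict'].unique())}"
                )
        if kind == "qtl_calls" and len(df):
            inside = (df["ci_lo_bin_index"] <= df["peak_bin_index"]) & (
                df["peak_bin_index"] <= df["ci_hi_bin_index"]
            ) if "ci_lo_bin_index" in df.columns else pd.Series(True, index=df.index)
            if not inside.all():
                raise ValidationError("qtl_calls: support interval must contain peak")
        cols = layouts.get(kind)
        if cols is not None:
            out = df.reindex(columns=cols) if len(df) else pd.DataFrame(columns=cols)
        else:
            out = df
        dest = out_dir / f"{kind}.tsv"
        out.to_csv(dest, sep="\t", index=False, float_format="%.6g")
        written[kind] = dest
    if metadata is not None:
        dest = out_dir / "run_metadata.json"
        with open(dest, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        written["run_metadata"] = dest
    return written
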