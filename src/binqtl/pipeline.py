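"""Config-driven end-to-end orchestration.

A run either simulates a study or loads genotype/phenotype tables, then
executes: trait statistics (line means, heritability, G x E), genetic map,
CIM QTL scan, single-locus additive scan, and the two-locus epistasis
scan, writing one TSV per result kind plus a machine-readable manifest.

One global seed fans out deterministically (numpy SeedSequence) into
per-stage child seeds, so a rerun with the same config reproduces every
table byte for byte and any stage can be replayed in isolation.
"""

from __future__ import annotations

import shutil
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import additive as addmod
from . import cim, epistasis, io, linkage, phenostats, sim
from .core import DENSITIES, ValidationError

__all__ = ["RunConfig", "StageError", "run_pipeline", "report_tables"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    out_dir: str = "binqtl_run"
    seed: int = 0
    # --- input: either simulate or load ---
    simulate: dict | None = None  # sim spec, see _build_sim_spec
    genotypes: str | None = None
    phenotypes: str | None = None
    # --- analysis scope ---
    densities: list = field(default_factory=lambda: list(DENSITIES))
    experiments: list | None = None  # None: every experiment in the data
    traits: list | None = None
    # --- thresholds / permutations ---
    lod_alpha: float = 0.05
    n_perm_lod: int = 1000
    n_cofactors: int = 3
    f_screen_additive: float = addmod.F_SCREEN_DEFAULT
    n_perm_additive: int = 1000
    f_screen_epistasis: float = epistasis.F_PAIR_DEFAULT
    n_perm_epistasis: int = 10_000
    epistasis_max_exceed: int = 1
    thin: int = 1
    min_cell: int = 3
    map_function: str = "haldane"
    run_cim: bool = True
    run_additive: bool = True
    run_epistasis: bool = True

    def __post_init__(self) -> None:
        for name in ("lod_alpha", "f_screen_additive", "f_screen_epistasis"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _build_sim_spec(conf: dict):
    """Translate the `simulate:` config block into generator inputs."""
    chroms = conf.get("chromosomes")
    if chroms:
        map_spec = sim.SimMapSpec(
            [
                sim.ChromSpec(c["chrom"], int(c["n_bins"]), float(c.get("r", 0.005625)))
                for c in chroms
            ]
        )
    else:
        map_spec = sim.default_map()
    models = []
    for m in conf.get("traits", []):
        models.append(
            sim.TraitModel(
                trait=m["trait"],
                mu=m.get("mu", 0.0),
                qtls=[sim.QtlEffect(int(q["bin"]), q["a"]) for q in m.get("qtls", [])],
                epistasis=[
                    sim.EpistaticPair(int(p["bin_i"]), int(p["bin_j"]), p["aa"])
                    for p in m.get("epistasis", [])
                ],
                sigma_e=float(m.get("sigma_e", 1.0)),
                sigma_rep=float(m.get("sigma_rep", 0.0)),
                sigma_block=float(m.get("sigma_block", 0.0)),
            )
        )
    return map_spec, models, conf


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return a manifest dict (also on disk)."""
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out_dir)
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:  # remove partial outputs, keep pre-existing directory
            for p in out_dir.glob("*.tsv"):
                p.unlink()
            (out_dir / "run_metadata.json").unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(f"{exc}\n{traceback.format_exc(limit=3)}") from exc


def _run(config: RunConfig, out_dir: Path) -> dict:
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "cim", "additive", "epistasis"), ss.spawn(4)
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "counts": {},
    }
    tables: dict = {}

    # ---- stage: input -------------------------------------------------
    try:
        if config.simulate is not None:
            map_spec, models, conf = _build_sim_spec(config.simulate)
            study = sim.make_study(
                map_spec,
                models,
                n_lines=int(conf.get("n_lines", 213)),
                densities=config.densities,
                experiments=conf.get("experiments", list(sim.EXPERIMENTS)),
                n_reps=int(conf.get("n_reps", 3)),
                seed=seeds["simulate"],
            )
            geno, pheno = study.genotypes, study.phenotypes
            io.write_genotypes(geno, out_dir / "genotypes.tsv")
            io.write_phenotypes(pheno, out_dir / "phenotypes.tsv")
        elif config.genotypes and config.phenotypes:
            geno = io.read_genotypes(config.genotypes)
            pheno = io.read_phenotypes(config.phenotypes)
        else:
            raise ValidationError(
                "config needs either a `simulate` block or genotype+phenotype paths"
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[input] {exc}") from exc

    traits = config.traits or sorted(pheno.df["trait"].unique())
    experiments = config.experiments or sorted(pheno.df["experiment"].unique())
    densities = [d for d in config.densities if d in set(pheno.df["density"])]
    manifest["counts"].update(
        {"lines": geno.n_lines, "bins": geno.n_bins, "traits": len(traits)}
    )

    # ---- stage: phenostats --------------------------------------------
    try:
        tables["trait_summary"] = phenostats.summarize_traits(pheno)
        herit_rows, gxe_rows = [], []
        for t in traits:
            for d in densities:
                if pheno.stratum(t, d)["experiment"].nunique() >= 2:
                    h = phenostats.heritability(pheno, t, d)
                    herit_rows.append(
                        {
                            "trait": t, "density": d,
                            "H_pct": 100.0 * h.H,
                            "sigma2_g": h.components.sigma2_g,
                            "sigma2_ge": h.components.sigma2_ge,
                            "sigma2_e": h.components.sigma2_e,
                        }
                    )
            for e in experiments:
                try:
                    g = phenostats.gxe_anova(pheno, t, e)
                    gxe_rows.append(
                        {"trait": t, "experiment": e, "f": g.f, "p": g.p,
                         "degenerate": g.degenerate}
                    )
                except ValidationError:
                    pass
        tables["heritability"] = pd.DataFrame(herit_rows)
        tables["gxe"] = pd.DataFrame(gxe_rows)
        means = {
            (t, d, e): phenostats.line_means(pheno, t, d, e)
            for t in traits for d in densities for e in experiments
            if not pheno.stratum(t, d, e).empty
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[phenostats] {exc}") from exc

    # ---- stage: map ----------------------------------------------------
    try:
        gmap = linkage.build_map(geno, map_function=config.map_function)
        io.write_map(gmap, out_dir / "genetic_map.tsv")
        manifest["counts"]["map_cm"] = round(gmap.total_cm, 2)
    except Exception as exc:
        raise StageError(f"[map] {exc}") from exc

    # ---- stage: scan-qtl ----------------------------------------------
    all_calls = []
    if config.run_cim:
        try:
            lod_rows = []
            for (t, d, e), y in means.items():
                cof = cim.select_cofactors(geno, y, config.n_cofactors)
                scan = cim.cim_scan(geno, y, cof, trait=t, density=d, experiment=e)
                thr = cim.permutation_threshold(
                    geno, y, alpha=config.lod_alpha, n_perm=config.n_perm_lod,
                    k=config.n_cofactors, seed=seeds["cim"],
                )
                calls = cim.call_qtls(scan, thr, geno, y)
                all_calls.extend(calls)
                lod_rows.append(
                    pd.DataFrame(
                        {"bin": geno.bin_ids, "trait": t, "density": d,
                         "experiment": e, "lod": scan.lod, "threshold": thr}
                    )
                )
            tables["lod_track"] = (
                pd.concat(lod_rows, ignore_index=True) if lod_rows else pd.DataFrame()
            )
            tables["qtl_calls"] = pd.DataFrame(
                [
                    {
                        "qtl": c.name, "trait": c.trait, "density": c.density,
                        "experiment": c.experiment, "chrom": c.chrom,
                        "peak_bin": c.peak_bin, "position": c.position,
                        "ci_lo_bin": c.ci_lo_bin, "ci_hi_bin": c.ci_hi_bin,
                        "lod": c.lod, "additive_effect": c.additive_effect,
                        "var_pct": c.var_pct, "class": c.klass,
                    }
                    for c in all_calls
                ]
            )
            hs = cim.detect_hotspots(all_calls)
            tables["hotspots"] = pd.DataFrame(
                [
                    {"chrom": h.chrom, "lo_bin": geno.bin_ids[h.lo_index],
                     "hi_bin": geno.bin_ids[h.hi_index],
                     "traits": ",".join(sorted(h.traits)),
                     "n_members": len(h.members)}
                    for h in hs
                ]
            )
            manifest["counts"]["qtl_calls"] = len(all_calls)
            manifest["counts"]["hotspots"] = len(hs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"[scan-qtl] {exc}") from exc

    # ---- stage: scan-additive -----------------------------------------
    verdicts: dict = {}
    if config.run_additive:
        try:
            add_rows = []
            for (t, d, e), y in means.items():
                scan = addmod.additive_scan(
                    geno, y, f_threshold=config.f_screen_additive,
                    trait=t, density=d, experiment=e,
                )
                conf_df = addmod.permutation_confirm(
                    geno, y, scan.screened_bins,
                    n_perm=config.n_perm_additive, seed=seeds["additive"],
                )
                v = addmod.classify(scan, conf_df)
                verdicts[(t, d, e)] = v
                add_rows.append(
                    pd.DataFrame(
                        {
                            "bin": geno.bin_ids,
                            "chrom": geno.bins["chrom"],
                            "trait": t, "density": d, "experiment": e,
                            "a": scan.table["a"], "f": scan.table["f"],
                            "n_AA": scan.table["n_AA"], "n_BB": scan.table["n_BB"],
                            "verdict": v.to_numpy(),
                        }
                    )
                )
            tables["additive_scan"] = (
                pd.concat(add_rows, ignore_index=True) if add_rows else pd.DataFrame()
            )
            venn_rows = []
            for t in traits:
                for e in experiments:
                    sets = {
                        d: set(
                            np.nonzero((verdicts[(t, d, e)] != "NA").to_numpy())[0]
                        )
                        for d in densities
                        if (t, d, e) in verdicts
                    }
                    if len(sets) == 3:
                        row = {"trait": t, "experiment": e}
                        row.update(addmod.venn_counts(*[sets[d] for d in densities]))
                        venn_rows.append(row)
            tables["venn"] = pd.DataFrame(venn_rows)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"[scan-additive] {exc}") from exc

    # ---- stage: scan-epistasis ----------------------------------------
    epi_results: dict = {}
    if config.run_epistasis:
        try:
            epi_rows = []
            for (t, d, e), y in means.items():
                res = epistasis.genome_pair_scan(
                    geno, y,
                    f_threshold=config.f_screen_epistasis,
                    min_cell=config.min_cell, thin=config.thin,
                    n_perm=config.n_perm_epistasis,
                    max_exceed=config.epistasis_max_exceed,
                    seed=seeds["epistasis"], trait=t, density=d, experiment=e,
                )
                epi_results[(t, d, e)] = res
                for r in res.records:
                    if r.confirmed:
                        epi_rows.append(
                            {
                                "trait": t, "density": d, "experiment": e,
                                "bin_i": geno.bin_ids[r.bin_i],
                                "bin_j": geno.bin_ids[r.bin_j],
                                "aa": r.aa, "f": r.f, "var_pct": r.var_pct,
                                "confirmed": r.confirmed, "sign": r.sign,
                            }
                        )
            tables["epistasis"] = pd.DataFrame(epi_rows)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"[scan-epistasis] {exc}") from exc

    # ---- stage: report -------------------------------------------------
    try:
        tables.update(
            report_tables(
                tables, verdicts=verdicts, epi_results=epi_results,
                traits=traits, densities=densities, experiments=experiments,
                qtl_calls=all_calls,
            )
        )
    except Exception as exc:
        raise StageError(f"[report] {exc}") from exc

    thresholds = {
        "lod_alpha": config.lod_alpha,
        "f_screen_additive": config.f_screen_additive,
        "f_screen_epistasis": config.f_screen_epistasis,
        "n_perm": {
            "lod": config.n_perm_lod,
            "additive": config.n_perm_additive,
            "epistasis": config.n_perm_epistasis,
        },
    }
    manifest["thresholds"] = thresholds
    manifest["counts"]["tables"] = {k: int(len(v)) for k, v in tables.items()}
    io.write_results(tables, out_dir, metadata=manifest)
    return manifest


def report_tables(
    tables: dict,
    verdicts: dict | None = None,
    epi_results: dict | None = None,
    traits=(),
    densities=(),
    experiments=(),
    qtl_calls=(),
) -> dict:
    """Publication-style summaries.

    ``qtl_by_density``: one row per QTL x experiment with Add/LOD/Var%
    columns per density (empty where the QTL was not detected).
    ``summary_counts``: PAE/NAE (significant additive bins by sign) and
    PEE/NEE (confirmed pairs by sign) per trait x density x experiment.
    """
    out: dict = {}
    calls = tables.get("qtl_calls")
    if calls is not None:
        if len(calls) == 0:
            cols = ["qtl", "trait", "experiment", "chrom", "peak_bin"]
            for d in densities:
                cols += [f"add_{d}", f"lod_{d}", f"var_{d}"]
            out["qtl_by_density"] = pd.DataFrame(columns=cols)
        else:
            rows = {}
            for _, c in calls.iterrows():
                key = (c["trait"], c["experiment"], c["chrom"], c["peak_bin"])
                row = rows.setdefault(
                    key,
                    {"qtl": c["qtl"], "trait": c["trait"],
                     "experiment": c["experiment"], "chrom": c["chrom"],
                     "peak_bin": c["peak_bin"]},
                )
                d = c["density"]
                row[f"add_{d}"] = c["additive_effect"]
                row[f"lod_{d}"] = c["lod"]
                row[f"var_{d}"] = c["var_pct"]
            df = pd.DataFrame(list(rows.values()))
            for d in densities:
                for p in ("add", "lod", "var"):
                    if f"{p}_{d}" not in df.columns:
                        df[f"{p}_{d}"] = np.nan
            out["qtl_by_density"] = df
    rows = []
    for t in traits:
        for d in densities:
            for e in experiments:
                row = {"trait": t, "density": d, "experiment": e}
                if verdicts and (t, d, e) in verdicts:
                    row.update(addmod.pae_nae(verdicts[(t, d, e)]))
                if epi_results and (t, d, e) in epi_results:
                    s = epistasis.summarize_epistasis(
                        epi_results[(t, d, e)], qtl_calls=qtl_calls
                    )
                    row["PEE"], row["NEE"] = s["PEE"], s["NEE"]
                rows.append(row)
    if rows:
        out["summary_counts"] = pd.DataFrame(rows)
    return out
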