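"""Line means, G x E ANOVA, heritability and correlations."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from binqtl import phenostats, sim
from binqtl.core import PhenotypeTable, ValidationError
from binqtl.phenostats import VarianceComponents


def _pheno(rows):
    return PhenotypeTable(pd.DataFrame(rows))


class TestLineMeans:
    def test_balanced_data_equals_arithmetic_means(self, toy_pheno):
        got = phenostats.line_means(toy_pheno, "SH", "LD", "Ex1")
        expected = toy_pheno.df.groupby("line")["value"].mean()
        pd.testing.assert_series_equal(got, expected, check_names=False)

    def test_two_replicates_average(self):
        ph = _pheno(
            [
                {"line": "L1", "trait": "SH", "density": "LD", "experiment": "Ex1",
                 "replicate": r, "block": "B1", "value": v}
                for r, v in [("R1", 1.0), ("R2", 3.0)]
            ]
        )
        assert phenostats.line_means(ph, "SH", "LD", "Ex1")["L1"] == pytest.approx(2.0)

    def test_unbalanced_matches_normal_equations_oracle(self):
        # brute-force fixed-effects least squares with sum-coded replicates
        rng = np.random.default_rng(0)
        rows = []
        for i, line in enumerate(["L1", "L2", "L3", "L4"]):
            reps = ["R1", "R2", "R3"] if i % 2 == 0 else ["R1", "R3"]
            for r in reps:
                rows.append(
                    {"line": line, "trait": "SH", "density": "LD",
                     "experiment": "Ex1", "replicate": r, "block": "B1",
                     "value": float(i + {"R1": -1, "R2": 0, "R3": 1}[r] + rng.normal())}
                )
        ph = _pheno(rows)
        got = phenostats.line_means(ph, "SH", "LD", "Ex1")
        df = ph.df
        lines = sorted(df["line"].unique())
        reps = sorted(df["replicate"].unique())
        L = np.zeros((len(df), len(lines)))
        for k, ln in enumerate(lines):
            L[(df["line"] == ln).to_numpy(), k] = 1
        Z = np.zeros((len(df), len(reps) - 1))
        for j, rp in enumerate(reps[1:], start=1):
            Z[(df["replicate"] == rp).to_numpy(), j - 1] = 1
        Z[(df["replicate"] == reps[0]).to_numpy(), :] = -1
        beta = np.linalg.lstsq(
            np.hstack([L, Z]), df["value"].to_numpy(), rcond=None
        )[0]
        np.testing.assert_allclose(got.to_numpy(), beta[: len(lines)], atol=1e-10)

    def test_missing_stratum_is_error(self, toy_pheno):
        with pytest.raises(ValidationError):
            phenostats.line_means(toy_pheno, "SH", "HD", "Ex1")


class TestTwoWayAnovaCore:
    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(1)
        rows = []
        for ln in ["L1", "L2", "L3", "L4", "L5"]:
            for d in ["LD", "MD", "HD"]:
                for r in ["R1", "R2"]:
                    rows.append(
                        {"line": ln, "trait": "SH", "density": d,
                         "experiment": "Ex1", "replicate": r, "block": "B1",
                         "value": float(rng.normal())}
                    )
        ph = _pheno(rows)
        got = phenostats.gxe_anova(ph, "SH", "Ex1")
        fit = ols("value ~ C(line) * C(density)", data=ph.df).fit()
        tab = anova_lm(fit, typ=2)
        f_ref = tab.loc["C(line):C(density)", "F"]
        p_ref = tab.loc["C(line):C(density)", "PR(>F)"]
        assert got.f == pytest.approx(f_ref, rel=1e-10)
        assert got.p == pytest.approx(p_ref, rel=1e-10)

    def test_no_replication_is_error(self, toy_pheno):
        df = toy_pheno.df[toy_pheno.df["replicate"] == "R1"].copy()
        md = df.assign(density="MD")
        ph = PhenotypeTable(pd.concat([df, md], ignore_index=True))
        with pytest.raises(ValidationError, match="replication"):
            phenostats.gxe_anova(ph, "SH", "Ex1")

    def test_constant_trait_flagged_degenerate(self):
        rows = [
            {"line": ln, "trait": "SH", "density": d, "experiment": "Ex1",
             "replicate": r, "block": "B1", "value": 5.0}
            for ln in ["L1", "L2"] for d in ["LD", "MD"] for r in ["R1", "R2"]
        ]
        res = phenostats.gxe_anova(_pheno(rows), "SH", "Ex1")
        assert res.degenerate


class TestGxECalibration:
    def test_null_rejection_rate_near_alpha(self):
        """Density-invariant genetics: interaction p rejects at ~alpha."""
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 6, 0.3)])
        rejections = 0
        n_runs = 120
        for s in range(n_runs):
            g = sim.simulate_ril_genotypes(ms, 30, seed=1000 + s)
            model = sim.TraitModel("SH", qtls=[sim.QtlEffect(2, 0.5)], sigma_e=1.0)
            ph = sim.simulate_phenotypes(
                g, model, densities=("LD", "MD"), experiments=("Ex1",),
                n_reps=2, seed=2000 + s,
            )
            if phenostats.gxe_anova(ph, "SH", "Ex1").p <= 0.05:
                rejections += 1
        rate = rejections / n_runs
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_density_specific_effect_detected(self):
        """a_LD = 0.8, a_HD = 0 is a strong G x E signal at 150 lines."""
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 6, 0.3)])
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            g = sim.simulate_ril_genotypes(ms, 150, seed=3000 + s)
            model = sim.TraitModel(
                "SH", qtls=[sim.QtlEffect(2, {"LD": 0.8, "HD": 0.0})], sigma_e=1.0
            )
            ph = sim.simulate_phenotypes(
                g, model, densities=("LD", "HD"), experiments=("Ex1",),
                n_reps=3, seed=4000 + s,
            )
            if phenostats.gxe_anova(ph, "SH", "Ex1").p <= 0.01:
                hits += 1
        assert hits >= int(0.9 * n_runs)


class TestHeritability:
    def test_plug_in_formula(self):
        comp = VarianceComponents(sigma2_g=4, sigma2_ge=2, sigma2_e=3, r=3, n=3)
        assert comp.heritability() == pytest.approx(0.80)

    def test_noise_free_limit_is_one(self):
        comp = VarianceComponents(sigma2_g=4, sigma2_ge=0, sigma2_e=0, r=3, n=3)
        assert comp.heritability() == pytest.approx(1.0)

    def test_recovery_within_tolerance(self):
        ph = sim.simulate_variance_components(
            213, n_experiments=3, n_reps=3, sigma2_g=4, sigma2_ge=2,
            sigma2_e=3, seed=42,
        )
        res = phenostats.heritability(ph, "SH", "LD")
        assert abs(res.H - 0.80) < 0.05

    def test_affine_invariance(self):
        ph = sim.simulate_variance_components(60, seed=7)
        h1 = phenostats.heritability(ph, "SH", "LD").H
        scaled = PhenotypeTable(ph.df.assign(value=ph.df["value"] * 3.7 + 11.0))
        h2 = phenostats.heritability(scaled, "SH", "LD").H
        assert h1 == pytest.approx(h2, rel=1e-9)

    def test_single_experiment_is_error(self):
        ph = sim.simulate_variance_components(20, n_experiments=1, seed=0)
        with pytest.raises(ValidationError, match="experiments"):
            phenostats.heritability(ph, "SH", "LD")

    def test_component_recovery_across_replications(self):
        ests = [
            phenostats.heritability(
                sim.simulate_variance_components(100, seed=500 + s), "SH", "LD"
            ).components.sigma2_g
            for s in range(40)
        ]
        assert np.mean(ests) == pytest.approx(4.0, rel=0.08)


class TestCorrelations:
    def test_self_and_exact_negative(self):
        x = np.arange(10.0)
        mm = pd.DataFrame({"SH": x, "RDW": -x, "FLL": x + np.sin(x)})
        r, p, stars = phenostats.trait_correlations(mm)
        assert r.at["SH", "SH"] == pytest.approx(1.0)
        assert r.at["SH", "RDW"] == pytest.approx(-1.0)
        assert stars.at["SH", "RDW"] == "**"

    def test_zero_variance_trait_flagged(self):
        mm = pd.DataFrame({"SH": np.arange(5.0), "RDW": np.ones(5)})
        r, p, stars = phenostats.trait_correlations(mm)
        assert np.isnan(r.at["SH", "RDW"]) and stars.at["SH", "RDW"] == ""

    def test_shared_locus_of_opposite_sign_gives_negative_r(self, two_chrom_map):
        g = sim.simulate_ril_genotypes(two_chrom_map, 200, seed=13)
        sh = sim.TraitModel("SH", qtls=[sim.QtlEffect(10, 1.0)], sigma_e=0.5)
        rdw = sim.TraitModel("RDW", qtls=[sim.QtlEffect(10, -1.0)], sigma_e=0.5)
        ps = [
            sim.simulate_phenotypes(g, m, densities=("LD",), experiments=("Ex1",),
                                    n_reps=1, seed=14 + i)
            for i, m in enumerate([sh, rdw])
        ]
        mm = pd.DataFrame(
            {
                "SH": phenostats.line_means(ps[0], "SH", "LD", "Ex1"),
                "RDW": phenostats.line_means(ps[1], "RDW", "LD", "Ex1"),
            }
        )
        r, _, _ = phenostats.trait_correlations(mm)
        assert r.at["SH", "RDW"] < -0.5


class TestSummaries:
    def test_parent_contrast_and_range(self):
        rows = []
        for ln, base in [("NIP", 20.0), ("9311", 18.0), ("RIL001", 19.0),
                         ("RIL002", 17.0)]:
            for r in ("R1", "R2", "R3"):
                rows.append(
                    {"line": ln, "trait": "SH", "density": "LD",
                     "experiment": "Ex1", "replicate": r, "block": "B1",
                     "value": base + 0.1 * {"R1": -1, "R2": 0, "R3": 1}[r]}
                )
        out = phenostats.summarize_traits(_pheno(rows))
        row = out.iloc[0]
        assert row["min"] == pytest.approx(17.0) and row["max"] == pytest.approx(19.0)
        assert row["mean_NIP"] == pytest.approx(20.0)
        assert row["parent_p"] < 0.01 and row["parent_t"] > 0
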