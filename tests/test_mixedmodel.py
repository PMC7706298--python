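"""REML mixed-model engine: closed-form oracles, lme4 cross-check,
outlier screening, and the two BLUP preprocessing methods."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from phenosel.mixedmodel import (TERMS_FULL, TERMS_WITHIN_ENV,
                                 MixedModelDesign, blups_method1,
                                 blups_method2, fit_mixed_model,
                                 remove_outliers_studentized)
from phenosel.preprocess import adjust_moisture, filter_shattered
from phenosel.simulate import simulate_panel

from tests.conftest import small_sim_config


def _balanced_one_term(n_geno=5, n_rep=3, s2g=4.0, s2e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), n_geno)
    rows = []
    for i in range(n_geno):
        for r in range(n_rep):
            rows.append({"genotype": f"g{i}",
                         "y": 10 + g[i] + rng.normal(0, np.sqrt(s2e))})
    return pd.DataFrame(rows)


class TestClosedFormOracle:
    def test_balanced_blup_equals_shrunken_mean(self):
        """For y = mu + G + e with n reps per genotype, the BLUP is the
        genotype mean deviation shrunken by n s2G / (n s2G + s2e)."""
        df = _balanced_one_term(seed=3)
        fit = fit_mixed_model(df, "y", {"genotype": ("genotype",)})
        n = 3
        s2g, s2e = fit.varcomps["genotype"], fit.varcomps["residual"]
        shrink = n * s2g / (n * s2g + s2e)
        gm = df.groupby("genotype")["y"].mean()
        expected = shrink * (gm - gm.mean())
        got = fit.genotype_blups.loc[expected.index]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(),
                                   atol=1e-6)

    def test_no_genetic_signal_fully_shrinks(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "genotype": np.repeat([f"g{i}" for i in range(20)], 6),
            "y": rng.normal(0, 1, 120)})
        fit = fit_mixed_model(df, "y", {"genotype": ("genotype",)})
        # estimated genotype variance collapses, BLUPs shrink toward zero
        assert fit.varcomps["genotype"] < 0.2
        assert fit.genotype_blups.abs().max() < 0.5

    def test_shrinkage_inequality(self):
        df = _balanced_one_term(n_geno=8, n_rep=4, seed=11)
        fit = fit_mixed_model(df, "y", {"genotype": ("genotype",)})
        gm = df.groupby("genotype")["y"].mean()
        raw_dev = (gm - gm.mean()).abs()
        assert (fit.genotype_blups.abs() <= raw_dev.loc[
            fit.genotype_blups.index] + 1e-9).all()

    def test_blups_sum_to_zero(self, tiny_dataset):
        plots = tiny_dataset.plots
        fit = fit_mixed_model(plots, "seed_yield", TERMS_FULL)
        for term, b in fit.blups.items():
            assert abs(b.sum()) < 1e-4 * max(b.abs().max(), 1.0)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
class TestLme4Agreement:
    def test_variance_components_and_blups_match_lme4(self, tmp_path):
        cfg = small_sim_config(n_genotypes=50, n_environments=3,
                               n_blocks_per_rep=5, n_snps=200,
                               band_range=(500, 900, 200), seed=13)
        ds = simulate_panel(cfg)
        path = tmp_path / "plots.csv"
        ds.plots.to_csv(path, index=False)
        fit = fit_mixed_model(ds.plots, "seed_yield")
        r_code = f'''
        suppressMessages(library(lme4))
        d <- read.csv("{path}")
        d$rep <- interaction(d$environment, d$replicate)
        d$blk <- interaction(d$environment, d$replicate, d$block)
        d$gxe <- interaction(d$genotype, d$environment)
        m <- lmer(seed_yield ~ 1 + (1|environment) + (1|rep) + (1|blk)
                  + (1|genotype) + (1|gxe), data=d,
                  control=lmerControl(check.conv.singular="ignore"))
        vc <- as.data.frame(VarCorr(m))
        write.csv(vc[, c("grp", "vcov")], "{tmp_path}/vc.csv", row.names=FALSE)
        b <- ranef(m)$genotype
        b$genotype <- rownames(b)
        write.csv(b, "{tmp_path}/blup.csv", row.names=FALSE)
        '''
        subprocess.run(["Rscript", "-e", r_code], check=True,
                       capture_output=True, timeout=300)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        mapping = {"environment": "environment", "rep": "replicate",
                   "blk": "block", "genotype": "genotype", "gxe": "gxe",
                   "Residual": "residual"}
        scale = vc.sum()
        for rgrp, term in mapping.items():
            assert fit.varcomps[term] == pytest.approx(
                vc[rgrp], rel=2e-3, abs=1e-4 * scale), term
        blup = pd.read_csv(tmp_path / "blup.csv").set_index("genotype")
        ours = fit.genotype_blups
        np.testing.assert_allclose(
            ours.loc[blup.index].to_numpy(),
            blup["(Intercept)"].to_numpy(), rtol=5e-3, atol=1e-3 * scale ** 0.5)


class TestOutlierScreen:
    def test_spiked_observation_flagged(self, tiny_dataset):
        plots = tiny_dataset.plots.copy()
        sd = plots["seed_yield"].std()
        idx = plots.index[100]
        plots.loc[idx, "seed_yield"] += 10 * sd
        clean, flagged, _ = remove_outliers_studentized(
            plots, "seed_yield", TERMS_FULL)
        assert idx in flagged
        assert len(flagged) <= 0.02 * len(plots)

    def test_nothing_flagged_when_clean(self):
        df = _balanced_one_term(n_geno=10, n_rep=5, s2e=1.0, seed=2)
        clean, flagged, _ = remove_outliers_studentized(
            df, "y", {"genotype": ("genotype",)}, threshold=8.0)
        assert len(flagged) == 0
        assert len(clean) == len(df)

    def test_infinite_threshold_is_identity(self, tiny_dataset):
        clean, flagged, _ = remove_outliers_studentized(
            tiny_dataset.plots, "seed_yield", TERMS_FULL,
            threshold=np.inf)
        assert len(flagged) == 0
        assert len(clean) == len(tiny_dataset.plots)


class TestBlupMethods:
    def test_method1_shape(self, tiny_dataset):
        t = blups_method1(tiny_dataset.plots, "seed_yield")
        cfg = tiny_dataset.config
        assert len(t) == cfg.n_genotypes * cfg.n_environments
        assert set(t.columns) >= {"genotype", "environment", "blup",
                                  "predicted"}

    def test_method2_shape_and_unbalance(self, tiny_dataset):
        plots = tiny_dataset.plots
        # drop one genotype from two environments: BLUP still produced
        g0 = plots["genotype"].iloc[0]
        unbalanced = plots[~((plots["genotype"] == g0)
                             & plots["environment"].isin(["E1", "E2"]))]
        t = blups_method2(unbalanced, "seed_yield")
        assert len(t) == tiny_dataset.config.n_genotypes
        assert g0 in set(t["genotype"])

    def test_single_environment_reduces_to_method1(self, tiny_dataset):
        plots = tiny_dataset.plots
        sub = plots[plots["environment"] == "E1"]
        with pytest.warns(UserWarning, match="dropped"):
            m2 = blups_method2(sub, "seed_yield")
        m1 = blups_method1(sub, "seed_yield")
        merged = m1.merge(m2, on="genotype", suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["blup_1"], merged["blup_2"],
                                   rtol=1e-4, atol=1e-3)

    def test_fewer_than_two_reps_rejected(self, tiny_dataset):
        plots = tiny_dataset.plots
        sub = plots[plots["replicate"] == "R1"]
        with pytest.raises(ValueError, match="2 replicates"):
            blups_method1(sub, "seed_yield")

    def test_methods_agree_without_gxe(self):
        cfg = small_sim_config(n_genotypes=80, var_gxe=0.0, var_env=0.0,
                               band_range=(500, 900, 200),
                               band_sd_gxe=0.004, band_sd_env=0.01, seed=42)
        ds = simulate_panel(cfg)
        plots, _ = filter_shattered(ds.plots)
        plots = plots.assign(seed_yield=adjust_moisture(
            plots["seed_yield"], plots["moisture"]))
        m1 = blups_method1(plots, "seed_yield")
        m2 = blups_method2(plots, "seed_yield")
        m1_mean = m1.groupby("genotype")["blup"].mean()
        merged = pd.concat(
            [m1_mean, m2.set_index("genotype")["blup"]], axis=1)
        r = np.corrcoef(merged.iloc[:, 0], merged.iloc[:, 1])[0, 1]
        assert r > 0.9

    def test_method_divergence_grows_with_gxe(self):
        """Rank agreement of Method-1 and Method-2 genotype orderings
        decreases monotonically in the configured GxE variance."""
        from scipy.stats import spearmanr
        agreements = []
        var_g, var_resid = 100_000.0, 120_000.0
        for ratio in (0.0, 0.5, 2.0):       # var_gxe as multiple of var_g
            var_gxe = ratio * var_g
            h2 = var_g / (var_g + var_gxe + var_resid)
            cfg = small_sim_config(
                n_genotypes=80, var_gxe=var_gxe, h2_yield=h2,
                var_resid=var_resid, band_range=(500, 900, 200), seed=31)
            ds = simulate_panel(cfg)
            m1 = blups_method1(ds.plots, "seed_yield")
            m2 = blups_method2(ds.plots, "seed_yield").set_index(
                "genotype")["blup"]
            # per-environment orderings against the across-environment one
            per_env = [
                spearmanr(sub.set_index("genotype")["blup"],
                          m2.loc[sub["genotype"]]).statistic
                for _, sub in m1.groupby("environment")]
            agreements.append(float(np.mean(per_env)))
        assert agreements[0] > agreements[1] > agreements[2]

    def test_more_noise_means_more_shrinkage(self):
        # genetic variance held fixed while residual noise quadruples
        means = []
        var_g, var_gxe = 60_000.0, 40_000.0
        for var_resid in (60_000.0, 240_000.0):
            h2 = var_g / (var_g + var_gxe + var_resid)
            cfg = small_sim_config(n_genotypes=60, var_resid=var_resid,
                                   var_gxe=var_gxe, h2_yield=h2,
                                   band_range=(500, 900, 200), seed=8)
            ds = simulate_panel(cfg)
            fit = fit_mixed_model(ds.plots, "seed_yield", TERMS_FULL)
            means.append(fit.genotype_blups.abs().mean())
        assert means[1] < means[0]


class TestDesignValidation:
    def test_constant_response_rejected(self, tiny_dataset):
        plots = tiny_dataset.plots.copy()
        plots["const"] = 1.0
        with pytest.raises(ValueError, match="constant response"):
            fit_mixed_model(plots, "const", TERMS_FULL)

    def test_missing_design_column(self, tiny_dataset):
        with pytest.raises(KeyError):
            MixedModelDesign(tiny_dataset.plots.drop(columns=["block"]),
                             TERMS_FULL)
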