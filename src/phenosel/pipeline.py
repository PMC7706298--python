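"""End-to-end orchestration: simulate -> preprocess -> BLUP trait tables ->
genomic parameters -> prediction -> waveband optimization -> selection study.

Each stage is an importable function; :func:`run_pipeline` chains them,
records a manifest (config snapshot, removed plots with reasons, retained
bands, runtimes) and writes CSV outputs.  Stage functions operate on
in-memory objects so the CLI and tests can run any subset.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .datatypes import TraitTable
from .evaluation import confusion_at_intensity, training_size_study
from .ga import assemble_final_model, build_search_space, run_ga
from .mixedmodel import TERMS_FULL, TERMS_WITHIN_ENV, MixedModelDesign
from .prediction import (RESPONSE, evaluate, make_cohorts, make_cv1_splits,
                         run_cohort_experiment, train_rf)
from .preprocess import (adjust_moisture, average_plot_reflectance,
                         bin_wavebands, compute_vi,
                         estimate_band_repeatability,
                         filter_bands_by_repeatability, filter_low_emergence,
                         filter_shattered, normalize_ct_by_pass)
from .quantgen import (compute_grm, estimate_genetic_correlation,
                       estimate_h2_snp, snp_qc)
from .simulate import SimDataset, simulate_panel

__all__ = ["PreprocessResult", "RunManifest", "preprocess_dataset",
           "build_trait_tables", "genetic_parameter_tables", "run_pipeline"]


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    config: dict
    seed: int
    software_version: str = __version__
    removed_plots: list = field(default_factory=list)   # (env, plot, rule)
    retained_bands: dict = field(default_factory=dict)  # stage -> [nm]
    runtimes: dict = field(default_factory=dict)        # stage -> seconds
    notes: list = field(default_factory=list)

    def record_removals(self, frame: pd.DataFrame, rule: str) -> None:
        for _, row in frame.iterrows():
            self.removed_plots.append(
                {"environment": row["environment"],
                 "plot_id": row["plot_id"], "rule": rule})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PreprocessResult:
    """Plot-level traits ready for BLUP computation."""

    plot_traits: pd.DataFrame       # design cols + trait cols, one row/plot
    repeatability: dict             # stage -> per-band estimate frame
    bin_tables: dict                # stage -> bin table
    manifest: RunManifest


def preprocess_dataset(ds: SimDataset, cfg: PipelineConfig | None = None,
                       manifest: RunManifest | None = None,
                       compute_repeatability: bool = True
                       ) -> PreprocessResult:
    """Apply plot filters and derive all plot-level predictor traits.

    Yield is censored for shattered plots and rescaled to the 13% moisture
    basis; canopy temperature is pass-centered; spectra are scan-averaged,
    repeatability-filtered, binned, and turned into vegetation indices.
    """
    cfg = cfg or PipelineConfig()
    manifest = manifest or RunManifest(config={}, seed=cfg.seed)

    plots, removed_emerg = filter_low_emergence(ds.plots)
    manifest.record_removals(removed_emerg, "low_emergence")
    plots, removed_shatter = filter_shattered(plots)
    manifest.record_removals(removed_shatter, "shatter_score>=4")
    plots = plots.copy()
    plots["seed_yield"] = adjust_moisture(
        plots["seed_yield"], plots["moisture"], basis=cfg.moisture_basis)

    key = ["environment", "plot_id"]
    base = plots.set_index(key)[["replicate", "block", "genotype", "pass"]]
    trait_cols: dict[str, pd.Series] = {
        "seed_yield": plots.set_index(key)["seed_yield"]}

    # canopy traits, CT centered per data-collection pass
    canopy = ds.canopy.merge(plots[key + ["pass"]], on=key, how="inner")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        canopy["CT"] = normalize_ct_by_pass(canopy["CT"], canopy["pass"])
    for stage, sub in canopy.groupby("stage"):
        sub = sub.set_index(key)
        trait_cols[f"{stage}_CA"] = sub["CA"]
        trait_cols[f"{stage}_CT"] = sub["CT"]

    # scan-average and screen band repeatability per stage, then retain the
    # bands passing the threshold at every stage so both stages share one
    # binned waveband grid
    repeat, bin_tables = {}, {}
    averaged: dict[str, object] = {}
    retained_common: set | None = None
    for stage, spectra in ds.spectra.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            avg = average_plot_reflectance(spectra)
        # drop plots removed by the emergence filter
        avg.frame = avg.frame.loc[avg.frame.index.isin(base.index)]
        averaged[stage] = avg
        if compute_repeatability:
            est = estimate_band_repeatability(avg, plots)
            retained = filter_bands_by_repeatability(est, cfg.h2_threshold)
        else:
            est = None
            retained = list(avg.frame.columns)
        repeat[stage] = est
        retained_common = set(retained) if retained_common is None \
            else retained_common & set(retained)
    if not retained_common:
        raise ValueError("no wavebands pass the repeatability threshold "
                         "in every growth stage")
    for stage, avg in averaged.items():
        retained = [c for c in avg.frame.columns if c in retained_common]
        manifest.retained_bands[stage] = [float(b) for b in retained]
        binned, bin_table = bin_wavebands(
            avg.frame[retained], width=cfg.bin_width,
            grid_step=float(np.diff(avg.wavelengths).min()))
        bin_tables[stage] = bin_table
        vis = compute_vi(avg)
        for col in binned.columns:
            trait_cols[f"{stage}_{col}"] = binned[col]
        for col in vis.columns:
            trait_cols[f"{stage}_{col}"] = vis[col]

    plot_traits = base.join(pd.concat(trait_cols, axis=1)).reset_index()
    return PreprocessResult(plot_traits=plot_traits, repeatability=repeat,
                            bin_tables=bin_tables, manifest=manifest)


# ------------------------------------------------------------------ #
# BLUP trait tables
# ------------------------------------------------------------------ #

def _fit_columns(frame: pd.DataFrame, cols, terms, screen_threshold=None):
    """REML-fit many traits sharing a design; returns genotype predictions.

    Traits are grouped by missing-data pattern so each distinct pattern
    builds its mixed-model design once.  With ``screen_threshold`` set,
    observations with |studentized residual| above it are dropped and the
    model refit once before the BLUPs are extracted.
    """
    out = {}
    groups: dict[bytes, list] = {}
    for c in cols:
        mask = frame[c].notna().to_numpy()
        groups.setdefault(mask.tobytes(), []).append(c)
    for key_bytes, group in groups.items():
        mask = np.frombuffer(key_bytes, dtype=bool)
        sub = frame.loc[mask]
        if sub.empty:
            continue
        design = MixedModelDesign(sub, terms)
        genotypes = pd.Index(sorted(sub["genotype"].unique()),
                             name="genotype")
        start = None
        for c in group:
            y = sub[c].to_numpy(float)
            if np.ptp(y) == 0.0:
                # degenerate trait (e.g. an index whose bands collapse on a
                # coarse grid): every genotype predicts the constant
                warnings.warn(f"trait {c!r} is constant; skipped in BLUP "
                              "shrinkage", stacklevel=2)
                out[c] = pd.Series(y[0], index=genotypes)
                continue
            fit = design.fit(y, start=start)
            if screen_threshold is not None:
                t = fit.studentized_residuals()
                flag = np.abs(t) > screen_threshold
                if flag.any():
                    clean = sub.loc[~flag]
                    fit = MixedModelDesign(clean, terms).fit(
                        clean[c].to_numpy(float), start=dict(fit.varcomps))
            start = dict(fit.varcomps)
            out[c] = fit.mu + fit.genotype_blups
    return out


def build_trait_tables(plot_traits: pd.DataFrame,
                       environments: list | None = None,
                       outlier_threshold: float | None = 3.0
                       ) -> tuple[TraitTable, TraitTable]:
    """Method-1 (by-environment) and Method-2 (across-environment) BLUPs.

    Method 1 fits ``y = mu + R + B(R) + G + e`` within each environment;
    Method 2 fits the full trial model across environments.  Values exported
    are predicted genotype means (mu + BLUP).  ``outlier_threshold`` enables
    the one-pass studentized-residual screen inside every fit.
    """
    trait_cols = [c for c in plot_traits.columns
                  if c not in ("environment", "plot_id", "replicate",
                               "block", "genotype", "pass")]
    if environments is None:
        environments = sorted(plot_traits["environment"].unique())

    # Method 2: across-environment
    m2 = _fit_columns(plot_traits, trait_cols, TERMS_FULL,
                      screen_threshold=outlier_threshold)
    m2_frame = pd.DataFrame(m2)
    m2_frame.index.name = "genotype"

    # Method 1: by environment
    m1_frames = []
    for env in environments:
        sub = plot_traits[plot_traits["environment"] == env]
        cols = [c for c in trait_cols if sub[c].notna().any()]
        vals = _fit_columns(sub, cols, TERMS_WITHIN_ENV,
                            screen_threshold=outlier_threshold)
        fr = pd.DataFrame(vals)
        fr.index.name = "genotype"
        fr["environment"] = env
        m1_frames.append(fr.set_index("environment", append=True))
    m1_frame = pd.concat(m1_frames).reorder_levels(
        ["genotype", "environment"]).sort_index()
    # a genotype with no usable observations for a trait in an environment
    # is fully shrunk: its prediction is the population mean
    m1_frame = m1_frame.groupby(level="environment").transform(
        lambda s: s.fillna(s.mean()))
    m2_frame = m2_frame.fillna(m2_frame.mean())
    return (TraitTable(level="genotype_env", frame=m1_frame),
            TraitTable(level="genotype", frame=m2_frame))


# ------------------------------------------------------------------ #
# genomic parameter tables
# ------------------------------------------------------------------ #

def genetic_parameter_tables(m2_table: TraitTable, snps, cfg: PipelineConfig,
                             traits: list[str] | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame, object]:
    """Per-trait SNP heritability and trait-yield genetic correlations.

    Phenotypes are the Method-2 BLUPs.  Returns (h2 table, rg table, GRM).
    """
    qc = snp_qc(snps, max_missing=cfg.snp_max_missing,
                min_maf=cfg.snp_min_maf)
    grm = compute_grm(qc)
    frame = m2_table.frame
    if traits is None:
        traits = [c for c in frame.columns if not c.split("_")[-1][0] == "R"
                  or not c.split("_")[-1][1:].isdigit()]
    h2_rows, rg_rows = [], []
    yield_vals = frame[RESPONSE].dropna()
    for trait in traits:
        vals = frame[trait].dropna()
        if vals.std() == 0:
            warnings.warn(f"trait {trait!r} is constant; no genetic "
                          "parameters estimated", stacklevel=2)
            continue
        fit = estimate_h2_snp(vals, grm)
        h2_rows.append({"trait": trait, "h2_snp": fit.h2_snp,
                        "se": fit.se_h2, "sigma2_g": fit.sigma2_g,
                        "sigma2_e": fit.sigma2_e})
        if trait != RESPONSE:
            est = estimate_genetic_correlation(
                vals, yield_vals, grm, names=(trait, RESPONSE))
            rg_rows.append({"trait": trait, "rg": est.rg, "se": est.se_rg,
                            "defined": est.defined})
    return pd.DataFrame(h2_rows), pd.DataFrame(rg_rows), grm


# ------------------------------------------------------------------ #
# full run
# ------------------------------------------------------------------ #

def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 dataset: SimDataset | None = None) -> dict:
    """Execute every stage and write results + manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg), seed=cfg.seed)
    results: dict = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()

            def __exit__(self, *a):
                manifest.runtimes[name] = round(time.time() - self.t0, 2)
        return _T()

    with _stage("simulate"):
        if dataset is None:
            dataset = simulate_panel(cfg.sim)
    with _stage("preprocess"):
        prep = preprocess_dataset(dataset, cfg, manifest)
    with _stage("blup"):
        m1, m2 = build_trait_tables(
            prep.plot_traits,
            outlier_threshold=cfg.outlier_threshold)
        m1.frame.to_csv(outdir / "traits_method1.csv")
        m2.frame.to_csv(outdir / "traits_method2.csv")
    with _stage("quantgen"):
        h2_table, rg_table, _ = genetic_parameter_tables(
            m2, dataset.snps, cfg)
        h2_table.to_csv(outdir / "h2_snp.csv", index=False)
        rg_table.to_csv(outdir / "genetic_correlations.csv", index=False)
    with _stage("predict"):
        experiment = run_cohort_experiment(
            m1, m2, n_iter=cfg.n_cv_iterations, train_frac=cfg.train_frac,
            rf_config=cfg.rf, seed=cfg.seed)
        experiment.iterations.to_csv(outdir / "prediction_iterations.csv",
                                     index=False)
        experiment.summary().to_csv(outdir / "prediction_summary.csv",
                                    index=False)
    with _stage("optimize"):
        space = build_search_space(m1.frame.columns)
        genotypes = sorted(m1.frame.index.get_level_values("genotype").unique())
        split = make_cv1_splits(genotypes, cfg.train_frac, 1, cfg.seed)[0]
        train = m1.frame.loc[
            m1.frame.index.get_level_values("genotype").isin(
                split.train_genotypes)]
        test = m1.frame.loc[
            m1.frame.index.get_level_values("genotype").isin(
                split.test_genotypes)]
        ga_cfg = cfg.ga
        ga_cfg.seed = cfg.seed
        ga_res = run_ga(train, space, ga_cfg)
        ga_res.log.to_csv(outdir / "ga_generations.csv", index=False)
        model, feats, metrics = assemble_final_model(
            ga_res.best_features, train, rg_table, cfg.rf, seed=cfg.seed)
        rho = evaluate(model, test[feats], test[RESPONSE],
                       environments=pd.Series(
                           test.index.get_level_values("environment")))
        cm = confusion_at_intensity(
            test[RESPONSE].to_numpy(), model.predict(test[feats]),
            cfg.selection_intensity,
            ids=test.index.get_level_values("genotype"))
        results["ga"] = {"bins": list(ga_res.best_bins),
                         "fitness": ga_res.best_fitness,
                         "test_rho": rho, **cm.as_dict()}
        pd.DataFrame([results["ga"]]).to_csv(
            outdir / "final_model_metrics.csv", index=False)
    with _stage("evaluate"):
        multis = feats
        study = training_size_study(
            m1, list(ga_res.best_features), list(multis),
            fractions=cfg.training_fractions, n_iter=cfg.n_cv_iterations,
            intensity=cfg.selection_intensity, rf_config=cfg.rf,
            seed=cfg.seed)
        study.to_csv(outdir / "training_size_study.csv", index=False)

    manifest.write(outdir / "manifest.yaml")
    results.update({
        "m1": m1, "m2": m2, "h2": h2_table, "rg": rg_table,
        "experiment": experiment, "study": study, "manifest": manifest,
    })
    return results
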