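"""Synthetic multi-environment soybean trial generator.

Produces every input the analysis pipeline consumes — plot tables from an
alpha-lattice layout (incomplete blocks nested in replicates nested in
environments), per-scan canopy reflectance spectra at two growth stages,
canopy area/temperature, and a biallelic SNP matrix — together with the
ground truth needed for parameter-recovery tests.

Generative model
----------------
Seed yield follows the trial mixed model

    y = mu + G + E + R + B(R) + GxE + eps

with genotype values ``G`` built additively from a random subset of causal
SNPs, so SNP-based heritability is recoverable from the genomic relationship
matrix.  Band reflectance is a smooth vegetation-like baseline plus a
genotype-level genetic deviation constructed from the standardized yield
genetic values: at wavelength ``w`` with target genetic correlation
``rho(w)``,

    u_g(w) = sd_g(w) * ( rho(w) * z_g + sqrt(1 - rho(w)^2) * eta_g(w) )

where ``z_g`` is the standardized genetic yield value and ``eta_g`` is an
independent smooth random field, so the genetic correlation between band and
yield equals ``rho(w)`` by construction.  Informative regions (defaults:
red edge 700-850 nm and SWIR 2030-2119 nm) get a larger genetic standard
deviation, hence higher band repeatability, than background bands.

A configurable fraction of plots is degraded (low emergence counts, high
shatter scores) so the plot-quality filters are exercised; harvested yield is
stored at field moisture so the 13%-basis adjustment is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .config import SimConfig
from .datatypes import GenotypeMatrix, SpectraMatrix, TruthRecord

__all__ = ["SimDataset", "simulate_genotypes", "simulate_panel",
           "write_fixture", "load_fixture"]


@dataclass
class SimDataset:
    """A complete synthetic trial: all pipeline inputs plus ground truth."""

    config: SimConfig
    plots: pd.DataFrame
    spectra: dict[str, SpectraMatrix]
    canopy: pd.DataFrame
    snps: GenotypeMatrix
    truth: TruthRecord | None


# ------------------------------------------------------------------ #
# genotypes
# ------------------------------------------------------------------ #

def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate a genotype x SNP matrix of additive codes {0, 1, 2}.

    Allele frequencies are drawn uniformly on ``config.maf_range`` and
    genotypes sampled under Hardy-Weinberg proportions (Binomial(2, p)).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_genotypes, config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    codes = rng.binomial(2, p, size=(n, m)).astype(float)
    idx = pd.Index([f"G{i:04d}" for i in range(n)], name="genotype")
    cols = [f"snp{j:05d}" for j in range(m)]
    return GenotypeMatrix(frame=pd.DataFrame(codes, index=idx, columns=cols))


def _genetic_values(snps: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator) -> pd.Series:
    """Additive genetic yield values from a random causal subset of SNPs."""
    m = snps.shape[1]
    n_causal = min(config.n_causal_snps, m)
    causal = rng.choice(m, size=n_causal, replace=False)
    effects = rng.normal(size=n_causal)
    W = snps.to_numpy()[:, causal]
    g = (W - W.mean(axis=0)) @ effects
    sd = g.std()
    if sd == 0:
        raise ValueError("degenerate genetic values (monomorphic causal set)")
    g = g / sd * np.sqrt(config.var_genetic)
    return pd.Series(g, index=snps.index, name="genetic_value")


# ------------------------------------------------------------------ #
# spectra helpers
# ------------------------------------------------------------------ #

def _baseline_spectrum(lam: np.ndarray, stage: str) -> np.ndarray:
    """Smooth vegetation-like reflectance curve (unitless proportions)."""
    nir = 0.44 if stage == "S1" else 0.50
    x = lam.astype(float)
    r = 0.035 + 0.055 * np.exp(-((x - 550.0) / 40.0) ** 2)
    r = r + nir / (1.0 + np.exp(-(x - 715.0) / 16.0))
    r = r * (1.0 - 0.18 / (1.0 + np.exp(-(x - 1350.0) / 120.0)))
    r = r * (1.0 - 0.38 * np.exp(-((x - 1450.0) / 40.0) ** 2))
    r = r * (1.0 - 0.52 * np.exp(-((x - 1940.0) / 55.0) ** 2))
    r = r * (1.0 - 0.12 * np.exp(-((x - 2350.0) / 120.0) ** 2))
    return r


def _smooth_basis(lam: np.ndarray, spacing: float = 60.0,
                  width: float = 45.0) -> np.ndarray:
    """Row-normalized Gaussian bump basis: unit marginal variance fields."""
    centers = np.arange(lam.min() - width, lam.max() + width + spacing, spacing)
    phi = np.exp(-((lam[:, None] - centers[None, :]) / width) ** 2)
    norm = np.sqrt((phi ** 2).sum(axis=1, keepdims=True))
    return phi / norm          # (n_bands, n_basis)


_RED_EDGE_CENTER = 715.0
_RED_EDGE_WIDTH = 16.0
_NIR_MEAN = 0.47          # average NIR plateau across growth stages


def _edge_gradient(lam: np.ndarray, nir: float = _NIR_MEAN) -> np.ndarray:
    """d(reflectance)/d(red-edge center shift), per nm, at each band."""
    x = (lam - _RED_EDGE_CENTER) / _RED_EDGE_WIDTH
    sig = 1.0 / (1.0 + np.exp(-x))
    return nir / _RED_EDGE_WIDTH * sig * (1.0 - sig)


def _band_profiles(lam: np.ndarray, config: SimConfig):
    """Per-band channel coefficients and the repeatability/rg truth.

    The genetic (and GxE) deviation of a band has two routes: the direct
    deviation channel and the performance-tracking red-edge shift.  The
    direct channel's loading on the performance axis is compensated so the
    TOTAL per-band genetic sd and genetic correlation equal the configured
    targets; the edge shift then only redistributes how the correlation is
    realized across neighboring bands (giving derivative-type indices their
    information) without moving the planted band-level moments.
    """
    lo_sd, hi_sd = config.band_sd_genetic_bg
    sd_g = lo_sd + (hi_sd - lo_sd) * 0.5 * (1.0 + np.sin(lam / 137.0))
    rho = np.zeros_like(lam, dtype=float)
    for start, end, rg in config.informative_regions:
        mask = (lam >= start) & (lam <= end)
        sd_g[mask] = config.band_sd_genetic_info
        rho[mask] = rg
    var_g = config.var_genetic
    if config.band_sd_gxe is None:
        sd_gxe = sd_g * np.sqrt(config.var_gxe / var_g)
    else:
        sd_gxe = np.full_like(sd_g, config.band_sd_gxe)
    if config.band_sd_env is None:
        sd_env = sd_g * np.sqrt(config.var_env / var_g)
    else:
        sd_env = np.full_like(sd_g, config.band_sd_env)

    # performance-axis shares of the red-edge shift
    perf_var = var_g + config.var_gxe + config.var_env
    shift = config.red_edge_shift_sd
    grad = _edge_gradient(lam)
    e_g = grad * shift * np.sqrt(var_g / perf_var)
    e_ge = grad * shift * np.sqrt(config.var_gxe / perf_var)
    # Compensated direct-channel loadings: the edge shift contributes -e on
    # the performance axis, so the direct channel carries sd*rho + e and
    # the total loading is exactly sd*rho.  The independent channel carries
    # sd*sqrt(1-rho^2), keeping the total band variance at sd^2.
    c_z = sd_g * rho + e_g
    s_z = sd_g * np.sqrt(1.0 - rho ** 2)
    rho_ge = rho * config.rg_gxe_scale
    c_zge = sd_gxe * rho_ge + e_ge
    s_zge = sd_gxe * np.sqrt(1.0 - rho_ge ** 2)

    e, r = config.n_environments, config.n_reps
    var_eps_eff = config.band_sd_plot ** 2 + config.band_sd_scan ** 2 / 2.0
    h2 = sd_g ** 2 / (sd_g ** 2 + sd_gxe ** 2 / e + var_eps_eff / (r * e))
    return {
        "sd_g": sd_g, "rho": rho, "sd_gxe": sd_gxe, "sd_env": sd_env,
        "h2": h2, "c_z": c_z, "s_z": s_z, "c_zge": c_zge, "s_zge": s_zge,
        "rho_env": rho * config.rg_env_scale,
    }


# ------------------------------------------------------------------ #
# full panel
# ------------------------------------------------------------------ #

def simulate_panel(config: SimConfig) -> SimDataset:
    """Generate a complete synthetic trial.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    snps = simulate_genotypes(config, rng)
    g = _genetic_values(snps.frame, config, rng)
    genotypes = snps.frame.index
    n_g = config.n_genotypes
    z = (g - g.mean()) / g.std()
    z = z.to_numpy()

    envs = [f"E{i + 1}" for i in range(config.n_environments)]
    reps = [f"R{j + 1}" for j in range(config.n_reps)]
    n_blocks = config.n_blocks_per_rep

    # ------------------------------------------------------------------ #
    # field layout and yield
    # ------------------------------------------------------------------ #
    env_eff = rng.normal(0, np.sqrt(config.var_env), len(envs))
    rows = []
    plot_geno_idx = []
    for ei, env in enumerate(envs):
        plot_no = 0
        for rj, rep in enumerate(reps):
            rep_eff = rng.normal(0, np.sqrt(config.var_rep))
            order = rng.permutation(n_g)
            # blocks tile the genotype set within each replicate
            bounds = np.linspace(0, n_g, n_blocks + 1).round().astype(int)
            block_eff = rng.normal(0, np.sqrt(config.var_block), n_blocks)
            for b in range(n_blocks):
                for gi in order[bounds[b]:bounds[b + 1]]:
                    plot_no += 1
                    rows.append((env, rep, f"B{b + 1:02d}",
                                 f"P{plot_no:04d}", genotypes[gi],
                                 ei, rj, b, gi,
                                 env_eff[ei] + rep_eff + block_eff[b]))
                    plot_geno_idx.append(gi)
    plots = pd.DataFrame(rows, columns=[
        "environment", "replicate", "block", "plot_id", "genotype",
        "_ei", "_rj", "_b", "_gi", "_design_eff"])
    n_plots = len(plots)
    gi = plots["_gi"].to_numpy()
    ei = plots["_ei"].to_numpy()

    gxe_yield = rng.normal(0, np.sqrt(config.var_gxe), (n_g, len(envs)))
    resid = rng.normal(0, np.sqrt(config.var_resid), n_plots)
    y13 = (config.mean_yield + g.to_numpy()[gi] + plots["_design_eff"]
           + gxe_yield[gi, ei] + resid)

    # plot-quality degradation
    stand = np.clip(np.round(rng.normal(30, 2.5, n_plots)), 0, None)
    low = rng.random(n_plots) < config.frac_low_stand
    stand[low] = np.round(rng.uniform(5, 18, low.sum()))
    shatter = rng.choice([1, 2, 3], size=n_plots, p=[0.72, 0.20, 0.08])
    shat = rng.random(n_plots) < config.frac_shattered
    shatter[shat] = rng.choice([4, 5], size=shat.sum())
    loss = np.where(shatter >= 5, 0.45, np.where(shatter >= 4, 0.70, 1.0))
    y13 = np.maximum(y13 * loss, 0.0)

    moisture = np.clip(rng.normal(0.13, 0.015, n_plots), 0.08, 0.20)
    y_wet = y13 * (1.0 - 0.13) / (1.0 - moisture)

    # data-collection passes: consecutive plots within an env-rep pair
    pass_ids = (plots["environment"] + "|" + plots["replicate"] + "|p"
                + (plots.groupby(["environment", "replicate"]).cumcount()
                   // config.plots_per_pass).astype(str))

    plots_out = pd.DataFrame({
        "environment": plots["environment"],
        "replicate": plots["replicate"],
        "block": plots["block"],
        "pass": pass_ids,
        "plot_id": plots["plot_id"],
        "genotype": plots["genotype"],
        "stand_count": stand.astype(int),
        "shatter_score": shatter.astype(int),
        "moisture": moisture.round(4),
        "seed_yield": y_wet.round(2),
    })

    # ------------------------------------------------------------------ #
    # spectra
    # ------------------------------------------------------------------ #
    lo, hi, step = config.band_range
    lam = np.arange(lo, hi + 1, step, dtype=float)
    prof = _band_profiles(lam, config)
    sd_g_band, rho, h2_band = prof["sd_g"], prof["rho"], prof["h2"]
    sd_gxe_band, sd_env_band = prof["sd_gxe"], prof["sd_env"]
    phi = _smooth_basis(lam)
    n_basis = phi.shape[1]

    # direct deviation channels (performance-axis loadings compensated for
    # the red-edge shift so per-band moments hit the configured targets)
    eta = rng.normal(size=(n_g, n_basis)) @ phi.T          # genetic noise field
    u_band = prof["c_z"] * z[:, None] + prof["s_z"] * eta
    sd_e = env_eff.std()
    z_env = (env_eff - env_eff.mean()) / sd_e if sd_e > 0 \
        else np.zeros(len(envs))
    rho_env = prof["rho_env"]
    eta_env = rng.normal(size=(len(envs), n_basis)) @ phi.T
    env_field = sd_env_band * (
        rho_env * z_env[:, None] + np.sqrt(1.0 - rho_env ** 2) * eta_env)
    sd_ge = gxe_yield.std()
    z_ge = ((gxe_yield - gxe_yield.mean()) / sd_ge).reshape(-1) \
        if sd_ge > 0 else np.zeros(n_g * len(envs))
    eta_ge = rng.normal(size=(n_g * len(envs), n_basis)) @ phi.T
    gxe_field = prof["c_zge"] * z_ge[:, None] + prof["s_zge"] * eta_ge
    gxe_idx = gi * len(envs) + ei

    # per-plot red-edge shift tracking total realized performance
    perf_sd = np.sqrt(config.var_genetic + config.var_gxe + config.var_env)
    perf_plot = (g.to_numpy()[gi] + gxe_yield[gi, ei] + env_eff[ei]) / perf_sd
    delta_edge = config.red_edge_shift_sd * perf_plot      # nm, per plot

    spec_envs = envs if config.n_spectra_environments is None \
        else envs[:config.n_spectra_environments]
    env_mask = plots["environment"].isin(spec_envs).to_numpy()
    sub = np.flatnonzero(env_mask)

    spectra: dict[str, SpectraMatrix] = {}
    cols = [int(w) if w.is_integer() else w for w in lam]
    for stage in config.stages:
        base = _baseline_spectrum(lam, stage)
        nir = 0.44 if stage == "S1" else 0.50
        edge = _edge_gradient(lam, nir)
        plot_level = (base[None, :]
                      + u_band[gi[sub]]
                      + env_field[ei[sub]]
                      + gxe_field[gxe_idx[sub]]
                      - edge[None, :] * delta_edge[sub, None]
                      + rng.normal(0, config.band_sd_plot,
                                   (len(sub), len(lam))))
        frames = []
        for scan in (1, 2):
            refl = plot_level + rng.normal(0, config.band_sd_scan,
                                           plot_level.shape)
            fr = pd.DataFrame(refl, columns=cols)
            fr.index = pd.MultiIndex.from_arrays(
                [plots["environment"].iloc[sub], plots["plot_id"].iloc[sub],
                 np.full(len(sub), scan)],
                names=["environment", "plot_id", "scan"])
            frames.append(fr)
        spectra[stage] = SpectraMatrix(
            stage=stage, wavelengths=lam.copy(),
            frame=pd.concat(frames).sort_index())

    # ------------------------------------------------------------------ #
    # canopy traits
    # ------------------------------------------------------------------ #
    def _correlated_trait(rg: float, scale: float, n: int,
                          perf: np.ndarray) -> np.ndarray:
        """Trait component tracking a standardized performance vector."""
        noise = rng.normal(size=n)
        return scale * (rg * perf + np.sqrt(1.0 - rg ** 2) * noise)

    pass_codes, _ = pd.factorize(pass_ids)
    pass_offset = rng.normal(0, 2.0, pass_codes.max() + 1)
    canopy_frames = []
    for stage in config.stages:
        ca_mean = 0.55 if stage == "S1" else 0.75
        # genetic and GxE components both track realized performance
        ca_g = _correlated_trait(config.rg_canopy_area, 0.08, n_g, z)
        ct_g = _correlated_trait(config.rg_canopy_temp, 1.5, n_g, z)
        ca_ge = _correlated_trait(config.rg_canopy_area * config.rg_gxe_scale,
                                  0.05, n_g * len(envs), z_ge)
        ct_ge = _correlated_trait(config.rg_canopy_temp * config.rg_gxe_scale,
                                  1.0, n_g * len(envs), z_ge)
        ca_env = rng.normal(0, 0.03, len(envs))
        ct_env = rng.normal(0, 0.8, len(envs))
        ca = np.clip(ca_mean + ca_g[gi] + ca_ge[gxe_idx] + ca_env[ei]
                     + rng.normal(0, 0.05, n_plots), 0.01, 0.99)
        ct = (28.0 + pass_offset[pass_codes] + ct_g[gi] + ct_ge[gxe_idx]
              + ct_env[ei] + rng.normal(0, 0.8, n_plots))
        canopy_frames.append(pd.DataFrame({
            "environment": plots["environment"],
            "plot_id": plots["plot_id"],
            "stage": stage,
            "CA": ca.round(4), "CT": ct.round(3),
        }))
    canopy = pd.concat(canopy_frames, ignore_index=True)

    # SNP missingness (applied only to the released matrix, not the truth)
    snp_out = snps.frame.to_numpy().copy()
    miss_rate = np.full(config.n_snps, config.snp_missing_rate)
    high = rng.random(config.n_snps) < config.frac_high_missing_snps
    miss_rate[high] = rng.uniform(0.11, 0.20, high.sum())
    mask = rng.random(snp_out.shape) < miss_rate[None, :]
    snp_out[mask] = np.nan
    snps_released = GenotypeMatrix(frame=pd.DataFrame(
        snp_out, index=snps.frame.index, columns=snps.frame.columns))

    e, r = config.n_environments, config.n_reps
    true_h2_snp = config.var_genetic / (
        config.var_genetic + config.var_gxe / e
        + (config.var_block + config.var_resid) / (r * e))
    truth = TruthRecord(
        true_genetic_values=g,
        true_band_rg=pd.Series(rho, index=lam, name="rg"),
        true_band_h2=pd.Series(h2_band, index=lam, name="H2"),
        true_h2_snp=float(true_h2_snp),
        variance_components={
            "environment": config.var_env, "replicate": config.var_rep,
            "block": config.var_block, "genotype": config.var_genetic,
            "gxe": config.var_gxe, "residual": config.var_resid,
        },
    )
    return SimDataset(config=config, plots=plots_out, spectra=spectra,
                      canopy=canopy, snps=snps_released, truth=truth)


# ------------------------------------------------------------------ #
# fixture I/O
# ------------------------------------------------------------------ #

def write_fixture(dataset: SimDataset, directory: str | Path) -> list[Path]:
    """Write a dataset to the standard CSV/YAML fixture layout."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"fixture directory does not exist: {directory}")
    written = []

    def _put(name: str, writer, obj) -> None:
        path = directory / name
        writer(obj, path)
        written.append(path)

    _put("plots.csv", psio.write_plot_table, dataset.plots)
    _put("canopy.csv", psio.write_canopy_table, dataset.canopy)
    _put("snps.csv", psio.write_genotype_matrix, dataset.snps)
    for stage, sp in dataset.spectra.items():
        _put(f"spectra_{stage}.csv", psio.write_spectra, sp)
    if dataset.truth is not None:
        t = dataset.truth
        payload = {
            "true_h2_snp": t.true_h2_snp,
            "variance_components": t.variance_components,
            "true_genetic_values": {str(k): float(v) for k, v
                                    in t.true_genetic_values.items()},
            "true_band_rg": {float(k): float(v) for k, v
                             in t.true_band_rg.items()},
            "true_band_h2": {float(k): float(v) for k, v
                             in t.true_band_h2.items()},
        }
        path = directory / "truth.yaml"
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        written.append(path)
    path = directory / "config.yaml"
    path.write_text(yaml.safe_dump(asdict(dataset.config), sort_keys=False))
    written.append(path)
    return written


def load_fixture(directory: str | Path) -> SimDataset:
    """Read a fixture directory back into a dataset (truth if present)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such fixture directory: {directory}")
    plots = psio.read_plot_table(directory / "plots.csv")
    canopy = psio.read_canopy_table(directory / "canopy.csv")
    snps = psio.read_genotype_matrix(directory / "snps.csv")
    spectra = {}
    for path in sorted(directory.glob("spectra_*.csv")):
        stage = path.stem.split("_", 1)[1]
        spectra[stage] = psio.read_spectra(path, stage)
    truth = None
    truth_path = directory / "truth.yaml"
    if truth_path.exists():
        raw = yaml.safe_load(truth_path.read_text())
        truth = TruthRecord(
            true_genetic_values=pd.Series(raw["true_genetic_values"]),
            true_band_rg=pd.Series(raw["true_band_rg"]),
            true_band_h2=pd.Series(raw["true_band_h2"]),
            true_h2_snp=raw["true_h2_snp"],
            variance_components=raw.get("variance_components", {}),
        )
    config = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        from .config import _coerce
        config = _coerce(SimConfig, yaml.safe_load(cfg_path.read_text()))
    return SimDataset(config=config, plots=plots, spectra=spectra,
                      canopy=canopy, snps=snps, truth=truth)
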