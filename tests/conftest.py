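"""Shared fixtures: small synthetic trials and their derived trait tables.

Expensive objects (a full preprocessed trial with BLUP tables) are built
once per session and shared; problem sizes are scaled to keep the whole
suite fast while preserving the structure of the emulated study (multiple
environments with replicates and incomplete blocks, two growth stages,
informative red-edge and SWIR regions).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from phenosel.config import GAConfig, PipelineConfig, RFConfig, SimConfig
from phenosel.pipeline import build_trait_tables, preprocess_dataset
from phenosel.simulate import simulate_panel

#: regions carrying planted genetic signal in every synthetic trial here
PLANTED_REGIONS = ((700.0, 850.0), (2030.0, 2119.0))

#: four-region architecture for waveband-selection recovery experiments
FOUR_REGIONS = ((460.0, 520.0, -0.6), (700.0, 850.0, -0.7),
                (1650.0, 1720.0, -0.6), (2030.0, 2119.0, -0.6))


def small_sim_config(**overrides) -> SimConfig:
    """A fast trial: 60 genotypes, 3 environments, coarse 100-nm grid.

    Informative regions are clipped to whatever band range is requested.
    """
    defaults = dict(
        n_genotypes=60, n_environments=3, n_reps=2, n_blocks_per_rep=6,
        n_snps=400, n_causal_snps=80, band_range=(400, 2500, 100),
        seed=101)
    defaults.update(overrides)
    if "informative_regions" not in overrides:
        lo, hi, _ = defaults["band_range"]
        regions = tuple(r for r in SimConfig.informative_regions
                        if lo <= r[0] and r[1] <= hi)
        if not regions:
            regions = ((float(lo), float(hi), -0.7),)
        defaults["informative_regions"] = regions
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete trial used by I/O, preprocessing and model tests."""
    return simulate_panel(small_sim_config())


@pytest.fixture(scope="session")
def study_dataset():
    """Mid-sized trial mirroring the emulated study design: six
    environments with phenomics in four, strong genotype-by-environment
    interaction, 25-nm spectral grid."""
    cfg = SimConfig(
        n_genotypes=120, n_environments=6, n_spectra_environments=4,
        n_reps=2, n_blocks_per_rep=12, n_snps=500, n_causal_snps=100,
        band_range=(400, 2500, 25), h2_yield=0.2857,
        var_gxe=120_000.0, var_resid=90_000.0, seed=21)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def study_tables(study_dataset):
    """(Method-1 table, Method-2 table, preprocess result) for the study
    trial; built once and reused by prediction/GA/evaluation tests."""
    cfg = PipelineConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep = preprocess_dataset(study_dataset, cfg)
        m1, m2 = build_trait_tables(prep.plot_traits)
    return m1, m2, prep


@pytest.fixture(scope="session")
def four_region_tables():
    """Method-1 table for a trial with four planted informative regions
    (the waveband-selection recovery design)."""
    cfg = PipelineConfig(sim=SimConfig(
        n_genotypes=120, n_environments=4, n_reps=2, n_blocks_per_rep=12,
        n_snps=500, n_causal_snps=100, band_range=(400, 2500, 25),
        informative_regions=FOUR_REGIONS, seed=77))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate_panel(cfg.sim)
        prep = preprocess_dataset(ds, cfg)
        m1, _ = build_trait_tables(prep.plot_traits)
    return m1


def in_four_region(bin_label: str) -> bool:
    nm = float(bin_label.lstrip("R"))
    return any(lo <= nm <= hi for lo, hi, _ in FOUR_REGIONS)


@pytest.fixture(scope="session")
def fast_rf():
    return RFConfig(n_trees=120)


@pytest.fixture(scope="session")
def fast_ga():
    return GAConfig(population_size=20, n_generations=8, fitness_trees=50,
                    fitness_folds=3, patience=4, seed=0)


def in_planted_region(bin_label: str) -> bool:
    nm = float(bin_label.lstrip("R"))
    return any(lo <= nm <= hi for lo, hi in PLANTED_REGIONS)


def geno_env_subset(frame, genotypes, env=None, exclude_env=None):
    gl = frame.index.get_level_values("genotype")
    mask = gl.isin(genotypes)
    if env is not None or exclude_env is not None:
        el = frame.index.get_level_values("environment")
        if env is not None:
            mask &= el == env
        if exclude_env is not None:
            mask &= el != exclude_env
    return frame.loc[mask]
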