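"""Configuration objects for simulation, prediction and optimization.

Every quantity a breeding analyst might want to pin down — trial layout,
variance components, spectral signal placement, repeatability threshold,
random-forest and genetic-algorithm settings — is a named field with the
pipeline's default value, serializable to/from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimConfig", "RFConfig", "GAConfig", "PipelineConfig",
           "load_config", "save_config"]


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-environment trial generator.

    Defaults mirror the emulated study: 292 accessions, 6 environments with
    2 replicates of 30 incomplete blocks each, 1-nm reflectance from
    350-2500 nm with yield-correlated genetic signal in the red-edge
    (700-850 nm) and shortwave-infrared (2030-2119 nm) regions, and ~35k
    biallelic SNPs of which a subset is causal for yield.
    Variances are on the kg/ha yield scale.
    """

    n_genotypes: int = 292
    n_environments: int = 6
    n_reps: int = 2
    n_blocks_per_rep: int = 30
    n_snps: int = 35000
    n_causal_snps: int = 200
    # (start nm, stop nm, step nm); reduce the grid for fast experiments
    band_range: tuple[int, int, int] = (350, 2500, 1)
    # (start nm, end nm, target genetic correlation of band with yield)
    informative_regions: tuple[tuple[float, float, float], ...] = (
        (700.0, 850.0, -0.70),
        (2030.0, 2119.0, -0.60),
    )
    h2_yield: float = 0.45          # plot-level heritability of seed yield
    mean_yield: float = 2100.0      # kg/ha at 13% moisture
    var_env: float = 250_000.0
    var_rep: float = 10_000.0
    var_block: float = 10_000.0
    var_gxe: float = 40_000.0
    var_resid: float = 90_000.0
    maf_range: tuple[float, float] = (0.05, 0.95)
    snp_missing_rate: float = 0.01
    frac_high_missing_snps: float = 0.02
    # spectra noise model (reflectance units)
    band_sd_genetic_info: float = 0.012
    band_sd_genetic_bg: tuple[float, float] = (0.001, 0.006)
    # Spectral GxE / environment deviations default to tracking the yield
    # variance components: sd_gxe(w) = sd_g(w) * sqrt(var_gxe / var_g), and
    # likewise for environments.  Reflectance is a readout of the realized
    # canopy, so performance differences are visible at every level
    # (consistent reaction norms) — the mechanism that gives by-environment
    # models their edge.  Set a float to override with a flat value.
    band_sd_gxe: float | None = None
    band_sd_env: float | None = None
    # fraction of a band's performance correlation applied at the GxE and
    # environment levels
    rg_gxe_scale: float = 1.0
    rg_env_scale: float = 1.0
    # Performance-tracking red-edge shift (nm per SD of total performance):
    # higher chlorophyll moves the reflectance inflection to longer
    # wavelengths, which is what makes derivative-type red-edge indices
    # (VREI2) informative.  Band-level genetic moments are compensated so
    # the configured per-band rg and repeatability targets still hold.
    red_edge_shift_sd: float = 3.0
    band_sd_plot: float = 0.012
    band_sd_scan: float = 0.005
    # plot-quality degradation
    frac_low_stand: float = 0.01
    frac_shattered: float = 0.01
    # canopy traits: genetic correlation with yield
    rg_canopy_area: float = 0.33
    rg_canopy_temp: float = -0.44
    plots_per_pass: int = 20
    stages: tuple[str, ...] = ("S1", "S2")
    n_spectra_environments: int | None = None   # None: spectra in all envs
    seed: int = 2016

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_environments", "n_reps",
                     "n_blocks_per_rep", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("var_env", "var_rep", "var_block", "var_gxe",
                     "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.h2_yield <= 1.0:
            raise ValueError("h2_yield must lie in [0, 1]")
        lo, hi, step = self.band_range
        if step < 1 or hi <= lo:
            raise ValueError("band_range must be (start, stop, step>=1)")
        for start, end, rg in self.informative_regions:
            if not (lo <= start < end <= hi):
                raise ValueError(
                    f"informative region ({start}, {end}) outside band range")
            if not -1.0 <= rg <= 1.0:
                raise ValueError(f"target genetic correlation {rg} outside [-1, 1]")

    @property
    def var_genetic(self) -> float:
        """Additive genetic variance implied by the plot-level h2_yield."""
        if self.h2_yield >= 1.0:
            raise ValueError("h2_yield = 1 implies infinite genetic variance")
        return self.h2_yield / (1.0 - self.h2_yield) * (
            self.var_gxe + self.var_resid)

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_environments * self.n_reps


@dataclass
class RFConfig:
    """Random-forest settings for yield-rank prediction.

    ``max_features_grid`` is the tuning grid searched by repeated k-fold
    cross-validation inside the training set; ``tune=False`` fits at
    ``max_features`` directly (the fast default for batch experiments).
    """

    n_trees: int = 500
    max_features: float | str = 0.33
    tune: bool = False
    max_features_grid: tuple = (0.1, 0.2, 0.33, 0.6, 1.0)
    tune_folds: int = 10
    tune_repeats: int = 5
    min_samples_leaf: int = 2

    def sklearn_kwargs(self) -> dict:
        return {"n_estimators": self.n_trees,
                "max_features": self.max_features,
                "min_samples_leaf": self.min_samples_leaf,
                "n_jobs": 1, "oob_score": True, "bootstrap": True}


@dataclass
class GAConfig:
    """Genetic-algorithm settings for waveband subset selection."""

    n_select: int = 4
    population_size: int = 50
    n_generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    tournament_size: int = 3
    fitness_folds: int = 5
    fitness_trees: int = 100       # reduced forest during the search
    patience: int = 10
    stage_shared: bool = True      # 4 bins, each used at both growth stages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.population_size <= self.elitism:
            raise ValueError("population_size must exceed elitism")


@dataclass
class PipelineConfig:
    """Full-run configuration: one section per pipeline stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    h2_threshold: float = 0.3       # repeatability cutoff for wavebands
    bin_width: int = 10             # nm per averaged waveband
    outlier_threshold: float = 3.0  # |studentized residual| cutoff
    moisture_basis: float = 0.13    # yield reporting moisture
    selection_intensity: float = 0.20
    train_frac: float = 0.80
    n_cv_iterations: int = 10
    training_fractions: tuple[float, ...] = (0.80, 0.60, 0.40, 0.20)
    snp_max_missing: float = 0.10
    snp_min_maf: float = 0.05
    seed: int = 2016


_SECTIONS = {"sim": SimConfig, "rf": RFConfig, "ga": GAConfig}


def _coerce(cls, data: dict):
    # YAML round-trips tuples as lists; restore tuples for dataclass fields
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML, validating every section."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _coerce(_SECTIONS[key], val or {})
        else:
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid configuration key: {exc}") from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
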