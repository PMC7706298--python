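"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraMatrix", "GenotypeMatrix", "TraitTable", "TruthRecord",
           "ConfusionSummary"]


@dataclass
class SpectraMatrix:
    """Plot-level canopy reflectance for one growth stage.

    ``frame`` is indexed by (environment, plot_id, scan) — or
    (environment, plot_id) once scans have been averaged — with one column
    per wavelength, labeled by integer nm (center of the 1-nm band).
    """

    stage: str
    wavelengths: np.ndarray
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if len(self.wavelengths) != self.frame.shape[1]:
            raise ValueError("wavelength grid does not match reflectance columns")

    @property
    def n_plots(self) -> int:
        if "scan" in (self.frame.index.names or []):
            return self.frame.index.droplevel("scan").nunique()
        return len(self.frame)

    def band(self, nm: float) -> pd.Series:
        """Reflectance at the grid wavelength nearest to ``nm``."""
        j = int(np.argmin(np.abs(self.wavelengths - nm)))
        return self.frame.iloc[:, j]


@dataclass
class GenotypeMatrix:
    """Genotypes x markers, additive codes {0, 1, 2} with NaN for missing.

    With ``dosage=True`` fractional allele dosages in [0, 2] are allowed
    (the state after mean imputation of missing calls).
    """

    frame: pd.DataFrame
    dosage: bool = False

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicated marker identifiers")
        vals = self.frame.to_numpy(float)
        if self.dosage:
            bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 2.0))
        else:
            bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} for genotype "
                f"{self.frame.index[i]!r}, marker {self.frame.columns[j]!r}")

    @property
    def missing_rate(self) -> pd.Series:
        """Fraction of missing calls per marker."""
        return self.frame.isna().mean(axis=0)

    @property
    def n_genotypes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_markers(self) -> int:
        return self.frame.shape[1]


@dataclass
class TraitTable:
    """Genotype-level or genotype-by-environment trait values (BLUPs).

    At level ``"genotype"`` the frame is indexed by genotype; at level
    ``"genotype_env"`` by (genotype, environment).  Columns are trait names
    (seed_yield, CA, CT, vegetation indices, binned waveband reflectances
    such as ``S1_R705``).
    """

    level: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("genotype", "genotype_env"):
            raise ValueError(f"unknown trait table level {self.level!r}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicated keys in trait table")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicated trait names in trait table")

    def columns_matching(self, prefix: str) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(prefix)]


@dataclass
class TruthRecord:
    """Ground truth retained by the simulator for recovery tests."""

    true_genetic_values: pd.Series          # genotype -> genetic yield value
    true_band_rg: pd.Series                 # wavelength -> rg with yield
    true_band_h2: pd.Series                 # wavelength -> repeatability
    true_h2_snp: float
    variance_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.abs(self.true_band_rg.to_numpy()) > 1.0 + 1e-9):
            raise ValueError("band genetic correlations outside [-1, 1]")
        h2 = self.true_band_h2.to_numpy()
        if np.any((h2 < -1e-9) | (h2 > 1.0 + 1e-9)):
            raise ValueError("band repeatabilities outside [0, 1]")
        if not 0.0 <= self.true_h2_snp <= 1.0:
            raise ValueError("true_h2_snp outside [0, 1]")


@dataclass
class ConfusionSummary:
    """Selection outcome at a fixed selection intensity.

    TP/TN/FP/FN count test genotypes against membership in the top
    ``selection_intensity`` fraction by observed vs predicted rank.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    selection_intensity: float

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def SPE(self) -> float:
        """Specificity TN / (TN + FP)."""
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else np.nan

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else np.nan

    @property
    def BAC(self) -> float:
        """Balanced accuracy: mean of sensitivity and specificity."""
        return 0.5 * (self.sensitivity + self.SPE)

    @property
    def FS(self) -> float:
        """F score 2TP / (2TP + FP + FN)."""
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom else np.nan

    def as_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
                "SPE": self.SPE, "BAC": self.BAC, "FS": self.FS,
                "selection_intensity": self.selection_intensity}
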