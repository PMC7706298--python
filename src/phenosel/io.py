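"""Validating readers and writers for the on-disk trial data layout.

All files are plain CSV (comma-separated, UTF-8, ``.`` decimal, ``NA`` for
missing).  A fixture directory holds::

    plots.csv        one row per experimental plot (design + yield)
    spectra_S1.csv   wide reflectance, one column per wavelength, per scan
    spectra_S2.csv
    canopy.csv       canopy area / temperature per plot and stage
    snps.csv         genotype x marker additive codes
    truth.yaml       simulator ground truth (synthetic fixtures only)
    config.yaml      generating configuration (synthetic fixtures only)

Identifiers (environment, replicate, block, genotype, plot) are opaque
strings; no positional semantics are attached.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SpectraMatrix, TraitTable

__all__ = [
    "read_plot_table", "write_plot_table",
    "read_spectra", "write_spectra",
    "read_genotype_matrix", "write_genotype_matrix",
    "read_canopy_table", "write_canopy_table",
    "read_trait_table", "write_trait_table",
    "fixture_inventory",
]

NA = "NA"

PLOT_COLUMNS = ["environment", "replicate", "block", "pass", "plot_id",
                "genotype", "stand_count", "shatter_score", "moisture",
                "seed_yield"]

_ID_COLS = ["environment", "replicate", "block", "pass", "plot_id", "genotype"]


class SchemaError(ValueError):
    """A file does not match the declared column layout."""


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    _check_rectangular(path)
    return path


def _check_rectangular(path: Path) -> None:
    """Reject silently truncated CSVs (rows with missing trailing fields)."""
    with open(path) as fh:
        header = fh.readline()
        n = header.count(",")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and line.count(",") != n:
                raise ValueError(
                    f"{path}: line {lineno} has {line.count(',') + 1} fields, "
                    f"header has {n + 1} (truncated file?)")


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plot table.

    Raises :class:`SchemaError` on missing columns and ``ValueError`` (with
    offending row numbers) on out-of-range values or duplicated
    (environment, plot_id) keys.
    """
    path = _check_path(path)
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     dtype={c: str for c in _ID_COLS})
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df[PLOT_COLUMNS].copy()
    for col, lo, hi in [("shatter_score", 1, 5), ("stand_count", 0, None)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (
            vals.isna() | (vals < lo) | ((hi is not None) & (vals > hi))
            | (vals != vals.round())
        )
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
            raise ValueError(
                f"{path}: invalid {col} at file line(s) {rows}")
        df[col] = vals.astype("Int64")
    for col in ("moisture", "seed_yield"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df["moisture"].notna() & ~df["moisture"].between(0, 1, inclusive="left")
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"{path}: moisture outside [0, 1) at line(s) {rows}")
    if (df["seed_yield"].dropna() < 0).any():
        raise ValueError(f"{path}: negative seed_yield")
    dup = df.duplicated(subset=["environment", "plot_id"])
    if dup.any():
        keys = df.loc[dup, ["environment", "plot_id"]].iloc[0].tolist()
        raise ValueError(f"{path}: duplicated (environment, plot_id) key {keys}")
    return df


def write_plot_table(df: pd.DataFrame, path: str | Path) -> None:
    df[PLOT_COLUMNS].to_csv(path, index=False, na_rep=NA)


def read_spectra(path: str | Path, stage: str) -> SpectraMatrix:
    """Read wide per-scan reflectance; wavelength grid parsed from headers."""
    path = _check_path(path)
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     dtype={"environment": str, "plot_id": str})
    for col in ("environment", "plot_id", "scan"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    band_cols = [c for c in df.columns
                 if c not in ("environment", "plot_id", "scan")]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric wavelength column") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise SchemaError(
            f"{path}: wavelength columns are not strictly increasing")
    refl = df[band_cols].apply(pd.to_numeric).astype(float)
    n_over = int((refl.to_numpy() > 1.0).sum())
    if n_over:
        warnings.warn(
            f"{path}: {n_over} reflectance values exceed 1.0 "
            "(possible sun glint); retained", stacklevel=2)
    refl.index = pd.MultiIndex.from_frame(
        df[["environment", "plot_id", "scan"]])
    refl.columns = [int(w) if float(w).is_integer() else float(w)
                    for w in wavelengths]
    return SpectraMatrix(stage=stage, wavelengths=wavelengths, frame=refl)


def write_spectra(spectra: SpectraMatrix, path: str | Path) -> None:
    out = spectra.frame.reset_index()
    out.to_csv(path, index=False, na_rep=NA)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a genotype x marker matrix of additive codes {0,1,2,NA}."""
    path = _check_path(path)
    df = pd.read_csv(path, index_col=0, na_values=[NA],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric genotype code") from exc
    return GenotypeMatrix(frame=df.astype(float))


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    out = gm.frame.copy()
    # keep integer formatting for called genotypes
    out = out.astype("Int64")
    out.to_csv(path, na_rep=NA, index_label="genotype")


CANOPY_COLUMNS = ["environment", "plot_id", "stage", "CA", "CT"]


def read_canopy_table(path: str | Path) -> pd.DataFrame:
    path = _check_path(path)
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     dtype={"environment": str, "plot_id": str, "stage": str})
    missing = [c for c in CANOPY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("CA", "CT"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df[CANOPY_COLUMNS]


def write_canopy_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CANOPY_COLUMNS].to_csv(path, index=False, na_rep=NA)


def read_trait_table(path: str | Path, level: str) -> TraitTable:
    path = _check_path(path)
    idx = ["genotype"] if level == "genotype" else ["genotype", "environment"]
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False,
                     dtype={c: str for c in idx})
    missing = [c for c in idx if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing key columns {missing}")
    df = df.set_index(idx)
    return TraitTable(level=level, frame=df.apply(pd.to_numeric))


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.frame.to_csv(path, na_rep=NA)


def fixture_inventory(directory: str | Path) -> dict:
    """Describe a fixture directory: files present and spectra coverage.

    Environments without spectral data (sparse phenomics, as happens when
    sensors are not deployed at every site) are reported per stage.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such fixture directory: {directory}")
    inv: dict = {"files": sorted(p.name for p in directory.glob("*"))}
    if (directory / "plots.csv").exists():
        plots = read_plot_table(directory / "plots.csv")
        envs = set(plots["environment"])
        inv["environments"] = sorted(envs)
        sparse = {}
        for stage_file in sorted(directory.glob("spectra_*.csv")):
            stage = stage_file.stem.split("_", 1)[1]
            sp = read_spectra(stage_file, stage)
            covered = set(sp.frame.index.get_level_values("environment"))
            sparse[stage] = sorted(envs - covered)
        inv["environments_without_spectra"] = sparse
    return inv
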