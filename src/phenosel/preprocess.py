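"""Plot-quality filtering, trait derivation and spectral preprocessing.

Order of operations for the spectral pipeline:

1. average the two reflectance scans per plot;
2. estimate per-waveband repeatability across environments,
   H2 = s2_g / (s2_g + s2_gxe/e + s2_eps/(r e)), from the REML fit of the
   full trial model;
3. drop wavebands with H2 below the threshold (default 0.3);
4. compute vegetation indices;
5. average retained 1-nm bands into contiguous 10-nm bins.

Yield preprocessing removes low-emergence plots (stand count more than two
interquartile ranges below the first quartile, per environment), excludes
yield observations from plots with preharvest shatter score >= 4 (phenomics
retained), and rescales harvested yield to a 13% moisture basis preserving
dry matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import SpectraMatrix
from .mixedmodel import TERMS_FULL, MixedModelDesign

__all__ = [
    "filter_low_emergence", "filter_shattered", "adjust_moisture",
    "normalize_ct_by_pass", "average_plot_reflectance", "repeatability_index",
    "estimate_band_repeatability", "filter_bands_by_repeatability",
    "bin_wavebands", "VIDefinition", "DEFAULT_VI_REGISTRY", "compute_vi",
]


def repeatability_index(sigma2_g: float, sigma2_gxe: float, sigma2_eps: float,
                        e: int, r: int) -> float:
    """Entry-mean repeatability H2 = s2_g / (s2_g + s2_gxe/e + s2_eps/(r e)).

    Negative variance inputs are truncated at zero.  ``e`` environments and
    ``r`` replicates set how much the interaction and residual variances
    average out of a genotype mean.
    """
    s2g = max(sigma2_g, 0.0)
    denom = s2g + max(sigma2_gxe, 0.0) / e + max(sigma2_eps, 0.0) / (r * e)
    return s2g / denom if denom > 0 else 0.0


# ------------------------------------------------------------------ #
# plot-quality filters
# ------------------------------------------------------------------ #

def filter_low_emergence(plots: pd.DataFrame,
                         n_iqr: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop plots whose stand count falls more than ``n_iqr`` interquartile
    ranges below the first quartile of their environment.

    Quartiles use linear interpolation between order statistics.  Removal is
    strict (< threshold); with IQR = 0 only counts strictly below Q1 go.
    Returns (retained plots, removed plots).
    """
    if plots["stand_count"].isna().all():
        raise ValueError("all stand counts missing; emergence filter undefined")
    removed_masks = []
    for env, sub in plots.groupby("environment"):
        counts = sub["stand_count"].dropna().astype(float)
        if counts.empty:
            raise ValueError(f"environment {env!r} has no stand counts")
        q1, q3 = np.percentile(counts, [25, 75])
        thresh = q1 - n_iqr * (q3 - q1)
        removed_masks.append(sub.index[sub["stand_count"] < thresh])
    removed_idx = removed_masks[0].append(removed_masks[1:]) if removed_masks \
        else plots.index[:0]
    removed = plots.loc[plots.index.isin(removed_idx)]
    retained = plots.drop(index=removed.index)
    return retained, removed


def filter_shattered(plots: pd.DataFrame,
                     threshold: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude yield observations from plots with shatter score >= threshold.

    Only the yield value is blanked; the plot row (and its phenomics) is
    retained.  Returns (table with censored yields, the affected plot rows).
    """
    out = plots.copy()
    mask = out["shatter_score"].notna() & (out["shatter_score"] >= threshold)
    removed = plots.loc[mask]
    out.loc[mask, "seed_yield"] = np.nan
    return out, removed


def adjust_moisture(yield_wet, moisture, basis: float = 0.13):
    """Rescale harvested yield to a common moisture basis (default 13%).

    Dry matter is preserved: ``y_basis = y_wet * (1 - m) / (1 - basis)``.
    """
    yield_wet = np.asarray(yield_wet, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    if np.any(moisture >= 1.0) or np.any(moisture < 0.0):
        raise ValueError("moisture must lie in [0, 1)")
    return yield_wet * (1.0 - moisture) / (1.0 - basis)


def normalize_ct_by_pass(ct: pd.Series, passes: pd.Series) -> pd.Series:
    """Center canopy temperature within each data-collection pass.

    Removes additive ambient-temperature drift between passes while
    preserving genotype contrasts within a pass.  Each pass mean maps to 0.
    """
    if len(ct) != len(passes):
        raise ValueError("ct and pass labels differ in length")
    sizes = passes.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        warnings.warn(
            f"{len(singletons)} pass(es) contain a single plot; their "
            "normalized CT is 0 by construction", stacklevel=2)
    return ct - ct.groupby(passes.to_numpy()).transform("mean")


# ------------------------------------------------------------------ #
# spectra
# ------------------------------------------------------------------ #

def average_plot_reflectance(spectra: SpectraMatrix) -> SpectraMatrix:
    """Average the per-plot scans into one spectrum per plot.

    Plots missing a scan (or with NA values in one scan) fall back to the
    available scan with a warning.
    """
    frame = spectra.frame
    if "scan" not in (frame.index.names or []):
        raise ValueError("spectra have already been scan-averaged")
    grouped = frame.groupby(level=["environment", "plot_id"], sort=True)
    counts = grouped.count()
    n_scans = frame.index.get_level_values("scan").nunique()
    incomplete = (counts < n_scans).any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} plot(s) missing a reflectance scan; "
            "single available scan used", stacklevel=2)
    mean = grouped.mean()
    return SpectraMatrix(stage=spectra.stage,
                         wavelengths=spectra.wavelengths.copy(),
                         frame=mean)


def estimate_band_repeatability(
    spectra: SpectraMatrix, plots: pd.DataFrame,
    terms: dict[str, tuple[str, ...]] | None = None,
    tol: float = 1e-6, max_iter: int = 500,
) -> pd.DataFrame:
    """Per-waveband repeatability from REML variance components.

    Fits the full trial model to every band (bands share one design, so the
    factorization is reused and adjacent-band estimates warm-start the EM)
    and evaluates H2 = s2_g / (s2_g + s2_gxe/e + s2_eps/(r e)) with ``e`` the
    number of environments and ``r`` the replicate count.

    Requires scan-averaged spectra and at least two environments and two
    replicates.
    """
    if "scan" in (spectra.frame.index.names or []):
        raise ValueError("average scans before estimating repeatability")
    if terms is None:
        terms = TERMS_FULL
    design_cols = sorted({c for cols in terms.values() for c in cols})
    meta = plots.set_index(["environment", "plot_id"])[
        [c for c in design_cols if c not in ("environment", "plot_id")]]
    frame = spectra.frame.join(meta, how="inner").reset_index()
    if frame["environment"].nunique() < 2:
        raise ValueError(
            "repeatability across environments requires >= 2 environments; "
            "a single-environment reduced formula is not supported")
    if frame.groupby("environment")["replicate"].nunique().min() < 2:
        raise ValueError("repeatability requires >= 2 replicates per environment")
    e = frame["environment"].nunique()
    r = int(frame.groupby("environment")["replicate"].nunique().median())

    design = MixedModelDesign(frame, terms)
    band_cols = list(spectra.frame.columns)
    rows = []
    start = None
    for col in band_cols:
        fit = design.fit(frame[col].to_numpy(float), tol=tol,
                         max_iter=max_iter, start=start)
        start = dict(fit.varcomps)      # warm start for the adjacent band
        s2g = max(fit.varcomps.get("genotype", 0.0), 0.0)
        s2gxe = max(fit.varcomps.get("gxe", 0.0), 0.0)
        s2e = max(fit.varcomps["residual"], 0.0)
        rows.append({
            "band": col, "sigma2_g": s2g, "sigma2_gxe": s2gxe,
            "sigma2_eps": s2e, "r": r, "e": e,
            "H2": repeatability_index(s2g, s2gxe, s2e, e, r),
        })
    return pd.DataFrame(rows).set_index("band")


def filter_bands_by_repeatability(estimates: pd.DataFrame,
                                  threshold: float = 0.3) -> list:
    """Bands retained at the repeatability threshold (strict ``H2 < t`` drop)."""
    retained = estimates.index[estimates["H2"] >= threshold].tolist()
    return retained


def bin_wavebands(frame: pd.DataFrame, wavelengths: np.ndarray | None = None,
                  width: float = 10.0,
                  grid_step: float | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average retained bands into contiguous ``width``-nm blocks.

    ``frame`` holds one column per retained wavelength (column labels are
    nm).  Blocks are anchored at the lowest wavelength of each contiguous
    segment of the retained grid and trailing partial blocks are dropped, so
    1780 contiguous 1-nm bands yield exactly 178 ten-band features.

    Returns (binned frame with columns ``R<center>``, bin table with the
    wavelength span of every bin).
    """
    if frame.shape[1] == 0:
        raise ValueError("no retained bands to bin")
    if wavelengths is None:
        wavelengths = np.array([float(c) for c in frame.columns])
    wavelengths = np.asarray(wavelengths, dtype=float)
    if grid_step is None:
        diffs = np.diff(np.sort(wavelengths))
        grid_step = float(diffs.min()) if len(diffs) else 1.0
    per_bin = max(int(round(width / grid_step)), 1)
    order = np.argsort(wavelengths)
    lam = wavelengths[order]
    cols = frame.columns[order]

    # split into contiguous segments of the underlying grid
    breaks = np.flatnonzero(np.diff(lam) > grid_step * 1.5)
    segments = np.split(np.arange(len(lam)), breaks + 1)
    binned = {}
    bins = []
    for seg in segments:
        n_full = len(seg) // per_bin
        for b in range(n_full):
            idx = seg[b * per_bin:(b + 1) * per_bin]
            center = int(np.floor(lam[idx].mean() + 0.5))
            label = f"R{center}"
            binned[label] = frame[cols[idx]].mean(axis=1)
            bins.append({"label": label, "start": lam[idx].min(),
                         "end": lam[idx].max(), "center": center,
                         "n_bands": len(idx)})
    if not bins:
        raise ValueError(
            f"retained bands form no complete {width}-nm block")
    binned_frame = pd.DataFrame(binned, index=frame.index)
    return binned_frame, pd.DataFrame(bins)


# ------------------------------------------------------------------ #
# vegetation indices
# ------------------------------------------------------------------ #

@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation index over reflectances at fixed wavelengths."""

    name: str
    bands: tuple[float, ...]
    func: Callable


def _safe_div(num, den, name):
    den = np.asarray(den, dtype=float)
    zero = den == 0
    if np.any(zero):
        warnings.warn(f"{name}: zero denominator in {int(zero.sum())} "
                      "plot(s); NaN returned", stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    out[zero] = np.nan
    return out


#: Standard literature definitions of the indices used for yield prediction.
DEFAULT_VI_REGISTRY: tuple[VIDefinition, ...] = (
    VIDefinition("NDVI", (800, 670),
                 lambda r800, r670: _safe_div(r800 - r670, r800 + r670, "NDVI")),
    VIDefinition("VREI2", (734, 747, 715, 726),
                 lambda r734, r747, r715, r726:
                 _safe_div(r734 - r747, r715 + r726, "VREI2")),
    VIDefinition("NWI", (970, 900),
                 lambda r970, r900: _safe_div(r970 - r900, r970 + r900, "NWI")),
    VIDefinition("RARSb", (675, 650, 700),
                 lambda r675, r650, r700: _safe_div(r675, r650 * r700, "RARSb")),
    VIDefinition("RARSc", (760, 500),
                 lambda r760, r500: _safe_div(r760, r500, "RARSc")),
    VIDefinition("NMDI", (860, 1640, 2130),
                 lambda r860, r1640, r2130:
                 _safe_div(r860 - (r1640 - r2130), r860 + (r1640 - r2130),
                           "NMDI")),
)


def _band_lookup(nm: float, source, bin_table: pd.DataFrame | None,
                 vi_name: str) -> pd.Series:
    if bin_table is not None:
        hit = bin_table[(bin_table["start"] <= nm) & (nm <= bin_table["end"])]
        if hit.empty:
            raise KeyError(
                f"{vi_name}: no retained waveband bin contains {nm} nm")
        return source[hit["label"].iloc[0]]
    if isinstance(source, SpectraMatrix):
        lam = source.wavelengths
        j = int(np.argmin(np.abs(lam - nm)))
        # nearest-band lookup; tolerance widens with a coarse grid
        step = float(np.median(np.diff(lam))) if len(lam) > 1 else 1.0
        if abs(lam[j] - nm) > max(15.0, 0.6 * step):
            raise KeyError(
                f"{vi_name}: no measured band near {nm} nm "
                f"(closest is {lam[j]} nm)")
        return source.frame.iloc[:, j]
    raise TypeError("source must be a SpectraMatrix or a binned frame "
                    "with its bin table")


def compute_vi(source, bin_table: pd.DataFrame | None = None,
               registry: tuple[VIDefinition, ...] = DEFAULT_VI_REGISTRY
               ) -> pd.DataFrame:
    """Compute vegetation indices from raw spectra or binned features.

    ``source`` is either a scan-averaged :class:`SpectraMatrix` (reflectance
    read from the nearest measured band) or a binned feature frame paired
    with its ``bin_table`` (reflectance read from the bin containing the
    wavelength).  A missing required band raises, naming index and band.
    """
    out = {}
    for vi in registry:
        series = [_band_lookup(nm, source, bin_table, vi.name)
                  for nm in vi.bands]
        vals = vi.func(*[s.to_numpy(float) for s in series])
        out[vi.name] = vals
    index = source.frame.index if isinstance(source, SpectraMatrix) \
        else source.index
    return pd.DataFrame(out, index=index)
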