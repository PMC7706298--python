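"""SNP QC, genomic relationships, SNP-based heritability and genetic
correlations.

The genomic relationship matrix follows the centered-allele-frequency form

    A = W W' / (2 * sum_k p_k (1 - p_k)),   W = M - 2 p,

with ``M`` the genotype x marker matrix of additive codes.  SNP-based
heritability comes from the one-random-term genomic model

    y = mu + u + e,   u ~ N(0, A s2_g),  e ~ N(0, s2_e I),
    h2_snp = s2_g / (s2_g + s2_e),

fit by exact REML: rotating by the eigenvectors of A diagonalizes the
covariance so the restricted likelihood is evaluated in O(n) per candidate,
and a bounded scalar search over h2 (with the total variance profiled out)
finds the optimum.  Genetic correlations between trait pairs use the
bivariate extension with 2x2 genetic and residual covariance matrices,
optimized over their Cholesky factors in the same rotated space.

Phenotype inputs are the across-environment (Method 2) genotype BLUPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as sopt

from .datatypes import GenotypeMatrix

__all__ = ["GRM", "GenomicModelFit", "GeneticCorrelationEstimate",
           "snp_qc", "compute_grm", "estimate_h2_snp",
           "estimate_genetic_correlation"]

_RIDGE = 1e-8


@dataclass
class GRM:
    """Additive genomic relationship matrix with the frequencies used."""

    matrix: pd.DataFrame
    allele_freqs: pd.Series

    @property
    def genotypes(self) -> pd.Index:
        return self.matrix.index

    def eigendecompose(self, jitter: float = _RIDGE):
        vals, vecs = np.linalg.eigh(self.matrix.to_numpy())
        if vals.min() < -1e-6 * max(vals.max(), 1.0):
            raise ValueError(
                f"relationship matrix is not PSD (min eigenvalue {vals.min():.3g})")
        return np.clip(vals, jitter, None), vecs


@dataclass
class GenomicModelFit:
    mu: float
    sigma2_g: float
    sigma2_e: float
    h2_snp: float
    se_h2: float
    loglik: float
    n: int


@dataclass
class GeneticCorrelationEstimate:
    traits: tuple[str, str]
    rg: float
    se_rg: float
    genetic_cov: float
    genetic_vars: tuple[float, float]
    residual_vars: tuple[float, float]
    defined: bool = True


# ------------------------------------------------------------------ #
# marker QC and relationships
# ------------------------------------------------------------------ #

def snp_qc(gm: GenotypeMatrix, max_missing: float = 0.10,
           min_maf: float = 0.05) -> GenotypeMatrix:
    """Marker quality control: missingness filter, mean imputation, MAF filter.

    Markers missing in more than ``max_missing`` of genotypes are dropped;
    remaining missing calls are replaced by the marker mean; markers with
    minor allele frequency below ``min_maf`` (computed after imputation) are
    then removed.
    """
    frame = gm.frame
    keep = gm.missing_rate <= max_missing
    frame = frame.loc[:, keep]
    frame = frame.fillna(frame.mean(axis=0))
    p = frame.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    frame = frame.loc[:, maf >= min_maf]
    if frame.shape[1] == 0:
        raise ValueError("no markers survive quality control")
    return GenotypeMatrix(frame=frame, dosage=True)


def compute_grm(gm: GenotypeMatrix) -> GRM:
    """Additive genomic relationship matrix from a complete marker matrix."""
    frame = gm.frame
    if frame.isna().any().any():
        raise ValueError("marker matrix contains missing codes; run snp_qc first")
    if frame.shape[1] < 2:
        raise ValueError("at least 2 markers required for a relationship matrix")
    M = frame.to_numpy(float)
    p = M.mean(axis=0) / 2.0
    W = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; relationship matrix undefined")
    A = (W @ W.T) / denom
    return GRM(matrix=pd.DataFrame(A, index=frame.index, columns=frame.index),
               allele_freqs=pd.Series(p, index=frame.columns, name="p"))


# ------------------------------------------------------------------ #
# univariate genomic REML
# ------------------------------------------------------------------ #

def _align(values: pd.Series, grm: GRM) -> np.ndarray:
    missing = grm.genotypes.difference(values.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} genotypes in the GRM lack phenotypes "
            f"(e.g. {missing[0]!r})")
    return values.loc[grm.genotypes].to_numpy(float)


def _univariate_profile(h2: float, d: np.ndarray, yt: np.ndarray,
                        xt: np.ndarray, n: int):
    """Profiled restricted log-likelihood at heritability ``h2``."""
    v = h2 * d + (1.0 - h2)                      # variance up to scale
    xvx = np.sum(xt * xt / v)
    xvy = np.sum(xt * yt / v)
    ypy = np.sum(yt * yt / v) - xvy ** 2 / xvx
    s2p = ypy / (n - 1)                          # profiled total variance
    ll = -0.5 * (np.sum(np.log(v)) + np.log(xvx)
                 + (n - 1) * np.log(s2p) + (n - 1))
    return ll, s2p, xvy / xvx


def _reml_loglik_uni(s2g: float, s2e: float, d, yt, xt) -> float:
    v = s2g * d + s2e
    xvx = np.sum(xt * xt / v)
    xvy = np.sum(xt * yt / v)
    ypy = np.sum(yt * yt / v) - xvy ** 2 / xvx
    return -0.5 * (np.sum(np.log(v)) + np.log(xvx) + ypy)


def estimate_h2_snp(values: pd.Series, grm: GRM) -> GenomicModelFit:
    """SNP-based heritability of a genotype-level phenotype by exact REML."""
    y = _align(values, grm)
    n = len(y)
    if n < 10:
        raise ValueError("too few genotypes for heritability estimation")
    d, U = grm.eigendecompose()
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    res = sopt.minimize_scalar(
        lambda h: -_univariate_profile(h, d, yt, xt, n)[0],
        bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8})
    h2 = float(res.x)
    ll, s2p, mu = _univariate_profile(h2, d, yt, xt, n)
    s2g, s2e = h2 * s2p, (1.0 - h2) * s2p

    # SE by the delta method on the observed information in (s2g, s2e)
    se_h2 = _se_h2(s2g, s2e, d, yt, xt)
    return GenomicModelFit(mu=float(mu), sigma2_g=float(s2g),
                           sigma2_e=float(s2e), h2_snp=h2, se_h2=se_h2,
                           loglik=float(ll), n=n)


def _se_h2(s2g: float, s2e: float, d, yt, xt) -> float:
    eps_g = max(s2g, 1e-8) * 1e-4
    eps_e = max(s2e, 1e-8) * 1e-4

    def f(a, b):
        return _reml_loglik_uni(max(a, 1e-12), max(b, 1e-12), d, yt, xt)

    H = np.empty((2, 2))
    H[0, 0] = (f(s2g + eps_g, s2e) - 2 * f(s2g, s2e)
               + f(s2g - eps_g, s2e)) / eps_g ** 2
    H[1, 1] = (f(s2g, s2e + eps_e) - 2 * f(s2g, s2e)
               + f(s2g, s2e - eps_e)) / eps_e ** 2
    H[0, 1] = H[1, 0] = (
        f(s2g + eps_g, s2e + eps_e) - f(s2g + eps_g, s2e - eps_e)
        - f(s2g - eps_g, s2e + eps_e) + f(s2g - eps_g, s2e - eps_e)
    ) / (4 * eps_g * eps_e)
    try:
        cov = np.linalg.inv(-H)
        tot = s2g + s2e
        grad = np.array([s2e, -s2g]) / tot ** 2
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


# ------------------------------------------------------------------ #
# bivariate genomic REML (genetic correlation)
# ------------------------------------------------------------------ #

def _bivariate_loglik(G0: np.ndarray, R0: np.ndarray, d, Yt, xt) -> float:
    """Restricted log-likelihood in the eigen-rotated space.

    ``Yt`` is (n, 2) rotated phenotypes, ``xt`` the rotated intercept.
    V_k = d_k G0 + R0 is 2x2 per component; everything vectorizes.
    """
    V = d[:, None, None] * G0[None] + R0[None]          # (n, 2, 2)
    det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(V[:, 0, 0] <= 0):
        return -np.inf
    inv = np.empty_like(V)
    inv[:, 0, 0] = V[:, 1, 1] / det
    inv[:, 1, 1] = V[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -V[:, 0, 1] / det
    ViY = np.einsum("kij,kj->ki", inv, Yt)
    XtVX = np.einsum("k,kij->ij", xt ** 2, inv)          # 2x2
    XtVy = np.einsum("k,kij,kj->i", xt, inv, Yt)
    ytVy = float(np.einsum("ki,ki->", Yt, ViY))
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    ypy = ytVy - float(XtVy @ beta)
    return -0.5 * (float(np.sum(np.log(det))) + logdet_x + ypy)


def _theta_to_cov(theta: np.ndarray):
    lg = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    lr = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
    return lg @ lg.T + _RIDGE * np.eye(2), lr @ lr.T + _RIDGE * np.eye(2)


def estimate_genetic_correlation(trait_a: pd.Series, trait_b: pd.Series,
                                 grm: GRM,
                                 names: tuple[str, str] | None = None
                                 ) -> GeneticCorrelationEstimate:
    """Genetic correlation between two genotype-level traits.

    Bivariate genomic REML with unstructured 2x2 genetic and residual
    covariance matrices; ``rg = cov_g / sqrt(var_g,a * var_g,b)``, clipped
    to [-1, 1] with a warning if optimization steps marginally outside.
    """
    if names is None:
        names = (str(trait_a.name or "trait_a"), str(trait_b.name or "trait_b"))
    ya = _align(trait_a, grm)
    yb = _align(trait_b, grm)
    n = len(ya)
    # standardize for optimizer conditioning; rg is scale-invariant
    sa, sb = ya.std(), yb.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant trait; genetic correlation undefined")
    za, zb = (ya - ya.mean()) / sa, (yb - yb.mean()) / sb

    d, U = grm.eigendecompose()
    Yt = np.column_stack([U.T @ za, U.T @ zb])
    xt = U.T @ np.ones(n)

    # starting values from univariate fits and the phenotypic correlation
    fits = [estimate_h2_snp(pd.Series(z, index=grm.genotypes), grm)
            for z in (za, zb)]
    h2a, h2b = (max(min(f.h2_snp, 0.95), 0.05) for f in fits)
    rp = float(np.corrcoef(za, zb)[0, 1]) * 0.8

    def pack(g11, g12, g22, r11, r12, r22):
        lg = np.linalg.cholesky(np.array([[g11, g12], [g12, g22]]))
        lr = np.linalg.cholesky(np.array([[r11, r12], [r12, r22]]))
        return np.array([np.log(lg[0, 0]), lg[1, 0], np.log(lg[1, 1]),
                         np.log(lr[0, 0]), lr[1, 0], np.log(lr[1, 1])])

    theta0 = pack(h2a, rp * np.sqrt(h2a * h2b) * 0.9, h2b,
                  1 - h2a, rp * np.sqrt((1 - h2a) * (1 - h2b)) * 0.5, 1 - h2b)

    def neg(theta):
        G0, R0 = _theta_to_cov(theta)
        return -_bivariate_loglik(G0, R0, d, Yt, xt)

    res = sopt.minimize(neg, theta0, method="Nelder-Mead",
                        options={"maxiter": 4000, "xatol": 1e-7,
                                 "fatol": 1e-9})
    G0, R0 = _theta_to_cov(res.x)

    var_scale = np.array([sa ** 2, sb ** 2])
    ga, gb = G0[0, 0], G0[1, 1]
    tot_a, tot_b = ga + R0[0, 0], gb + R0[1, 1]
    defined = (ga > 1e-4 * tot_a) and (gb > 1e-4 * tot_b)
    if not defined:
        warnings.warn(
            f"genetic variance of {names[0] if ga <= 1e-4 * tot_a else names[1]} "
            "is approximately zero; genetic correlation undefined", stacklevel=2)
        rg = np.nan
        se = np.nan
    else:
        rg = float(G0[0, 1] / np.sqrt(ga * gb))
        if abs(rg) > 1.0:
            warnings.warn(f"genetic correlation {rg:.3f} outside [-1, 1]; "
                          "clipped", stacklevel=2)
            rg = float(np.clip(rg, -1.0, 1.0))
        se = _se_rg(G0, R0, d, Yt, xt)
    return GeneticCorrelationEstimate(
        traits=names, rg=rg, se_rg=se,
        genetic_cov=float(G0[0, 1] * sa * sb),
        genetic_vars=(float(ga * var_scale[0]), float(gb * var_scale[1])),
        residual_vars=(float(R0[0, 0] * var_scale[0]),
                       float(R0[1, 1] * var_scale[1])),
        defined=defined)


def _se_rg(G0, R0, d, Yt, xt) -> float:
    """Delta-method SE of rg from the observed information in the
    unconstrained covariance parameters (g11, g12, g22, r11, r12, r22)."""
    par = np.array([G0[0, 0], G0[0, 1], G0[1, 1],
                    R0[0, 0], R0[0, 1], R0[1, 1]])

    def ll(p):
        G = np.array([[p[0], p[1]], [p[1], p[2]]])
        R = np.array([[p[3], p[4]], [p[4], p[5]]])
        return _bivariate_loglik(G, R, d, Yt, xt)

    k = len(par)
    eps = np.maximum(np.abs(par), 1e-4) * 1e-3
    H = np.empty((k, k))
    f0 = ll(par)
    for i in range(k):
        for j in range(i, k):
            pi, pj = np.zeros(k), np.zeros(k)
            pi[i] = eps[i]
            pj[j] = eps[j]
            if i == j:
                H[i, i] = (ll(par + pi) - 2 * f0 + ll(par - pi)) / eps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(par + pi + pj) - ll(par + pi - pj)
                    - ll(par - pi + pj) + ll(par - pi - pj)
                ) / (4 * eps[i] * eps[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan
    g11, g12, g22 = par[0], par[1], par[2]
    rt = np.sqrt(g11 * g22)
    grad = np.zeros(k)
    grad[0] = -0.5 * g12 / (rt * g11)
    grad[1] = 1.0 / rt
    grad[2] = -0.5 * g12 / (rt * g22)
    var = float(grad @ cov @ grad)
    if not np.isfinite(var) or var <= 0:
        return np.nan
    return float(np.sqrt(var))
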