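"""Variance-component mixed models for multi-environment trials.

Implements REML estimation for models of the form

    y = mu + sum_i Z_i u_i + e,    u_i ~ N(0, sigma_i^2 I),  e ~ N(0, sigma_e^2 I)

where every ``u_i`` is a categorical random term (environment, replicate,
incomplete block, genotype, genotype-by-environment).  The full trial model is

    y_ijkl = mu + E_i + R_j + B_k(j) + G_l + (ExG)_il + eps_ijkl

with all terms random, as is standard for BLUP extraction from alpha-lattice
multi-environment trials.  Estimation is EM-REML on Henderson's mixed-model
equations; the largest random term (typically genotype-by-environment) is
absorbed so each iteration only factorizes the dense Schur complement over
the remaining effects.  This keeps full-size fits (thousands of plots,
thousands of random-effect levels) in the tens of milliseconds per iteration.

Genotype BLUPs are obtained directly from the mixed-model equations at the
REML estimates.  Conditional residuals are studentized with their exact
prediction variances for outlier screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "MixedModelFit",
    "MixedModelDesign",
    "fit_mixed_model",
    "remove_outliers_studentized",
    "blups_method1",
    "blups_method2",
    "TERMS_FULL",
    "TERMS_WITHIN_ENV",
]

#: term name -> columns whose combination defines the factor levels.
#: Replicates and blocks are nested (unique per environment / replicate).
TERMS_FULL = {
    "environment": ("environment",),
    "replicate": ("environment", "replicate"),
    "block": ("environment", "replicate", "block"),
    "genotype": ("genotype",),
    "gxe": ("genotype", "environment"),
}

#: reduced model used within a single environment (all environment terms gone)
TERMS_WITHIN_ENV = {
    "replicate": ("replicate",),
    "block": ("replicate", "block"),
    "genotype": ("genotype",),
}

_SMALL = 1e-10


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge within the iteration cap."""


@dataclass
class MixedModelFit:
    """REML fit of an all-random variance-components model.

    ``varcomps`` maps term name (plus ``"residual"``) to its variance
    estimate; ``blups`` maps term name to a level-indexed Series of predicted
    random effects (shrunken toward zero, summing to approximately zero).
    """

    mu: float
    varcomps: dict[str, float]
    blups: dict[str, pd.Series]
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    history: np.ndarray | None = None
    _design: "MixedModelDesign | None" = field(default=None, repr=False)
    _leverage: np.ndarray | None = field(default=None, repr=False)

    @property
    def genotype_blups(self) -> pd.Series:
        return self.blups["genotype"]

    def predicted_genotype_means(self) -> pd.Series:
        """mu + genotype BLUP, the exported predicted genotype mean."""
        return self.mu + self.blups["genotype"]

    def leverage(self) -> np.ndarray:
        """Observation leverages h_ii = w_i' C^{-1} w_i from the MME."""
        if self._leverage is None:
            if self._design is None:
                raise ValueError("fit was detached from its design")
            self._leverage = self._design._leverage()
        return self._leverage

    def studentized_residuals(self) -> np.ndarray:
        """Internally studentized conditional residuals e_i / (s_e sqrt(1-h_ii))."""
        s2e = self.varcomps["residual"]
        h = np.clip(self.leverage(), 0.0, 1.0 - 1e-8)
        return self.residuals / np.sqrt(s2e * (1.0 - h))


class MixedModelDesign:
    """Pre-factorized design for repeated REML fits sharing one layout.

    Building the design once and calling :meth:`fit` per response vector is
    the fast path for per-waveband repeatability screens, where thousands of
    traits share a single field layout.
    """

    def __init__(self, frame: pd.DataFrame, terms: dict[str, tuple[str, ...]],
                 min_levels: int = 2):
        self.n = len(frame)
        if self.n == 0:
            raise ValueError("empty observation table")
        self.terms: dict[str, tuple[str, ...]] = {}
        self.codes: dict[str, np.ndarray] = {}
        self.levels: dict[str, pd.Index] = {}
        dropped = []
        for name, cols in terms.items():
            for c in cols:
                if c not in frame.columns:
                    raise KeyError(f"design column {c!r} missing from table")
            key = frame[list(cols)].astype(str).agg("|".join, axis=1)
            codes, lev = pd.factorize(key, sort=True)
            if len(lev) < min_levels:
                dropped.append(name)
                continue
            self.terms[name] = cols
            self.codes[name] = codes.astype(np.int64)
            self.levels[name] = pd.Index(lev, name=name)
        if dropped:
            warnings.warn(
                f"random terms dropped (fewer than {min_levels} levels): {dropped}",
                stacklevel=2,
            )
        # drop terms whose level partition duplicates an earlier term
        # (e.g. genotype-by-environment in a single-environment subset)
        seen: dict = {}
        dup = []
        for name in list(self.terms):
            key = self.codes[name].tobytes()
            if key in seen:
                dup.append(name)
                del self.terms[name], self.codes[name], self.levels[name]
            else:
                seen[key] = name
        if dup:
            warnings.warn(
                f"random terms dropped (confounded with an earlier term): {dup}",
                stacklevel=2)
        if not self.terms:
            raise ValueError("no estimable random terms in the model")
        self.term_names = list(self.terms)
        self.q = {t: len(self.levels[t]) for t in self.term_names}
        # absorb the largest random term
        self.absorbed = max(self.term_names, key=lambda t: self.q[t])
        self.dense_terms = [t for t in self.term_names if t != self.absorbed]
        # dense design F = [1 | Z_t for dense t]; slices index into F columns
        self.m = 1 + sum(self.q[t] for t in self.dense_terms)
        self.slices: dict[str, slice] = {}
        off = 1
        for t in self.dense_terms:
            self.slices[t] = slice(off, off + self.q[t])
            off += self.q[t]
        rows = np.arange(self.n)
        blocks = [sp.csr_matrix(np.ones((self.n, 1)))]
        for t in self.dense_terms:
            z = sp.csr_matrix(
                (np.ones(self.n), (rows, self.codes[t])), shape=(self.n, self.q[t])
            )
            blocks.append(z)
        self.F = sp.hstack(blocks, format="csr")
        qa = self.q[self.absorbed]
        self.Za = sp.csr_matrix(
            (np.ones(self.n), (rows, self.codes[self.absorbed])), shape=(self.n, qa)
        )
        self.FtF = (self.F.T @ self.F).toarray()
        self.B = (self.Za.T @ self.F).tocsr()        # qa x m
        self.counts_a = np.asarray(self.Za.sum(axis=0)).ravel()
        # state from the last fit (for BLUP back-out and leverages)
        self._last: dict | None = None

    # ------------------------------------------------------------------ #

    def _assemble(self, lam_dense: np.ndarray, lam_a: float):
        """Schur complement of the MME after absorbing the big term."""
        D = self.counts_a + lam_a
        Bsc = self.B.multiply((1.0 / D)[:, None]).tocsr()   # D^{-1} B
        S = self.FtF.copy()
        diag = np.zeros(self.m)
        for i, t in enumerate(self.dense_terms):
            diag[self.slices[t]] = lam_dense[i]
        S[np.diag_indices_from(S)] += diag
        S -= (self.B.T @ Bsc).toarray()
        return S, D, Bsc

    def _mme_step(self, theta: np.ndarray, y, Fty, Zaty, yty, floor,
                  want_ai: bool = False):
        """Solve the MME at ``theta`` = [sigma2 per term..., sigma2_e].

        Returns (EM-updated theta, restricted log-likelihood at the input
        theta, aux) where aux optionally carries the REML score vector and
        average-information matrix.  The likelihood comes for free from the
        absorbed factorization:
        -2 l_R = (n-q-p) log s2e + sum_i q_i log s2_i + log|C| + y'Py,
        with log|C| = log|D| + log|Schur|.
        """
        sig, s2e = theta[:-1], theta[-1]
        lam = s2e / sig
        dense_idx = [self.term_names.index(t) for t in self.dense_terms]
        a_idx = self.term_names.index(self.absorbed)
        S, D, Bsc = self._assemble(lam[dense_idx], lam[a_idx])
        # fixed count-scale ridge: guards the exact confounding of the
        # intercept with the absorbed indicators at a vanishing shrinkage
        # ratio, without perturbing the likelihood (entries of S are counts)
        S[np.diag_indices_from(S)] += 1e-12 * self.n
        cho = sla.cho_factor(S, lower=True, check_finite=False)
        Sinv = sla.cho_solve(cho, np.eye(self.m), check_finite=False)
        sF = Sinv @ (Fty - Bsc.T @ Zaty)
        sA = (Zaty - self.B @ sF) / D
        resid_ss = yty - sF @ Fty - sA @ Zaty
        q_tot = sum(self.q.values())
        logdet_c = float(2.0 * np.sum(np.log(np.diag(cho[0])))
                         + np.sum(np.log(D)))
        loglik = -0.5 * (
            (self.n - q_tot - 1) * np.log(s2e)
            + sum(self.q[t] * np.log(sig[i])
                  for i, t in enumerate(self.term_names))
            + logdet_c + resid_ss / s2e)

        # per-term u'u and trace of C^{-1} blocks (lambda-form)
        k = len(self.term_names)
        uu = np.empty(k)
        tr_c = np.empty(k)
        diagS = np.diag(Sinv)
        for i, t in zip(dense_idx, self.dense_terms):
            sl = self.slices[t]
            uu[i] = float(sF[sl] @ sF[sl])
            tr_c[i] = float(diagS[sl].sum())
        M = Bsc @ Sinv
        uu[a_idx] = float(sA @ sA)
        tr_c[a_idx] = float(np.sum(1.0 / D) + Bsc.multiply(M).sum())

        new = np.empty_like(theta)
        for i, t in enumerate(self.term_names):
            new[i] = max((uu[i] + s2e * tr_c[i]) / self.q[t], floor)
        new[-1] = max(resid_ss / (self.n - 1), floor)

        aux = None
        if want_ai:
            qs = np.array([self.q[t] for t in self.term_names], dtype=float)
            tr_pzz = (qs - lam * tr_c) / sig          # tr(P Z_i Z_i')
            ehat = y - self.F @ sF - self.Za @ sA
            score = np.empty(k + 1)
            score[:k] = -0.5 * (tr_pzz - uu / sig ** 2)
            tr_p = (self.n - 1 - float(np.sum(qs - lam * tr_c))) / s2e
            score[k] = -0.5 * (tr_p - float(ehat @ ehat) / s2e ** 2)
            # working vectors f_i = V_i P y; AI = 0.5 F' P F via MME solves
            Fm = np.empty((self.n, k + 1))
            for i, t in zip(dense_idx, self.dense_terms):
                Fm[:, i] = sF[self.slices[t]][self.codes[t]] / sig[i]
            Fm[:, a_idx] = sA[self.codes[self.absorbed]] / sig[a_idx]
            Fm[:, k] = ehat / s2e
            FtFm = self.F.T @ Fm
            ZatFm = self.Za.T @ Fm
            sF_f = Sinv @ (FtFm - Bsc.T @ ZatFm)
            sA_f = (ZatFm - self.B @ sF_f) / D[:, None]
            PF = (Fm - self.F @ sF_f - self.Za @ sA_f) / s2e
            ai = 0.5 * (Fm.T @ PF)
            aux = {"score": score, "ai": ai}
        return new, float(loglik), aux

    _debug = False

    def fit(self, y: np.ndarray, tol: float = 1e-6, max_iter: int = 500,
            start: dict[str, float] | None = None,
            compute_leverage: bool = False) -> MixedModelFit:
        """REML fit for one response vector.

        A few EM warmup steps stabilize the estimates, then
        average-information (Newton-type) updates take over, each safeguarded
        by the restricted likelihood: a proposal that decreases it, or steps
        outside the parameter space, falls back to the (monotone) EM update.
        Components driven to the zero boundary are pinned there.
        ``max_iter`` counts likelihood evaluations.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"response length {y.shape} != design size {self.n}")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        vary = float(np.var(y))
        if vary <= 0:
            raise ValueError("constant response: variance components undefined")
        k = len(self.term_names)
        if start is None:
            theta = np.full(k + 1, vary / (k + 1))
        else:
            # EM cannot escape an exact-zero start, so warm starts are kept
            # strictly interior
            lo = 1e-3 * vary
            theta = np.array(
                [max(float(start.get(t, vary / (k + 1))), lo)
                 for t in self.term_names]
                + [max(float(start.get("residual", vary / (k + 1))), lo)])

        Fty = self.F.T @ y
        Zaty = self.Za.T @ y
        yty = float(y @ y)
        floor = _SMALL * vary
        converged = False
        n_eval = 0
        warmup = 3
        hist = [theta]
        # a component pushed below this and pinned by the AI step, or
        # repeatedly shrinking under EM, is treated as zero
        pin = 1e-8 * vary
        frozen = np.zeros(k + 1, dtype=bool)

        def rel_change(a, b):
            d = np.abs(a - b) / np.maximum(b, floor)
            d[frozen] = 0.0
            return float(np.max(d))

        # state of the accepted point and of a pending AI proposal; the
        # boundary mask travels with each candidate point and is committed
        # only when that point is accepted
        base = None            # (theta, ll, em, frozen) last accepted
        pending = None         # (base_theta, step, n_halvings, prop_frozen)
        cooldown = 0           # iterations with AI disabled after a failure
        theta_frozen = frozen
        while n_eval < max_iter:
            try:
                em, ll, aux = self._mme_step(theta, y, Fty, Zaty, yty, floor,
                                             want_ai=True)
                n_eval += 1
            except np.linalg.LinAlgError:
                if pending is None:
                    raise
                em, ll, aux = None, -np.inf, None
            if pending is not None and base is not None \
                    and ll < base[1] - 1e-9 * (1.0 + abs(base[1])):
                # AI proposal decreased the likelihood: halve, then give up
                b_theta, step, nh, prop_frozen = pending
                if nh < 3:
                    step = step / 2.0
                    theta = np.maximum(b_theta + step, floor)
                    theta_frozen = frozen | (theta <= floor)
                    theta_frozen[-1] = False
                    pending = (b_theta, step, nh + 1, theta_frozen)
                    continue
                theta = base[2].copy()              # EM update of base
                theta_frozen = base[3]
                theta[theta_frozen] = floor
                pending = None
                cooldown = 4
                continue
            # accepted: commit the candidate's boundary mask
            frozen = theta_frozen
            d_ll = ll - base[1] if base is not None else np.inf
            if self._debug:
                print(f"  eval {n_eval}: ll={ll:.6f} d_ll={d_ll:.2e} "
                      f"theta={np.round(theta / vary, 5)} "
                      f"frozen={frozen.astype(int)} pend={pending is not None}")
            prev_theta = theta
            base = (theta, ll, em, frozen)
            pending = None
            if rel_change(em, prev_theta) < tol \
                    or abs(d_ll) < 1e-9 * (1.0 + abs(ll)):
                theta = em
                converged = True
                break
            # pin components crawling to the zero boundary; release a pinned
            # component whose score says the likelihood wants it positive
            frozen = frozen.copy()
            frozen[:-1] |= (em[:-1] < pin) & (em[:-1] <= prev_theta[:-1])
            release = frozen & (aux["score"] > 0.0) if aux is not None \
                else np.zeros_like(frozen)
            release[-1] = False
            if release.any():
                frozen &= ~release
                theta = theta.copy()
                theta[release] = 1e-3 * vary     # interior restart
                em = em.copy()
                em[release] = 1e-3 * vary
            cand_step = None
            prop_frozen = frozen
            if n_eval > warmup and cooldown == 0 and aux is not None:
                # components at (or numerically indistinguishable from) the
                # boundary are held fixed: their curvature terms are too
                # ill-conditioned for a stable Newton step
                free = ~frozen & (theta > 1e-6 * vary)
                free[-1] = True
                ai = aux["ai"][np.ix_(free, free)]
                sc = aux["score"][free]
                try:
                    delta = np.linalg.solve(
                        ai + 1e-10 * np.eye(ai.shape[0]) * np.trace(ai), sc)
                    cand_step = np.zeros_like(theta)
                    cand_step[free] = delta
                    cand = theta + cand_step
                    # a proposal outside the parameter space parks that
                    # component on the zero boundary (committed only if the
                    # proposal is accepted)
                    low = cand < floor
                    cand[low] = floor
                    prop_frozen = frozen | low
                    prop_frozen[-1] = False
                    cand = np.minimum(cand, 1e3 * vary)
                    cand_step = cand - theta
                except np.linalg.LinAlgError:
                    cand_step = None
            if cand_step is not None:
                pending = (theta, cand_step, 0, prop_frozen)
                theta = theta + cand_step
                theta_frozen = prop_frozen
            else:
                cooldown = max(cooldown - 1, 0)
                theta = em
                theta_frozen = frozen
            theta[theta_frozen] = floor
            hist.append(theta)
        it = n_eval
        if not converged and base is not None:
            theta = base[2]
        sig = dict(zip(self.term_names, theta[:-1]))
        s2e = float(theta[-1])

        # final solve at the converged estimates
        lam_dense = np.array([s2e / sig[t] for t in self.dense_terms])
        lam_a = s2e / sig[self.absorbed]
        S, D, Bsc = self._assemble(lam_dense, lam_a)
        S[np.diag_indices_from(S)] += 1e-12 * self.n
        cho = sla.cho_factor(S, lower=True, check_finite=False)
        Sinv = sla.cho_solve(cho, np.eye(self.m), check_finite=False)
        sF = Sinv @ (Fty - Bsc.T @ Zaty)
        sA = (Zaty - self.B @ sF) / D
        self._last = {"Sinv": Sinv, "D": D, "Bsc": Bsc, "s2e": s2e}

        mu = float(sF[0])
        blups = {}
        for t in self.dense_terms:
            blups[t] = pd.Series(sF[self.slices[t]], index=self.levels[t], name=t)
        blups[self.absorbed] = pd.Series(
            sA, index=self.levels[self.absorbed], name=self.absorbed
        )
        fitted = np.full(self.n, mu)
        for t in self.term_names:
            fitted += blups[t].to_numpy()[self.codes[t]]
        varcomps = {t: float(sig[t]) for t in self.term_names}
        varcomps["residual"] = float(s2e)
        fit = MixedModelFit(
            mu=mu, varcomps=varcomps, blups=blups,
            fitted=fitted, residuals=y - fitted,
            converged=converged, n_iter=it, n_obs=self.n,
            history=np.asarray(hist), _design=self,
        )
        if compute_leverage:
            fit._leverage = self._leverage()
        return fit

    def _leverage(self) -> np.ndarray:
        """h_ii = w_i' C^{-1} w_i for every observation (block inverse form)."""
        if self._last is None:
            raise RuntimeError("no fit has been run on this design")
        Sinv = self._last["Sinv"]
        D = self._last["D"]
        Bsc = self._last["Bsc"]
        code_a = self.codes[self.absorbed]
        # w_i = (f_i, a_i); with C = [[S0, B'], [B, D0]] the quadratic form is
        # (f - g_l)' Sinv (f - g_l) + 1/D_l where g_l is row l of D^{-1}B.
        V = (self.F - Bsc[code_a]).toarray()
        h = np.einsum("ij,ij->i", V @ Sinv, V)
        h += 1.0 / D[code_a]
        return h


# ---------------------------------------------------------------------- #
# convenience wrappers over observation tables
# ---------------------------------------------------------------------- #

def fit_mixed_model(frame: pd.DataFrame, response: str,
                    terms: dict[str, tuple[str, ...]] | None = None,
                    tol: float = 1e-6, max_iter: int = 500) -> MixedModelFit:
    """Fit the all-random trial model by EM-REML on a plot table.

    Terms with fewer than two observed levels (for example the environment
    term in a single-environment subset) are dropped with a warning, which
    reduces the model to its estimable form.
    """
    if terms is None:
        terms = TERMS_FULL
    sub = frame.loc[frame[response].notna()]
    design = MixedModelDesign(sub, terms)
    fit = design.fit(sub[response].to_numpy(float), tol=tol, max_iter=max_iter)
    if not fit.converged:
        warnings.warn(
            f"REML for {response!r} hit the {max_iter}-iteration cap "
            f"(last relative change above {tol:g})", stacklevel=2)
    return fit


def remove_outliers_studentized(
    frame: pd.DataFrame, response: str,
    terms: dict[str, tuple[str, ...]] | None = None,
    threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.Index, MixedModelFit]:
    """Flag |studentized residual| > threshold, drop, and refit once.

    Returns (clean table, index of flagged rows, refit on clean data).  A
    single flag-and-refit pass is performed; the screen is not iterated.
    """
    sub = frame.loc[frame[response].notna()]
    fit = fit_mixed_model(sub, response, terms)
    t = fit.studentized_residuals()
    flagged = sub.index[np.abs(t) > threshold]
    if len(flagged) > 0.2 * len(sub):
        warnings.warn(
            f"{len(flagged)}/{len(sub)} observations flagged as outliers; "
            "the model may be misspecified", stacklevel=2)
    clean = frame.drop(index=flagged)
    refit = fit_mixed_model(clean, response, terms) if len(flagged) else fit
    return clean, flagged, refit


def blups_method1(frame: pd.DataFrame, response: str,
                  environments: list | None = None) -> pd.DataFrame:
    """By-environment genotype BLUPs (``y = mu + R + B(R) + G + e`` per env).

    Returns a genotype-by-environment table with columns
    ``genotype, environment, blup, predicted`` where ``predicted`` is
    mu + BLUP (the predicted genotype mean in that environment).
    """
    if environments is None:
        environments = sorted(frame["environment"].unique())
    out = []
    for env in environments:
        sub = frame.loc[
            (frame["environment"] == env) & frame[response].notna()
        ]
        if sub.empty:
            raise ValueError(f"no observations for environment {env!r}")
        if sub.groupby("replicate").ngroups < 2:
            raise ValueError(
                f"environment {env!r} has fewer than 2 replicates")
        fit = fit_mixed_model(sub, response, TERMS_WITHIN_ENV)
        g = fit.genotype_blups
        out.append(pd.DataFrame({
            "genotype": g.index, "environment": env,
            "blup": g.to_numpy(), "predicted": fit.mu + g.to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def blups_method2(frame: pd.DataFrame, response: str) -> pd.DataFrame:
    """Across-environment genotype BLUPs from the full trial model.

    All design terms (environment, replicate, block, genotype, GxE) are
    random; unbalanced genotype-environment incidence is handled naturally
    by the mixed-model equations.  With a single observed environment the
    environment terms are inestimable and dropped, reducing to the
    within-environment model.
    """
    fit = fit_mixed_model(frame, response, TERMS_FULL)
    g = fit.genotype_blups
    return pd.DataFrame({
        "genotype": g.index,
        "blup": g.to_numpy(),
        "predicted": fit.mu + g.to_numpy(),
    })
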