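"""Genetic-algorithm selection of a small waveband subset for yield ranking.

The optimizer searches for ``n_select`` (default 4) binned wavebands whose
reflectances, taken at both growth stages, maximize random-forest rank
prediction of seed yield.  A chromosome is a set of distinct bin indices;
by default each chosen bin contributes its S1 and S2 features (the band set
is shared across stages, matching a single multispectral camera deployed at
both flights), so 4 bins expand to 8 model features out of a search space of
178 bins x 2 stages = 356 candidate features.  A stage-specific mode
(chromosomes drawn directly from the 356 stage-tagged features) is available
via ``GAConfig.stage_shared = False``.

Fitness is the mean Spearman rank correlation over an internal k-fold split
of the *training* rows only — held-out test data never reaches the fitness
function — using a reduced forest for speed; fitness values are cached by
chromosome.  Search operators: tournament selection, uniform crossover with
repair to distinctness, per-gene mutation to a random unused bin, elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .config import GAConfig, RFConfig
from .prediction import RESPONSE, train_rf

__all__ = ["SearchSpace", "GAResult", "build_search_space",
           "evaluate_fitness", "run_ga", "assemble_final_model"]


@dataclass(frozen=True)
class SearchSpace:
    """Candidate bins and their stage-tagged feature columns."""

    bins: tuple[str, ...]                   # e.g. ("R705", "R715", ...)
    stages: tuple[str, ...]
    features: tuple[str, ...]               # stage-tagged, len = bins x stages

    def expand(self, chromosome: tuple[int, ...],
               stage_shared: bool = True) -> list[str]:
        """Feature columns selected by a chromosome of indices."""
        if stage_shared:
            return [f"{s}_{self.bins[i]}" for i in chromosome
                    for s in self.stages]
        return [self.features[i] for i in chromosome]

    def n_candidates(self, stage_shared: bool = True) -> int:
        return len(self.bins) if stage_shared else len(self.features)


@dataclass
class GAResult:
    best_chromosome: tuple[int, ...]
    best_bins: tuple[str, ...]
    best_features: tuple[str, ...]
    best_fitness: float
    log: pd.DataFrame                      # generation, best, mean fitness
    n_evaluations: int
    training_index: tuple = ()             # audit: keys fitness ever saw


def build_search_space(columns, stages=("S1", "S2")) -> SearchSpace:
    """Candidate index over binned waveband features present at all stages.

    Raises if the stages were binned on different grids.
    """
    per_stage = {}
    for s in stages:
        per_stage[s] = sorted(
            (c.split("_", 1)[1] for c in columns
             if c.startswith(f"{s}_R") and c.split(f"{s}_R")[1].isdigit()),
            key=lambda b: int(b[1:]))
    first = per_stage[stages[0]]
    for s in stages[1:]:
        if per_stage[s] != first:
            raise ValueError(
                f"binned waveband grids differ between stages {stages[0]} "
                f"and {s}; rebin on a common grid")
    if not first:
        raise ValueError("no binned waveband columns found")
    bins = tuple(first)
    features = tuple(f"{s}_{b}" for s in stages for b in bins)
    return SearchSpace(bins=bins, stages=tuple(stages), features=features)


# ------------------------------------------------------------------ #
# fitness
# ------------------------------------------------------------------ #

def evaluate_fitness(chromosome: tuple[int, ...], train: pd.DataFrame,
                     space: SearchSpace, config: GAConfig,
                     cache: dict | None = None) -> float:
    """Internal-CV Spearman fitness of a chromosome on training rows only.

    With by-environment rows the rank correlation is computed within each
    test-fold environment and averaged, matching the final evaluation
    metric (pooled ranks would reward environment-level spectral shifts
    that say nothing about genotype ranking).
    """
    key = tuple(sorted(chromosome))
    if cache is not None and key in cache:
        return cache[key]
    cols = space.expand(chromosome, config.stage_shared)
    X = train[cols].to_numpy(float)
    y = train[RESPONSE].to_numpy(float)
    envs = None
    if isinstance(train.index, pd.MultiIndex) \
            and "environment" in train.index.names:
        envs = train.index.get_level_values("environment").to_numpy()
    if np.any(X.std(axis=0) == 0):
        fit = -1.0
    else:
        rhos = []
        kf = KFold(n_splits=config.fitness_folds, shuffle=True,
                   random_state=config.seed)
        for tr, te in kf.split(X):
            model = RandomForestRegressor(
                n_estimators=config.fitness_trees, random_state=config.seed,
                min_samples_leaf=2, n_jobs=1)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            if envs is None:
                rho = spearmanr(y[te], pred).statistic
            else:
                per_env = []
                for env in np.unique(envs[te]):
                    m = envs[te] == env
                    if m.sum() >= 3:
                        per_env.append(spearmanr(y[te][m],
                                                 pred[m]).statistic)
                rho = np.nanmean(per_env) if per_env else np.nan
            rhos.append(0.0 if np.isnan(rho) else float(rho))
        fit = float(np.mean(rhos))
    if cache is not None:
        cache[key] = fit
    return fit


# ------------------------------------------------------------------ #
# search
# ------------------------------------------------------------------ #

def _random_chromosome(rng, n_candidates, n_select):
    return tuple(sorted(rng.choice(n_candidates, n_select, replace=False)))


def _repair(genes, rng, n_candidates, n_select):
    seen = list(dict.fromkeys(genes))
    while len(seen) < n_select:
        cand = int(rng.integers(n_candidates))
        if cand not in seen:
            seen.append(cand)
    return tuple(sorted(seen[:n_select]))


def run_ga(train: pd.DataFrame, space: SearchSpace,
           config: GAConfig | None = None) -> GAResult:
    """Search for the best waveband subset on training rows.

    Terminates after ``n_generations`` or when the best fitness has not
    improved for ``patience`` generations.  With ``n_generations = 0`` the
    result is the best chromosome of the random initial population.
    """
    config = config or GAConfig()
    n_cand = space.n_candidates(config.stage_shared)
    if config.n_select > n_cand:
        raise ValueError(
            f"cannot select {config.n_select} of {n_cand} candidate bins")
    rng = np.random.default_rng(config.seed)
    cache: dict = {}

    def fitness(ch):
        return evaluate_fitness(ch, train, space, config, cache)

    pop = [_random_chromosome(rng, n_cand, config.n_select)
           for _ in range(config.population_size)]
    log = []
    best_ch, best_fit = None, -np.inf
    stall = 0
    for gen in range(config.n_generations + 1):
        fits = np.array([fitness(ch) for ch in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit + 1e-12:
            best_fit, best_ch = float(fits[gen_best]), pop[gen_best]
            stall = 0
        else:
            stall += 1
        log.append({"generation": gen, "best_fitness": best_fit,
                    "mean_fitness": float(fits.mean())})
        if gen == config.n_generations or stall > config.patience:
            break
        # elitism: carry the current best chromosomes unchanged
        order = np.argsort(fits)[::-1]
        nxt = [pop[i] for i in order[:config.elitism]]
        while len(nxt) < config.population_size:
            def tournament():
                idx = rng.choice(len(pop), config.tournament_size,
                                 replace=False)
                return pop[idx[np.argmax(fits[idx])]]
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                genes = [p1[i] if rng.random() < 0.5 else p2[i]
                         for i in range(config.n_select)]
            else:
                genes = list(p1)
            genes = [int(rng.integers(n_cand))
                     if rng.random() < config.mutation_rate else g
                     for g in genes]
            nxt.append(_repair(genes, rng, n_cand, config.n_select))
        pop = nxt

    feats = tuple(space.expand(best_ch, config.stage_shared))
    bins = tuple(space.bins[i] for i in best_ch) if config.stage_shared \
        else tuple(f.split("_", 1)[1] for f in feats)
    return GAResult(best_chromosome=best_ch, best_bins=bins,
                    best_features=feats, best_fitness=best_fit,
                    log=pd.DataFrame(log), n_evaluations=len(cache),
                    training_index=tuple(train.index))


# ------------------------------------------------------------------ #
# final multisensor model
# ------------------------------------------------------------------ #

def assemble_final_model(selected_features, train: pd.DataFrame,
                         rg_table: pd.DataFrame | None = None,
                         rf_config: RFConfig | None = None, seed: int = 0,
                         stages=("S1", "S2")):
    """Retrain the full-size forest on GA wavebands plus supplementary traits.

    Supplementary traits are the vegetation index with the largest |rg| with
    yield (from the genetic-correlation table: columns ``trait``, ``rg``)
    and the canopy traits (CA, CT) at every stage.  Missing canopy columns
    reduce the feature set with a warning.

    Returns (model, feature list, training metrics dict).
    """
    import warnings as _warnings

    features = list(selected_features)
    chosen_vi = None
    if rg_table is not None and len(rg_table):
        vi_rows = rg_table[rg_table["trait"].str.split("_").str[-1].isin(
            ["NDVI", "VREI2", "NWI", "RARSb", "RARSc", "NMDI"])]
        if len(vi_rows):
            best = vi_rows.loc[vi_rows["rg"].abs().idxmax(), "trait"]
            chosen_vi = best.split("_", 1)[1] if "_" in best else best
            for s in stages:
                col = f"{s}_{chosen_vi}"
                if col in train.columns:
                    features.append(col)
    for s in stages:
        for trait in ("CA", "CT"):
            col = f"{s}_{trait}"
            if col in train.columns:
                features.append(col)
            else:
                _warnings.warn(f"canopy trait {col} unavailable; final model "
                               "runs on the remaining features", stacklevel=2)
    features = list(dict.fromkeys(features))
    model, metrics = train_rf(train[features], train[RESPONSE],
                              rf_config, seed=seed)
    metrics = dict(metrics, chosen_vi=chosen_vi)
    return model, features, metrics
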