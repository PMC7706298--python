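"""Random-forest seed-yield rank prediction under breeding CV scenarios.

Predictor cohorts group the phenomic traits a given sensor payload would
deliver: canopy (area + temperature), vegetation indices, canopy+VI, and
binned reflectance wavebands.  Two cross-validation scenarios mirror the
decisions breeders face:

* CV1 — predict untested genotypes in observed environments: a random 80%
  of accessions train the model, the remaining 20% are ranked.
* CV2 — predict untested genotypes in an unobserved environment: for each
  held-out environment, training uses 80% of accessions from the *other*
  environments only, and testing uses the remaining 20% of accessions in
  the held-out environment.  Test genotypes never appear in training.

Models are evaluated by the Spearman rank correlation between observed and
predicted yield BLUPs of the test set; with multi-environment test rows the
correlation is computed within environment and averaged (pooled computation
available via ``pool_environments``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold, cross_val_score

from .config import RFConfig
from .datatypes import TraitTable

__all__ = ["CohortSpec", "CVSplit", "make_cohorts", "make_cv1_splits",
           "make_cv2_splits", "train_rf", "evaluate", "feature_importance",
           "run_cohort_experiment"]

RESPONSE = "seed_yield"


@dataclass(frozen=True)
class CohortSpec:
    """A named predictor cohort (column subset of the trait tables)."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self):
        if not self.columns:
            raise ValueError(f"cohort {self.name!r} has no predictors")


@dataclass
class CVSplit:
    scenario: str                       # "CV1" | "CV2"
    iteration: int
    train_genotypes: tuple
    test_genotypes: tuple
    held_out_environment: str | None = None

    def __post_init__(self):
        overlap = set(self.train_genotypes) & set(self.test_genotypes)
        if overlap:
            raise ValueError(f"train/test genotypes overlap: {sorted(overlap)[:3]}")


def make_cohorts(columns, stages=("S1", "S2")) -> dict[str, CohortSpec]:
    """Build the standard predictor cohorts from available trait columns."""
    cols = list(columns)

    def match(kinds):
        return tuple(c for c in cols
                     if any(c == f"{s}_{k}" for s in stages for k in kinds)
                     or any(c.startswith(f"{s}_R") and k == "R"
                            for s in stages for k in kinds))

    canopy = match(["CA", "CT"])
    vi = tuple(c for c in cols
               if any(c.startswith(f"{s}_") for s in stages)
               and c.split("_", 1)[1] in
               ("NDVI", "VREI2", "NWI", "RARSb", "RARSc", "NMDI"))
    bands = tuple(c for c in cols
                  if any(c.startswith(f"{s}_R") and c.split("_R")[1].isdigit()
                         for s in stages))
    out = {}
    if canopy:
        out["canopy"] = CohortSpec("canopy", canopy)
    if vi:
        out["vi"] = CohortSpec("vi", vi)
    if canopy and vi:
        out["canopy+vi"] = CohortSpec("canopy+vi", canopy + vi)
    if bands:
        out["wavebands"] = CohortSpec("wavebands", bands)
    return out


# ------------------------------------------------------------------ #
# splits
# ------------------------------------------------------------------ #

def _check_frac(train_frac: float):
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")


def make_cv1_splits(genotypes, train_frac: float = 0.80, n_iter: int = 10,
                    seed: int = 0) -> list[CVSplit]:
    """Random genotype partitions: train size = round(train_frac * N)."""
    _check_frac(train_frac)
    genotypes = list(genotypes)
    n = len(genotypes)
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: {n_train} train of {n}")
    rng = np.random.default_rng(seed)
    splits = []
    for it in range(n_iter):
        perm = rng.permutation(n)
        splits.append(CVSplit(
            scenario="CV1", iteration=it,
            train_genotypes=tuple(genotypes[i] for i in perm[:n_train]),
            test_genotypes=tuple(genotypes[i] for i in perm[n_train:])))
    return splits


def make_cv2_splits(genotypes, environments, train_frac: float = 0.80,
                    n_iter: int = 10, seed: int = 0) -> list[CVSplit]:
    """Leave-one-environment-out splits that also hold out test genotypes.

    For each complete environment ``e`` and iteration: training rows are a
    random ``train_frac`` of accessions in all environments except ``e``;
    test rows are the remaining accessions in ``e`` only.
    """
    _check_frac(train_frac)
    environments = list(environments)
    if len(environments) < 2:
        raise ValueError("CV2 requires at least 2 complete environments")
    genotypes = list(genotypes)
    n = len(genotypes)
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    splits = []
    for it in range(n_iter):
        for env in environments:
            perm = rng.permutation(n)
            splits.append(CVSplit(
                scenario="CV2", iteration=it,
                train_genotypes=tuple(genotypes[i] for i in perm[:n_train]),
                test_genotypes=tuple(genotypes[i] for i in perm[n_train:]),
                held_out_environment=env))
    return splits


# ------------------------------------------------------------------ #
# model fitting and evaluation
# ------------------------------------------------------------------ #

def train_rf(X: pd.DataFrame, y: pd.Series, config: RFConfig | None = None,
             seed: int = 0):
    """Fit (and optionally tune) a random-forest regressor on training rows.

    When ``config.tune`` is set, the number of candidate features per split
    is chosen from ``config.max_features_grid`` by repeated k-fold
    cross-validation inside the training data.  Returns
    (model, {"oob_r2", "oob_rmse", "cv_r2", "max_features"}).
    """
    if config is None:
        config = RFConfig()
    if X.isna().any().any():
        raise ValueError("missing predictor values in training data")
    yv = y.to_numpy(float)
    if np.ptp(yv) == 0:
        raise ValueError("constant response; nothing to learn")
    best_mf, cv_r2 = config.max_features, np.nan
    if config.tune:
        scores = {}
        for mf in config.max_features_grid:
            est = RandomForestRegressor(
                random_state=seed, **{**config.sklearn_kwargs(),
                                      "max_features": mf, "oob_score": False})
            cv = RepeatedKFold(n_splits=config.tune_folds,
                               n_repeats=config.tune_repeats,
                               random_state=seed)
            scores[mf] = cross_val_score(est, X, yv, cv=cv, scoring="r2").mean()
        best_mf = max(scores, key=scores.get)
        cv_r2 = scores[best_mf]
    with warnings.catch_warnings():
        # small trainings can leave a few rows out of every bootstrap
        warnings.filterwarnings("ignore", message=".*Some inputs do not have OOB.*")
        model = RandomForestRegressor(
            random_state=seed, **{**config.sklearn_kwargs(),
                                  "max_features": best_mf})
        model.fit(X, yv)
        oob_pred = model.oob_prediction_
        oob_r2 = model.oob_score_
    oob_rmse = float(np.sqrt(np.nanmean((yv - oob_pred) ** 2)))
    return model, {"oob_r2": float(oob_r2), "oob_rmse": oob_rmse,
                   "cv_r2": float(cv_r2), "max_features": best_mf}


def evaluate(model, X_test: pd.DataFrame, y_test: pd.Series,
             environments: pd.Series | None = None,
             pool_environments: bool = False) -> float:
    """Spearman rank correlation between observed and predicted test yield.

    With environment labels and ``pool_environments=False`` the correlation
    is computed within each test environment and averaged.
    """
    if len(X_test) < 3:
        raise ValueError("need at least 3 test observations for a rank correlation")
    pred = model.predict(X_test)
    obs = y_test.to_numpy(float)
    if environments is None or pool_environments \
            or environments.nunique() <= 1:
        return float(spearmanr(obs, pred).statistic)
    rhos = []
    for _, idx in pd.Series(range(len(obs))).groupby(environments.to_numpy()):
        ii = idx.to_numpy()
        if len(ii) >= 3:
            rhos.append(spearmanr(obs[ii], pred[ii]).statistic)
    if not rhos:
        raise ValueError("no test environment has >= 3 observations")
    return float(np.mean(rhos))


def feature_importance(models) -> pd.Series:
    """Mean impurity-based importances across models, normalized to sum 100."""
    if not isinstance(models, (list, tuple)):
        models = [models]
    imp = np.mean([m.feature_importances_ for m in models], axis=0)
    total = imp.sum()
    if total > 0:
        imp = imp / total * 100.0
    return pd.Series(imp, index=models[0].feature_names_in_,
                     name="importance").sort_values(ascending=False)


# ------------------------------------------------------------------ #
# the cohort experiment grid
# ------------------------------------------------------------------ #

@dataclass
class ExperimentResult:
    """Per-iteration rank correlations plus summaries of a cohort grid."""

    iterations: pd.DataFrame     # method, scenario, cohort, iteration, rho
    importances: dict = field(default_factory=dict)
    oob: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return (self.iterations
                .groupby(["method", "scenario", "cohort"])["rho"]
                .agg(mean_rho="mean", sd_rho="std", n_iterations="count")
                .reset_index())


def _frame_for(table: TraitTable, genotypes, env=None,
               exclude_env=None) -> pd.DataFrame:
    df = table.frame
    if table.level == "genotype":
        return df.loc[df.index.isin(genotypes)]
    gl = df.index.get_level_values("genotype")
    el = df.index.get_level_values("environment")
    mask = gl.isin(genotypes)
    if env is not None:
        mask &= el == env
    if exclude_env is not None:
        mask &= el != exclude_env
    return df.loc[mask]


def run_cohort_experiment(
    m1_table: TraitTable | None, m2_table: TraitTable | None,
    cohorts: dict[str, CohortSpec] | None = None,
    methods=(1, 2), scenarios=("CV1", "CV2"),
    environments=None, n_iter: int = 10, train_frac: float = 0.80,
    rf_config: RFConfig | None = None, seed: int = 0,
    pool_environments: bool = False,
) -> ExperimentResult:
    """Rank-prediction accuracy per (method, scenario, cohort).

    ``m1_table`` holds by-environment BLUPs (genotype x environment level),
    ``m2_table`` across-environment BLUPs (genotype level).  Method 1 trains
    and tests on by-environment rows; Method 2 trains on across-environment
    rows and, under CV2, tests on the by-environment rows of the held-out
    environment.
    """
    rf_config = rf_config or RFConfig()
    tables = {1: m1_table, 2: m2_table}
    methods = [m for m in methods if tables[m] is not None]
    if not methods:
        raise ValueError("no trait table supplied")
    some = tables[methods[0]]
    if cohorts is None:
        cohorts = make_cohorts(
            [c for c in some.frame.columns if c != RESPONSE])
    for spec in cohorts.values():
        missing = [c for c in spec.columns if c not in some.frame.columns]
        if missing:
            raise KeyError(f"cohort {spec.name!r} references missing "
                           f"columns {missing[:4]}")
    genotypes = sorted(
        some.frame.index.get_level_values("genotype").unique()
        if some.level == "genotype_env" else some.frame.index.unique())
    if m1_table is not None:
        if environments is None:
            # only environments with complete predictor data participate in
            # by-environment training and testing (sparse-phenomics
            # environments still inform the across-environment BLUPs)
            complete = m1_table.frame.notna().all(axis=1)
            environments = sorted(
                m1_table.frame.index.get_level_values("environment")[
                    complete.to_numpy()].unique())
        env_level = m1_table.frame.index.get_level_values("environment")
        m1_table = TraitTable(
            level="genotype_env",
            frame=m1_table.frame.loc[env_level.isin(environments)])
        if 1 in methods:
            tables[1] = m1_table
        environments = sorted(environments)

    rows, oob_rows = [], []
    imp_acc: dict[tuple, list] = {}
    rng = np.random.SeedSequence(seed)
    for method in methods:
        table = tables[method]
        for scenario in scenarios:
            base_seed = int(rng.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            if scenario == "CV1":
                splits = make_cv1_splits(genotypes, train_frac, n_iter,
                                         base_seed)
            else:
                if environments is None:
                    raise ValueError("CV2 requires environment labels")
                splits = make_cv2_splits(genotypes, environments, train_frac,
                                         n_iter, base_seed)
            for name, spec in cohorts.items():
                fold_rhos: dict[int, list] = {}
                models = []
                for k, split in enumerate(splits):
                    # Method 2 trains on across-environment BLUPs but is
                    # always tested against by-environment BLUPs when a
                    # by-environment table exists
                    if scenario == "CV2":
                        if method == 1:
                            train = _frame_for(
                                table, split.train_genotypes,
                                exclude_env=split.held_out_environment)
                        else:
                            train = _frame_for(table, split.train_genotypes)
                        test = _frame_for(
                            m1_table, split.test_genotypes,
                            env=split.held_out_environment)
                    else:
                        train = _frame_for(table, split.train_genotypes)
                        test_table = m1_table if m1_table is not None else table
                        test = _frame_for(test_table, split.test_genotypes)
                    model, oob = train_rf(
                        train[list(spec.columns)], train[RESPONSE],
                        rf_config, seed=base_seed + 7919 * k)
                    env_lab = None
                    if isinstance(test.index, pd.MultiIndex):
                        env_lab = pd.Series(
                            test.index.get_level_values("environment"))
                    rho = evaluate(model, test[list(spec.columns)],
                                   test[RESPONSE], environments=env_lab,
                                   pool_environments=pool_environments)
                    fold_rhos.setdefault(split.iteration, []).append(rho)
                    models.append(model)
                    oob_rows.append({"method": method, "scenario": scenario,
                                     "cohort": name, **oob})
                for it, rhos in fold_rhos.items():
                    rows.append({"method": method, "scenario": scenario,
                                 "cohort": name, "iteration": it,
                                 "rho": float(np.mean(rhos))})
                imp_acc[(method, scenario, name)] = feature_importance(models)
    return ExperimentResult(iterations=pd.DataFrame(rows),
                            importances=imp_acc,
                            oob=pd.DataFrame(oob_rows))
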