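"""Selection-outcome metrics and the training-population-size study.

A hypothetical selection intensity (default 20%) turns continuous yield
ranks into a binary advancement decision: a genotype is "positive" if it
sits in the top ``round(intensity * n)`` of its cohort.  Comparing the
decision implied by predicted ranks with the one implied by observed ranks
gives a confusion matrix, summarized by specificity (SPE), balanced
accuracy (BAC) and F score (FS) — the quantities a breeder cares about when
advancing lines on predicted performance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RFConfig
from .datatypes import ConfusionSummary, TraitTable
from .prediction import (RESPONSE, _frame_for, evaluate, make_cv1_splits,
                         make_cv2_splits, train_rf)

__all__ = ["confusion_at_intensity", "training_size_study",
           "plot_training_size_study"]


def _top_k_mask(values: np.ndarray, k: int, ids: np.ndarray) -> np.ndarray:
    # sort by value descending; ties broken by stable genotype-id order
    order = np.lexsort((ids, -values))
    mask = np.zeros(len(values), dtype=bool)
    mask[order[:k]] = True
    return mask


def confusion_at_intensity(observed, predicted, intensity: float = 0.20,
                           ids=None) -> ConfusionSummary:
    """Confusion matrix of predicted vs observed top-fraction membership.

    ``k = round(intensity * n)`` (at least 1) genotypes are "selected" under
    each ranking, computed separately for observed and predicted values.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted differ in length")
    n = len(observed)
    if n < 5:
        raise ValueError("need at least 5 genotypes for selection metrics")
    k = int(round(intensity * n))
    if k < 1:
        raise ValueError(
            f"selection intensity {intensity} selects no genotypes at n={n}")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    obs_top = _top_k_mask(observed, k, ids)
    pred_top = _top_k_mask(predicted, k, ids)
    tp = int(np.sum(obs_top & pred_top))
    tn = int(np.sum(~obs_top & ~pred_top))
    fp = int(np.sum(~obs_top & pred_top))
    fn = int(np.sum(obs_top & ~pred_top))
    return ConfusionSummary(TP=tp, TN=tn, FP=fp, FN=fn,
                            selection_intensity=intensity)


def training_size_study(
    m1_table: TraitTable,
    waveband_features: list[str],
    multisensor_features: list[str],
    fractions=(0.80, 0.60, 0.40, 0.20),
    scenarios=("CV1", "CV2"),
    environments=None,
    n_iter: int = 10,
    intensity: float = 0.20,
    rf_config: RFConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Prediction and selection metrics as the training population shrinks.

    For every (training fraction, CV scenario, model) cell, ``n_iter``
    random splits are drawn, the forest retrained, and mean Spearman rho
    plus SPE/BAC/FS at the given selection intensity recorded.  The two
    models are the GA-optimized wavebands alone and the multisensor set
    (wavebands + chosen VI + canopy traits).  By-environment (Method 1)
    BLUPs are used throughout, mirroring the optimization stage.
    """
    rf_config = rf_config or RFConfig()
    frame = m1_table.frame
    if environments is None:
        # only environments with complete predictor data participate
        complete = frame.notna().all(axis=1)
        environments = sorted(
            frame.index.get_level_values("environment")[
                complete.to_numpy()].unique())
    frame = frame.loc[
        frame.index.get_level_values("environment").isin(environments)]
    m1_table = TraitTable(level="genotype_env", frame=frame)
    genotypes = sorted(frame.index.get_level_values("genotype").unique())
    models = {"wavebands": list(waveband_features),
              "multisensor": list(multisensor_features)}
    rows = []
    ss = np.random.SeedSequence(seed)
    for frac in fractions:
        n_train = int(round(frac * len(genotypes)))
        if n_train < 10:
            raise ValueError(
                f"training fraction {frac} leaves only {n_train} genotypes")
        for scenario in scenarios:
            base_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            if scenario == "CV1":
                splits = make_cv1_splits(genotypes, frac, n_iter, base_seed)
            else:
                splits = make_cv2_splits(genotypes, environments, frac,
                                         n_iter, base_seed)
            for model_name, cols in models.items():
                per_iter: dict[int, list] = {}
                for k, split in enumerate(splits):
                    if scenario == "CV2":
                        train = _frame_for(m1_table, split.train_genotypes,
                                           exclude_env=split.held_out_environment)
                        test = _frame_for(m1_table, split.test_genotypes,
                                          env=split.held_out_environment)
                    else:
                        train = _frame_for(m1_table, split.train_genotypes)
                        test = _frame_for(m1_table, split.test_genotypes)
                    model, _ = train_rf(train[cols], train[RESPONSE],
                                        rf_config, seed=base_seed + 104729 * k)
                    env_lab = pd.Series(
                        test.index.get_level_values("environment"))
                    rho = evaluate(model, test[cols], test[RESPONSE],
                                   environments=env_lab)
                    pred = model.predict(test[cols])
                    # selection decisions are per test environment
                    mets = []
                    for env, sub in test.groupby(
                            test.index.get_level_values("environment")):
                        ii = test.index.get_level_values("environment") == env
                        if ii.sum() < 5:
                            continue
                        cm = confusion_at_intensity(
                            sub[RESPONSE].to_numpy(), pred[ii], intensity,
                            ids=sub.index.get_level_values("genotype"))
                        mets.append((cm.SPE, cm.BAC, cm.FS))
                    spe, bac, fs = (np.mean([m[j] for m in mets])
                                    for j in range(3)) if mets else (np.nan,) * 3
                    per_iter.setdefault(split.iteration, []).append(
                        (rho, spe, bac, fs))
                for it, vals in per_iter.items():
                    arr = np.asarray(vals, dtype=float)
                    rows.append({
                        "fraction": frac, "scenario": scenario,
                        "model": model_name, "iteration": it,
                        "n_train": n_train,
                        "rho": arr[:, 0].mean(), "SPE": arr[:, 1].mean(),
                        "BAC": arr[:, 2].mean(), "FS": arr[:, 3].mean(),
                    })
    return pd.DataFrame(rows)


def plot_training_size_study(study: pd.DataFrame, path) -> None:
    """Plot mean rho/SPE/BAC/FS against training fraction per model.

    Requires matplotlib (the optional ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["rho", "SPE", "BAC", "FS"]
    scenarios = sorted(study["scenario"].unique())
    fig, axes = plt.subplots(len(scenarios), len(metrics),
                             figsize=(3 * len(metrics), 2.6 * len(scenarios)),
                             squeeze=False, sharex=True)
    for i, scenario in enumerate(scenarios):
        sub = study[study["scenario"] == scenario]
        for j, metric in enumerate(metrics):
            ax = axes[i][j]
            for model, grp in sub.groupby("model"):
                mean = grp.groupby("fraction")[metric].mean()
                ax.plot(mean.index, mean.to_numpy(), marker="o", label=model)
            ax.set_title(f"{scenario}: {metric}", fontsize=9)
            ax.set_xlabel("training fraction")
            if j == 0:
                ax.set_ylabel(scenario)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
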