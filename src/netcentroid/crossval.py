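"""Cross-validated choice of the shrinkage amount.

The shrinkage grid is defined by its 30 fractional positions on [0, 1] of the
fit's ``delta_max``; within each fold the full pipeline (centroids, pooled
SDs, neighbourhood adjustment, grid scale) is refit on the training samples
only, and the fold's thresholds are the same fractional positions of its own
``delta_max``. Errors at each grid position are then comparable across folds
even though the absolute delta values differ slightly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import SampleGroups
from .nsc import N_DELTA_GRID, CentroidModel, EdgeNeighborhood, build_neighborhoods, fit
from .scoring import EdgeScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "cross_validate", "choose_delta"]


@dataclass
class CVResult:
    """Per-grid-position cross-validation errors and edge counts.

    ``table`` has one row per grid position with the full-data delta value,
    overall and per-group test error, training error and the mean number of
    selected edges across folds. ``fold_of`` maps each sample to its fold.
    """

    table: pd.DataFrame
    fold_of: pd.Series
    seed: int
    n_folds: int
    model: CentroidModel  # fitted on all samples; delta values refer to its grid

    @property
    def grid(self) -> np.ndarray:
        return self.table["delta"].to_numpy()


def cross_validate(
    scores: EdgeScoreMatrix,
    groups: SampleGroups,
    n_folds: int = 5,
    seed: int = 0,
    *,
    adjust: bool = True,
    eq_form: str = "mean",
    delta_form: str = "abs_dstar",
    priors: str = "equal",
) -> CVResult:
    """Stratified K-fold misclassification error along the shrinkage grid."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    data = scores.data
    samples = list(data.columns)
    assign = groups.assignments.reindex(samples)
    if assign.isna().any():
        raise ValueError("samples without group assignment")
    counts = assign.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples for cross-validation")
    min_group = int(counts.min())
    if min_group < n_folds:
        logger.warning("reducing folds from %d to smallest group size %d", n_folds, min_group)
        n_folds = min_group

    nb = build_neighborhoods(scores.network) if adjust else None
    full_model = fit(
        scores, groups, adjust=adjust, eq_form=eq_form, delta_form=delta_form,
        priors=priors, neighborhoods=nb,
    )
    n_grid = len(full_model.grid)
    fracs = (full_model.grid / full_model.delta_max
             if full_model.delta_max > 0 else np.zeros(n_grid))

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y = assign.to_numpy()
    fold_of = pd.Series(index=pd.Index(samples, name="sample"), dtype=int)

    labels = groups.labels
    test_err = np.zeros((n_folds, n_grid))
    train_err = np.zeros((n_folds, n_grid))
    n_sel = np.zeros((n_folds, n_grid))
    group_wrong = {g: np.zeros(n_grid) for g in labels}
    group_total = {g: 0 for g in labels}

    for f, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), y)):
        tr_samples = [samples[i] for i in tr]
        te_samples = [samples[i] for i in te]
        fold_of.loc[te_samples] = f
        tr_scores = EdgeScoreMatrix(scores.network, data[tr_samples])
        tr_groups = SampleGroups(assign.loc[tr_samples])
        model = fit(
            tr_scores, tr_groups, adjust=adjust, eq_form=eq_form,
            delta_form=delta_form, priors=priors, neighborhoods=nb,
        )
        for g in labels:
            group_total[g] += sum(1 for s in te_samples if assign[s] == g)
        for j, frac in enumerate(fracs):
            delta = frac * model.delta_max
            pred_te = model.classify(data[te_samples], delta)
            pred_tr = model.classify(data[tr_samples], delta)
            wrong_te = pred_te.labels.to_numpy() != assign.loc[te_samples].to_numpy()
            test_err[f, j] = wrong_te.mean()
            train_err[f, j] = (pred_tr.labels.to_numpy() != assign.loc[tr_samples].to_numpy()).mean()
            n_sel[f, j] = model.n_selected(delta)
            for g in labels:
                mask = assign.loc[te_samples].to_numpy() == g
                group_wrong[g][j] += wrong_te[mask].sum()

    table = pd.DataFrame(
        {
            "delta": full_model.grid,
            "frac": fracs,
            "cv_error": test_err.mean(axis=0),
            "cv_error_se": test_err.std(axis=0, ddof=1) / np.sqrt(n_folds),
            "train_error": train_err.mean(axis=0),
            "mean_n_selected": n_sel.mean(axis=0),
        }
    )
    for g in labels:
        table[f"cv_error_{g}"] = group_wrong[g] / max(group_total[g], 1)
    return CVResult(table=table, fold_of=fold_of, seed=seed, n_folds=n_folds, model=full_model)


def choose_delta(cv: CVResult, rule: str = "min_error_sparsest") -> float:
    """Pick the operating shrinkage from the CV error curve.

    ``min_error_sparsest``: among grid positions attaining the minimal overall
    CV error, the largest delta that still selects at least one edge.
    ``one_se``: the largest such delta whose error is within one standard
    error of the minimum.
    """
    t = cv.table
    err = t["cv_error"].to_numpy()
    nonempty = t["mean_n_selected"].to_numpy() > 0
    if rule == "min_error_sparsest":
        ok = np.isclose(err, err.min())
    elif rule == "one_se":
        i_min = int(err.argmin())
        ok = err <= err[i_min] + t["cv_error_se"].iloc[i_min]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    candidates = np.flatnonzero(ok & nonempty)
    if len(candidates) == 0:
        candidates = np.flatnonzero(ok)
    return float(t["delta"].iloc[candidates[-1]])
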