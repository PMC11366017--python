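"""Cross-validated choice of the number of clock sites.

Within each fold the entire training pipeline (candidate filtering,
correlation ranking, pruning, GLM fits, expected matrix) is re-run on the
training samples only, and the held-out samples are scored at every
candidate site count.  Folds are stratified by dataset (and cell type when
present) so every dataset contributes to both training and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import clock as _clock
from .io import BulkDataset, MethylomeProfile
from .predict import EPSILON, NoUsableSites, predict_age

logger = logging.getLogger("epiage")

SITE_GRID = (50, 100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000)
K_FOLDS = 10


def median_absolute_error(pairs) -> float:
    """Median of |predicted - true| over (predicted, true) age pairs, weeks."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("no prediction pairs")
    return float(np.median(np.abs(arr[:, 0] - arr[:, 1])))


def select_best_count(mae_by_count: dict[int, float]) -> int:
    """Site count minimising MAE; ties go to the smaller (cheaper) count."""
    if not mae_by_count:
        raise ValueError("empty MAE map")
    return min(mae_by_count, key=lambda n: (mae_by_count[n], n))


@dataclass
class CvResult:
    grid: list[int]
    mae_by_count: dict[int, float]
    best_count: int
    fold_assignments: dict[str, int] = field(default_factory=dict)
    predictions: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_count": list(self.mae_by_count),
             "mae_weeks": list(self.mae_by_count.values())}
        )


def sample_profile(ds: BulkDataset, sample_id: str) -> MethylomeProfile:
    """The observed methylation fractions of one bulk sample as a profile."""
    frac = ds.fractions().loc[sample_id].dropna()
    return MethylomeProfile(calls=frac, source_kind="bulk")


def _strata(datasets: list[BulkDataset]) -> pd.Series:
    metas = pd.concat([ds.meta for ds in datasets])
    labels = metas["dataset_id"].astype(str)
    if metas["cell_type"].notna().any():
        labels = labels + "|" + metas["cell_type"].fillna("NA").astype(str)
    return labels


def assign_folds(datasets: list[BulkDataset], k_folds: int,
                 rng_seed: int) -> dict[str, int]:
    """Stratified fold assignment balancing each stratum across folds."""
    labels = _strata(datasets)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rng_seed)
    folds: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # small strata
        for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            for s in labels.index[test_idx]:
                folds[s] = i
    return folds


def cross_validate(
    datasets: list[BulkDataset],
    site_grid: tuple[int, ...] = SITE_GRID,
    k_folds: int = K_FOLDS,
    rng_seed: int = 0,
    mode: str = "stratified",
    epsilon: float = EPSILON,
    **train_kwargs,
) -> CvResult:
    """Cross-validate the clock over candidate site counts.

    ``mode='stratified'`` uses k stratified folds; ``mode='lodo'`` holds out
    one whole dataset per fold (requires >= 3 datasets so the training side
    keeps >= 2).  Grid values exceeding the number of main sites available in
    some fold are skipped with a warning.  The per-count MAE pools held-out
    pairs over all folds; ties in the argmin go to the smaller count.
    """
    if len(datasets) < 2:
        raise ValueError("cross-validation requires at least 2 datasets")
    by_id = {str(ds.meta["dataset_id"].iloc[0]): ds for ds in datasets}

    if mode == "stratified":
        folds = assign_folds(datasets, k_folds, rng_seed)
        fold_ids = sorted(set(folds.values()))
    elif mode == "lodo":
        if len(datasets) < 3:
            raise ValueError("leave-one-dataset-out needs >= 3 datasets")
        folds = {}
        for i, ds in enumerate(datasets):
            for s in ds.meta.index:
                folds[s] = i
        fold_ids = list(range(len(datasets)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    site_grid = sorted(set(int(n) for n in site_grid))
    pairs: dict[int, list[tuple[float, float]]] = {n: [] for n in site_grid}
    pred_rows = []
    for fold in fold_ids:
        train_sets, test_samples = [], []
        for dsid, ds in by_id.items():
            in_test = ds.meta.index.map(lambda s: folds[s] == fold)
            tr = ds.meta.index[~np.asarray(in_test)]
            te = ds.meta.index[np.asarray(in_test)]
            if len(tr):
                train_sets.append(ds.subset_samples(tr))
            test_samples.extend((ds, s) for s in te)
        if not test_samples:
            raise RuntimeError(f"fold {fold} has no test samples")
        if len(train_sets) < 2:
            raise RuntimeError(f"fold {fold} leaves fewer than 2 training datasets")

        model, _ = _clock.train_clock(
            train_sets, n_sites=max(site_grid), allow_fewer_sites=True,
            **train_kwargs,
        )
        n_avail = len(model.main_sites)
        for n in site_grid:
            if n > n_avail:
                logger.warning("fold %d: skipping site count %d (> %d available)",
                               fold, n, n_avail)
                continue
            sub = _subset_clock(model, n)
            for ds, sid in test_samples:
                prof = sample_profile(ds, sid)
                try:
                    pred = predict_age(prof, sub, epsilon=epsilon)
                except NoUsableSites:
                    continue
                true_age = float(ds.meta.at[sid, "age_weeks"])
                pairs[n].append((pred.predicted_age_weeks, true_age))
                pred_rows.append({"fold": fold, "site_count": n, "sample_id": sid,
                                  "predicted": pred.predicted_age_weeks,
                                  "true": true_age})

    mae_by_count = {n: median_absolute_error(p) for n, p in pairs.items() if p}
    if not mae_by_count:
        raise RuntimeError("no site count produced predictions")
    best_count = select_best_count(mae_by_count)
    return CvResult(
        grid=list(mae_by_count),
        mae_by_count=mae_by_count,
        best_count=best_count,
        fold_assignments=folds,
        predictions=pd.DataFrame(pred_rows),
    )


def _subset_clock(model: _clock.ClockModel, n: int) -> _clock.ClockModel:
    """View of a trained clock restricted to its top-n main sites."""
    mains = model.main_sites[:n]
    backups = {s: model.backups.get(s, []) for s in mains}
    keep = list(mains) + [b for s in mains for b in backups[s]]
    return _clock.ClockModel(
        main_sites=mains,
        backups=backups,
        models={s: model.models[s] for s in keep},
        expected=model.expected.loc[keep],
        age_range=model.age_range,
        grid_step=model.grid_step,
        mean_rho={s: model.mean_rho[s] for s in keep if s in model.mean_rho},
    )
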