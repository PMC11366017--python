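"""Per-site binomial age models and the expected methylation-vs-age matrix.

Each clock site gets a binomial GLM of methylated read counts with a logit
link,

    logit(p) = intercept + slope * T(age) + effect(dataset),

fitted three times with T in {identity, log, sqrt} to capture non-linear
age trajectories; the transformation minimising the mean residual deviance
is kept.  The dataset of origin enters as a fixed effect to absorb batch
offsets between studies; when tabulating the expected matrix the *average*
dataset effect is added back so predictions target a typical dataset.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import selection as _sel
from .io import BulkDataset, site_index

logger = logging.getLogger("epiage")

TRANSFORMS = ("identity", "log", "sqrt")
GRID_STEP = 1.0
MIN_SAMPLES_PER_SITE = 10
PROB_CLIP = 1e-6  # guard against separation when tabulating fitted curves


def age_transform(ages, transform: str):
    a = np.asarray(ages, dtype=float)
    if transform == "identity":
        return a
    if transform == "log":
        if np.any(a <= 0):
            raise ValueError("log transform requires positive ages")
        return np.log(a)
    if transform == "sqrt":
        return np.sqrt(a)
    raise ValueError(f"unknown age transform {transform!r}")


class SiteUnusable(RuntimeError):
    """No transformation produced a converged fit for this site."""


@dataclass
class SiteAgeModel:
    """Fitted binomial age model for one CpG site (logit scale)."""

    site: tuple
    transform: str
    intercept: float
    slope: float
    dataset_effects: dict[str, float]   # reference dataset carries 0.0
    mean_dataset_effect: float
    fit_quality: float                  # mean residual deviance; lower is better

    def expected_fraction(self, ages) -> np.ndarray:
        eta = self.intercept + self.slope * age_transform(ages, self.transform) \
            + self.mean_dataset_effect
        return np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)


def _fit_one(meth, total, t_age, dataset_ids, datasets_sorted):
    n = len(meth)
    cols = [np.ones(n), t_age]
    for d in datasets_sorted[1:]:
        cols.append((dataset_ids == d).astype(float))
    exog = np.column_stack(cols)
    endog = np.column_stack([meth, total - meth])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings; guarded by clipping
        res = model.fit(maxiter=100)
    if not res.converged or not np.all(np.isfinite(res.params)):
        raise RuntimeError("fit did not converge")
    params = res.params
    effects = {datasets_sorted[0]: 0.0}
    for i, d in enumerate(datasets_sorted[1:]):
        effects[d] = float(params[2 + i])
    quality = float(res.deviance) / n
    return float(params[0]), float(params[1]), effects, quality


def fit_site_model(meth, total, age_weeks, dataset_id, site: tuple = ("", 0),
                   min_samples: int = MIN_SAMPLES_PER_SITE) -> SiteAgeModel:
    """Fit the three candidate age models for one site; keep the best.

    Observations with fractional methylation but no read counts should be
    passed with ``total = 1`` (weight-1 pseudo-observations).  Raises
    :class:`SiteUnusable` when none of the transformations converges, and
    ``ValueError`` for inputs that cannot identify an age effect.
    """
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    age_weeks = np.asarray(age_weeks, dtype=float)
    dataset_id = np.asarray(dataset_id, dtype=object)
    if len(meth) < min_samples:
        raise ValueError(f"need >= {min_samples} observations, got {len(meth)}")
    if len(np.unique(age_weeks)) < 2:
        raise ValueError("observations must span at least 2 distinct ages")
    if np.any(total <= 0) or np.any(meth < 0) or np.any(meth > total):
        raise ValueError("invalid counts")
    datasets_sorted = sorted(set(dataset_id.tolist()))

    best: SiteAgeModel | None = None
    for transform in TRANSFORMS:
        try:
            t_age = age_transform(age_weeks, transform)
            intercept, slope, effects, quality = _fit_one(
                meth, total, t_age, dataset_id, datasets_sorted
            )
        except Exception:
            continue
        if best is None or quality < best.fit_quality:
            best = SiteAgeModel(
                site=tuple(site),
                transform=transform,
                intercept=intercept,
                slope=slope,
                dataset_effects=effects,
                mean_dataset_effect=float(np.mean(list(effects.values()))),
                fit_quality=quality,
            )
    if best is None:
        raise SiteUnusable(f"no converged fit for site {site}")
    return best


def make_age_grid(age_range: tuple[float, float], grid_step: float = GRID_STEP) -> np.ndarray:
    """Weekly (by default) age grid spanning [min - 1, max + 1] weeks.

    The lower bound is clipped to one grid step when min - 1 would be
    non-positive (the log transform needs strictly positive ages).
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if hi < lo:
        raise ValueError("age range must be (min, max) with min <= max")
    start = lo - 1.0
    if start <= 0:
        start = grid_step
    return np.arange(start, hi + 1.0 + 1e-9, grid_step)


def build_expected_matrix(models: list[SiteAgeModel],
                          observed_age_range: tuple[float, float],
                          grid_step: float = GRID_STEP) -> pd.DataFrame:
    """Tabulate expected methylation fractions: sites x grid ages.

    Each entry is inverse-logit(intercept + slope * T(age) + mean dataset
    effect); rows are monotone in age with the direction of the slope.
    """
    if not models:
        raise ValueError("no site models supplied")
    grid = make_age_grid(observed_age_range, grid_step)
    values = np.vstack([m.expected_fraction(grid) for m in models])
    idx = pd.MultiIndex.from_tuples([m.site for m in models], names=("chrom", "pos"))
    return pd.DataFrame(values, index=idx, columns=grid)


# ---------------------------------------------------------------------------
# The trained clock
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """A trained methylation clock.

    ``main_sites`` is the ordered list of scoring sites; ``backups`` maps
    each main site to its ordered substitutes.  ``expected`` tabulates the
    model's expected methylation fraction for every modelled site (mains and
    backups alike — a substituted backup is scored against its own row) at
    every grid age.
    """

    main_sites: list[tuple]
    backups: dict[tuple, list[tuple]]
    models: dict[tuple, SiteAgeModel]
    expected: pd.DataFrame
    age_range: tuple[float, float]
    grid_step: float = GRID_STEP
    mean_rho: dict[tuple, float] = field(default_factory=dict)

    @property
    def age_grid(self) -> np.ndarray:
        return np.asarray(self.expected.columns, dtype=float)

    def grid_age(self, age: float) -> float:
        """Snap ``age`` to the grid, refusing values off the grid."""
        grid = self.age_grid
        i = int(np.argmin(np.abs(grid - age)))
        if abs(grid[i] - age) > 1e-6:
            raise ValueError(f"age {age} is not on the model grid")
        return float(grid[i])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        sites = []
        for rank, s in enumerate(self.main_sites, start=1):
            sites.append(self._site_record(s, "main", None, rank))
            for b in self.backups.get(s, []):
                sites.append(self._site_record(b, "backup", s, rank))
        return {
            "format": "epiage-clock",
            "version": 1,
            "age_range": [float(self.age_range[0]), float(self.age_range[1])],
            "grid_step": float(self.grid_step),
            "sites": sites,
        }

    def _site_record(self, site, role, partner, rank):
        m = self.models[site]
        return {
            "chrom": site[0],
            "pos": int(site[1]),
            "role": role,
            "rank": rank,
            "main_partner": None if partner is None else f"{partner[0]}:{partner[1]}",
            "transform": m.transform,
            "intercept": m.intercept,
            "slope": m.slope,
            "dataset_effects": m.dataset_effects,
            "mean_dataset_effect": m.mean_dataset_effect,
            "fit_quality": m.fit_quality,
            "mean_rho": self.mean_rho.get(site),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ClockModel":
        if doc.get("format") != "epiage-clock":
            raise ValueError("not a clock model document")
        main_sites, backups, models, mean_rho = [], {}, {}, {}
        for rec in doc["sites"]:
            site = (rec["chrom"], int(rec["pos"]))
            m = SiteAgeModel(
                site=site,
                transform=rec["transform"],
                intercept=float(rec["intercept"]),
                slope=float(rec["slope"]),
                dataset_effects={k: float(v) for k, v in rec["dataset_effects"].items()},
                mean_dataset_effect=float(rec["mean_dataset_effect"]),
                fit_quality=float(rec["fit_quality"]),
            )
            models[site] = m
            if rec.get("mean_rho") is not None:
                mean_rho[site] = float(rec["mean_rho"])
            if rec["role"] == "main":
                main_sites.append(site)
                backups[site] = []
            else:
                c, p = rec["main_partner"].split(":")
                backups[(c, int(p))].append(site)
        age_range = tuple(doc["age_range"])
        grid_step = float(doc.get("grid_step", GRID_STEP))
        ordered = [models[s] for s in main_sites] + [
            models[b] for s in main_sites for b in backups[s]
        ]
        expected = build_expected_matrix(ordered, age_range, grid_step)
        return cls(
            main_sites=main_sites,
            backups=backups,
            models=models,
            expected=expected,
            age_range=age_range,
            grid_step=grid_step,
            mean_rho=mean_rho,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ClockModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _site_observations(datasets: list[BulkDataset], site) -> tuple:
    meth, total, ages, dsids = [], [], [], []
    for ds in datasets:
        if site not in ds.sites:
            continue
        m = ds.meth[site].to_numpy(dtype=float)
        t = ds.total[site].to_numpy(dtype=float)
        ok = ~np.isnan(t)
        if not ok.any():
            continue
        meth.append(m[ok])
        total.append(t[ok])
        ages.append(ds.meta["age_weeks"].to_numpy(dtype=float)[ok])
        dsids.append(ds.meta["dataset_id"].astype(str).to_numpy()[ok])
    if not meth:
        return (np.array([]),) * 4
    return (np.concatenate(meth), np.concatenate(total),
            np.concatenate(ages), np.concatenate(dsids))


@dataclass
class TrainingReport:
    n_candidate_sites: int = 0
    n_sign_consistent: int = 0
    n_main_after_prune: int = 0
    n_main_selected: int = 0
    n_main_fitted: int = 0
    n_backup_fitted: int = 0
    dropped_unusable: list = field(default_factory=list)


def train_clock(
    datasets: list[BulkDataset],
    n_sites: int = _sel.DEFAULT_N_SITES,
    window_bp: int = _sel.PRUNE_WINDOW_BP,
    delta: float = _sel.PRUNE_DELTA,
    min_studies: int = _sel.MIN_STUDIES,
    max_per_dataset_missing: float = _sel.MAX_PER_DATASET_MISSING,
    max_overall_missing: float = _sel.MAX_OVERALL_MISSING,
    grid_step: float = GRID_STEP,
    min_samples: int = MIN_SAMPLES_PER_SITE,
    advisory_ids: tuple[str, ...] = (),
    allow_fewer_sites: bool = True,
    fit_backups: bool = True,
    max_backups: int | None = None,
) -> tuple[ClockModel, TrainingReport]:
    """Full training pipeline: candidate filter -> correlation ranking ->
    pruning -> per-site GLM fits -> expected matrix.

    ``advisory_ids`` marks datasets (e.g. pseudo-bulked single cells) that
    inform coverage and the sign filter but not the ranking.  When
    ``allow_fewer_sites`` the clock keeps every main site if fewer than
    ``n_sites`` survive pruning.
    """
    report = TrainingReport()
    candidates = _sel.filter_candidate_sites(
        datasets, min_studies, max_per_dataset_missing, max_overall_missing
    )
    report.n_candidate_sites = len(candidates)
    assoc = _sel.site_associations(datasets, candidates, advisory_ids)
    ranked = _sel.rank_associations(assoc)
    report.n_sign_consistent = len(ranked)
    sel = _sel.prune_sites(ranked, window_bp, delta)
    report.n_main_after_prune = len(sel.main)
    n_take = min(n_sites, len(sel.main)) if allow_fewer_sites else n_sites
    sel = _sel.select_top(sel, n_take)
    report.n_main_selected = n_take

    informative = [ds for ds in datasets
                   if str(ds.meta["dataset_id"].iloc[0]) not in advisory_ids]
    main_sites, backups, models, mean_rho = [], {}, {}, {}
    for s in sel.main_sites:
        try:
            m = fit_site_model(*_site_observations(informative, s), site=s,
                               min_samples=min_samples)
        except (SiteUnusable, ValueError) as exc:
            report.dropped_unusable.append((s, str(exc)))
            logger.warning("main site %s unusable: %s", s, exc)
            continue
        main_sites.append(s)
        models[s] = m
        mean_rho[s] = float(sel.main.at[s, "mean_rho"])
        fitted_backups = []
        if fit_backups:
            cand = sel.backups.get(s, [])
            if max_backups is not None:
                cand = cand[:max_backups]
            for b in cand:
                try:
                    mb = fit_site_model(*_site_observations(informative, b), site=b,
                                        min_samples=min_samples)
                except (SiteUnusable, ValueError) as exc:
                    report.dropped_unusable.append((b, str(exc)))
                    continue
                models[b] = mb
                if sel.table is not None and b in sel.table.index:
                    mean_rho[b] = float(sel.table.at[b, "mean_rho"])
                fitted_backups.append(b)
        backups[s] = fitted_backups
    if not main_sites:
        raise RuntimeError("no usable main sites after model fitting")
    report.n_main_fitted = len(main_sites)
    report.n_backup_fitted = sum(len(v) for v in backups.values())

    ages = np.concatenate([ds.meta["age_weeks"].to_numpy(dtype=float)
                           for ds in informative])
    age_range = (float(ages.min()), float(ages.max()))
    ordered = [models[s] for s in main_sites] + [
        models[b] for s in main_sites for b in backups[s]
    ]
    expected = build_expected_matrix(ordered, age_range, grid_step)
    model = ClockModel(
        main_sites=main_sites,
        backups=backups,
        models=models,
        expected=expected,
        age_range=age_range,
        grid_step=grid_step,
        mean_rho=mean_rho,
    )
    return model, report
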