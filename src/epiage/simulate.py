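"""Synthetic bulk cohorts and single-cell methylomes.

The generator reproduces the statistical structure the clock assumes:
multi-dataset cohorts with logit-scale batch offsets, per-site monotone age
trajectories under linear/log/sqrt age transformations, binomial read
sampling at finite depth, explicit missingness, and >90%-sparse binary
single-cell coverage obtained by downsampling.  It exists so every pipeline
stage can be exercised end to end — with known ground truth — without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clock import age_transform
from .io import BulkDataset, MethylomeProfile, site_index

CHROMS = tuple(f"chr{i}" for i in range(1, 20))
CHROM_SPAN = 3_000_000


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the package's reference cohort.

    ``slope_range`` gives the |slope| range on the logit scale per week for
    the identity transform; log/sqrt slopes are rescaled so every transform
    spans the same logit range over the cohort ages, keeping effect sizes
    comparable.  ``read_depth`` is the mean per-site sequencing depth
    (Poisson distributed); ``missing_rate`` is additional uniform dropout.
    """

    n_datasets: int = 2
    samples_per_dataset: int = 40
    age_range_weeks: tuple[float, float] = (3.0, 100.0)
    n_sites: int = 2000
    frac_age_associated: float = 0.25
    slope_range: tuple[float, float] = (0.01, 0.05)
    transform_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # identity, log, sqrt
    dataset_effect_sd: float = 0.5
    read_depth: float = 50.0
    missing_rate: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.age_range_weeks[0] <= 0:
            raise ValueError("minimum age must be positive")
        if self.age_range_weeks[1] <= self.age_range_weeks[0]:
            raise ValueError("age range must be increasing")
        if not np.isclose(sum(self.transform_mix), 1.0):
            raise ValueError("transform_mix must sum to 1")
        if not 0.0 <= self.frac_age_associated <= 1.0:
            raise ValueError("frac_age_associated must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_datasets < 1 or self.samples_per_dataset < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """True generator parameters; sufficient to recompute every mean exactly."""

    sites: pd.MultiIndex
    transform: np.ndarray        # per site
    intercept: np.ndarray        # logit scale
    slope: np.ndarray            # logit scale per transformed-age unit
    dataset_effects: dict[str, float]
    ages: pd.Series              # per sample_id
    spec: SyntheticSpec

    def mean_fraction(self, ages, dataset_id: str | None = None) -> np.ndarray:
        """True mean methylation (sites x ages); dataset effect optional."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        eta = np.empty((len(self.sites), len(ages)))
        for t in ("identity", "log", "sqrt"):
            mask = self.transform == t
            if mask.any():
                ta = age_transform(ages, t)
                eta[mask] = self.intercept[mask, None] + np.outer(self.slope[mask], ta)
        if dataset_id is not None:
            eta += self.dataset_effects[dataset_id]
        return expit(eta)

    def expected_matrix(self, age_grid) -> pd.DataFrame:
        """True expected matrix with the average dataset effect added back."""
        grid = np.asarray(age_grid, dtype=float)
        mean_eff = float(np.mean(list(self.dataset_effects.values())))
        eta = logit(self.mean_fraction(grid)) + mean_eff
        return pd.DataFrame(expit(eta), index=self.sites, columns=grid)


def _random_sites(n: int, rng: np.random.Generator) -> pd.MultiIndex:
    seen: set[tuple[str, int]] = set()
    while len(seen) < n:
        chroms = rng.choice(len(CHROMS), size=n - len(seen))
        pos = rng.integers(1, CHROM_SPAN, size=n - len(seen))
        seen.update((CHROMS[c], int(p)) for c, p in zip(chroms, pos))
    return site_index(seen)


def generate_bulk(spec: SyntheticSpec) -> tuple[list[BulkDataset], GroundTruth]:
    """Generate a multi-dataset bulk cohort with known ground truth.

    Ages are uniform on the cohort range; an ``frac_age_associated`` subset
    of sites carries a monotone logit-linear age trajectory under a randomly
    assigned transformation, the rest are flat.  Read totals are Poisson at
    ``read_depth`` (zero-depth and dropout entries are missing) and
    methylated counts are binomial at the true fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.age_range_weeks

    sites = _random_sites(spec.n_sites, rng)
    n = spec.n_sites
    associated = np.zeros(n, dtype=bool)
    associated[rng.choice(n, size=int(round(spec.frac_age_associated * n)),
                          replace=False)] = True
    transform = np.array(
        rng.choice(["identity", "log", "sqrt"], size=n, p=spec.transform_mix),
        dtype=object,
    )
    transform[~associated] = "identity"

    # identity-scale |slope|, rescaled per transform to span the same logit range
    slope_id = rng.uniform(spec.slope_range[0], spec.slope_range[1], size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    span_id = hi - lo
    slope = np.zeros(n)
    for t in ("identity", "log", "sqrt"):
        mask = associated & (transform == t)
        if mask.any():
            span_t = age_transform(hi, t) - age_transform(lo, t)
            slope[mask] = sign[mask] * slope_id[mask] * span_id / span_t

    mid = 0.5 * (lo + hi)
    base = rng.uniform(-2.5, 2.5, size=n)  # logit level at mid-range age
    intercept = np.empty(n)
    for t in ("identity", "log", "sqrt"):
        mask = transform == t
        if mask.any():
            intercept[mask] = base[mask] - slope[mask] * age_transform(mid, t)

    dataset_ids = [f"D{i + 1}" for i in range(spec.n_datasets)]
    effects = {d: float(rng.normal(0.0, spec.dataset_effect_sd))
               for d in dataset_ids}

    datasets, age_records = [], {}
    for d in dataset_ids:
        sample_ids = [f"{d}_s{j + 1}" for j in range(spec.samples_per_dataset)]
        # real cohorts sample animals at whole weeks of age
        ages = rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1,
                            size=spec.samples_per_dataset).astype(float)
        meta = pd.DataFrame({
            "age_weeks": ages,
            "dataset_id": d,
            "tissue": "synthetic",
            "cell_type": pd.NA,
        }, index=pd.Index(sample_ids, name="sample_id"))
        eta = np.empty((spec.samples_per_dataset, n))
        for t in ("identity", "log", "sqrt"):
            mask = transform == t
            if mask.any():
                ta = age_transform(ages, t)
                eta[:, mask] = intercept[mask] + np.outer(ta, slope[mask]) + effects[d]
        p = expit(eta)
        total = rng.poisson(spec.read_depth, size=p.shape).astype(float)
        if spec.missing_rate > 0:
            drop = rng.random(p.shape) < spec.missing_rate
            total[drop] = 0.0
        meth = np.where(total > 0,
                        rng.binomial(total.astype(int), p).astype(float),
                        np.nan)
        total[total == 0.0] = np.nan
        datasets.append(BulkDataset(
            meta=meta,
            meth=pd.DataFrame(meth, index=meta.index, columns=sites),
            total=pd.DataFrame(total, index=meta.index, columns=sites),
        ))
        age_records.update(dict(zip(sample_ids, ages)))

    truth = GroundTruth(
        sites=sites,
        transform=transform,
        intercept=intercept,
        slope=slope,
        dataset_effects=effects,
        ages=pd.Series(age_records, name="age_weeks"),
        spec=spec,
    )
    return datasets, truth


def downsample_to_cell(fractions: pd.Series, n_covered: int,
                       rng_seed: int) -> MethylomeProfile:
    """Downsample one bulk sample's fractions to a sparse binary cell.

    ``n_covered`` sites are drawn uniformly without replacement from the
    sites with data; each emits a single Bernoulli read at the sample's
    methylation fraction.
    """
    fractions = fractions.dropna()
    if n_covered > len(fractions):
        raise ValueError(
            f"requested {n_covered} covered sites, only {len(fractions)} available"
        )
    if n_covered < 1:
        raise ValueError("a cell must cover at least one site")
    rng = np.random.default_rng(rng_seed)
    pick = np.sort(rng.choice(len(fractions), size=n_covered, replace=False))
    sub = fractions.iloc[pick]
    calls = (rng.random(n_covered) < sub.to_numpy()).astype(float)
    return MethylomeProfile(
        calls=pd.Series(calls, index=sub.index).sort_index(),
        source_kind="single_cell",
    )


def simulate_cohort_cells(expected: pd.DataFrame, ages, coverage,
                          rng_seed: int) -> list[tuple[MethylomeProfile, float]]:
    """Simulate labelled single cells from an expected matrix.

    ``ages`` lists the true (grid) age per cell; ``coverage`` is either one
    integer or a sequence of per-cell covered-site counts.  Returns
    (cell, true_age) pairs for calibration and power studies.
    """
    grid = np.asarray(expected.columns, dtype=float)
    ages = np.asarray(ages, dtype=float)
    cov = np.broadcast_to(np.asarray(coverage, dtype=int), ages.shape).copy()
    if np.any(cov < 1):
        raise ValueError("every cell must cover at least one site")
    if np.any(cov > len(expected)):
        raise ValueError("coverage exceeds the number of matrix sites")
    rng = np.random.default_rng(rng_seed)
    cells = []
    values = expected.to_numpy()
    for age, k in zip(ages, cov):
        j = int(np.argmin(np.abs(grid - age)))
        if abs(grid[j] - age) > 1e-6:
            raise ValueError(f"age {age} is not on the matrix grid")
        pick = np.sort(rng.choice(len(expected), size=int(k), replace=False))
        p = values[pick, j]
        calls = (rng.random(len(pick)) < p).astype(float)
        prof = MethylomeProfile(
            calls=pd.Series(calls, index=expected.index[pick]).sort_index(),
            source_kind="single_cell",
        )
        cells.append((prof, float(grid[j])))
    return cells


def write_cohort(datasets: list[BulkDataset], outdir) -> None:
    """Write a cohort in the coverage + metadata formats the readers consume."""
    from pathlib import Path
    from .io import write_coverage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for ds in datasets:
        for sid in ds.meta.index:
            counts = pd.DataFrame({
                "meth": ds.meth.loc[sid].dropna(),
                "total": ds.total.loc[sid].dropna(),
            })
            write_coverage(outdir / f"{sid}.cov", counts)
        metas.append(ds.meta.reset_index())
    meta = pd.concat(metas, ignore_index=True)
    meta.to_csv(outdir / "metadata.csv", index=False)
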