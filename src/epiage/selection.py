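"""Selection of age-associated CpG sites across heterogeneous bulk datasets.

The clock keeps CpGs whose methylation correlates with age consistently
across training datasets.  Nearby sites carrying near-identical information
are pruned, but the pruned sites are remembered as *backups*: when a main
site is uncovered in a query methylome, a backup can stand in for it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BulkDataset, site_index

MIN_STUDIES = 2
MAX_PER_DATASET_MISSING = 0.25
MAX_OVERALL_MISSING = 0.33
PRUNE_WINDOW_BP = 5000
PRUNE_DELTA = 0.1
DEFAULT_N_SITES = 750


def filter_candidate_sites(
    datasets: list[BulkDataset],
    min_studies: int = MIN_STUDIES,
    max_per_dataset_missing: float = MAX_PER_DATASET_MISSING,
    max_overall_missing: float = MAX_OVERALL_MISSING,
) -> pd.MultiIndex:
    """Sites covered in >= ``min_studies`` datasets, with bounded missingness.

    A dataset *covers* a site if any of its samples has an observation there.
    Per-dataset missingness is evaluated only over covering datasets; overall
    missingness is evaluated over every sample of every supplied dataset.
    """
    if len(datasets) < 2:
        raise ValueError("site selection requires at least 2 datasets")
    all_sites = site_index(set().union(*(set(ds.sites) for ds in datasets)))
    n_total_samples = sum(len(ds.samples) for ds in datasets)

    n_covering = pd.Series(0, index=all_sites)
    worst_miss = pd.Series(0.0, index=all_sites)
    n_obs = pd.Series(0.0, index=all_sites)
    for ds in datasets:
        present = ds.total.notna().reindex(columns=all_sites, fill_value=False)
        frac_present = present.mean(axis=0)
        covers = frac_present > 0
        n_covering += covers.astype(int)
        miss = (1.0 - frac_present).where(covers, 0.0)
        worst_miss = np.maximum(worst_miss, miss)
        n_obs += present.sum(axis=0)

    overall_miss = 1.0 - n_obs / n_total_samples
    keep = (
        (n_covering >= min_studies)
        & (worst_miss <= max_per_dataset_missing)
        & (overall_miss <= max_overall_missing)
    )
    return all_sites[keep.to_numpy()]


def spearman_age_correlation(ages, fractions) -> float:
    """Spearman rank correlation of methylation with age; NaN if undefined.

    Requires >= 3 complete pairs; constant methylation or constant age gives
    NaN (zero rank variance).  Ties are handled by average ranks.
    """
    ages = np.asarray(ages, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    ok = ~(np.isnan(ages) | np.isnan(fractions))
    a, f = ages[ok], fractions[ok]
    if len(a) < 3 or np.all(a == a[0]) or np.all(f == f[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(a, f).statistic
    return float(rho)


def site_associations(
    datasets: list[BulkDataset],
    sites: pd.MultiIndex,
    advisory_ids: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-dataset Spearman rho with age, combined across datasets.

    Returns a frame indexed by site with one ``rho:<dataset>`` column per
    dataset plus ``mean_rho`` and ``sign_consistent``.  Datasets listed in
    ``advisory_ids`` take part in the sign-consistency filter but do not
    contribute to ``mean_rho`` (useful for pseudo-bulked single-cell data
    whose scale is not comparable to bulk).
    """
    rho_cols: dict[str, pd.Series] = {}
    for ds in datasets:
        ages = ds.meta["age_weeks"].to_numpy(dtype=float)
        frac = ds.fractions().reindex(columns=sites)
        dsid = str(ds.meta["dataset_id"].iloc[0])
        vals = frac.to_numpy()
        rho = np.full(len(sites), np.nan)
        for j in range(len(sites)):
            rho[j] = spearman_age_correlation(ages, vals[:, j])
        rho_cols[dsid] = pd.Series(rho, index=sites)

    tab = pd.DataFrame({f"rho:{d}": s for d, s in rho_cols.items()})
    informative = [d for d in rho_cols if d not in advisory_ids]
    if not informative:
        raise ValueError("all datasets are advisory; nothing to rank on")
    rho_all = tab.to_numpy()
    rho_inf = tab[[f"rho:{d}" for d in informative]].to_numpy()

    with np.errstate(invalid="ignore"):
        signs = np.sign(rho_all)
    signs[np.isnan(rho_all)] = 0.0  # missing and exact zero are sign-neutral
    any_pos = (signs > 0).any(axis=1)
    any_neg = (signs < 0).any(axis=1)
    tab["sign_consistent"] = ~(any_pos & any_neg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        tab["mean_rho"] = np.nanmean(rho_inf, axis=1)
    return tab


def combine_associations(rho_by_dataset: dict[str, float],
                         advisory_ids: tuple[str, ...] = ()) -> tuple[float, bool]:
    """Combine per-dataset rho for one site: (mean_rho, sign_consistent).

    ``mean_rho`` is the unweighted mean over non-missing, non-advisory
    values; sign consistency holds iff all non-missing values (advisory
    included) share one sign, zero counting as neutral.
    """
    vals = {d: v for d, v in rho_by_dataset.items() if v is not None and not np.isnan(v)}
    if not vals:
        raise ValueError("at least one non-missing rho is required")
    signs = {np.sign(v) for v in vals.values()} - {0.0}
    consistent = len(signs) <= 1
    informative = [v for d, v in vals.items() if d not in advisory_ids]
    mean_rho = float(np.mean(informative)) if informative else float("nan")
    return mean_rho, consistent


def rank_associations(assoc: pd.DataFrame) -> pd.DataFrame:
    """Keep sign-consistent sites with defined mean_rho, ranked by |mean_rho|.

    Ties in |mean_rho| are broken by (chrom, pos) ascending so the ranking
    is a deterministic total order.
    """
    keep = assoc["sign_consistent"] & assoc["mean_rho"].notna()
    ranked = assoc[keep].copy()
    ranked["abs_rho"] = ranked["mean_rho"].abs()
    # stable sort after ordering by site gives the (chrom, pos) tie-break
    ranked = ranked.sort_index()
    ranked = ranked.sort_values("abs_rho", ascending=False, kind="mergesort")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


@dataclass
class SelectionResult:
    """Ordered main sites and the backup map produced by pruning."""

    main: pd.DataFrame                     # ranked association rows, mains only
    backups: dict[tuple, list[tuple]] = field(default_factory=dict)
    table: pd.DataFrame | None = None      # full association table (mains + backups)

    @property
    def main_sites(self) -> list[tuple]:
        return list(self.main.index)

    def backup_sites(self) -> list[tuple]:
        return [s for bl in self.backups.values() for s in bl]


def prune_sites(ranked: pd.DataFrame, window_bp: int = PRUNE_WINDOW_BP,
                delta: float = PRUNE_DELTA) -> SelectionResult:
    """Greedy redundancy pruning of ranked sites, keeping backups.

    Scanning in rank order (highest |mean_rho| first), a site is demoted to
    a backup of an already-retained main when both lie on the same
    chromosome within ``window_bp`` bases and their |mean_rho| differ by
    less than ``delta``; otherwise it is retained as a new main.  When
    several mains qualify, the highest-ranked one takes the backup.
    """
    mains: list[tuple] = []
    backups: dict[tuple, list[tuple]] = {}
    by_chrom: dict[str, list[tuple[int, float, tuple]]] = {}

    abs_rho = ranked["abs_rho"] if "abs_rho" in ranked else ranked["mean_rho"].abs()
    for site, a in zip(ranked.index, abs_rho.to_numpy()):
        chrom, pos = site
        partner = None
        for mpos, ma, msite in by_chrom.get(chrom, ()):
            if abs(pos - mpos) <= window_bp and abs(a - ma) < delta:
                partner = msite
                break
        if partner is None:
            mains.append(site)
            backups[site] = []
            by_chrom.setdefault(chrom, []).append((pos, a, site))
        else:
            backups[partner].append(site)

    main_tab = ranked.loc[mains]
    return SelectionResult(main=main_tab, backups=backups, table=ranked)


def select_top(sel: SelectionResult, n_sites: int = DEFAULT_N_SITES) -> SelectionResult:
    """Keep the top ``n_sites`` main sites (with their backups)."""
    if n_sites > len(sel.main):
        raise ValueError(
            f"requested {n_sites} main sites but only {len(sel.main)} available "
            f"(short by {n_sites - len(sel.main)})"
        )
    main = sel.main.iloc[:n_sites]
    backups = {s: sel.backups.get(s, []) for s in main.index}
    return SelectionResult(main=main, backups=backups, table=sel.table)


def selection_table(sel: SelectionResult) -> pd.DataFrame:
    """Flat export of the selection: one row per main or backup site."""
    rows = []
    src = sel.table if sel.table is not None else sel.main
    rho_cols = [c for c in src.columns if c.startswith("rho:")]
    for site in sel.main.index:
        rows.append((site, "main", None))
        for b in sel.backups.get(site, []):
            rows.append((b, "backup", site))
    recs = []
    for site, role, partner in rows:
        rec = {"chrom": site[0], "pos": site[1], "role": role,
               "main_partner": f"{partner[0]}:{partner[1]}" if partner else ""}
        if site in src.index:
            rec["mean_rho"] = src.at[site, "mean_rho"]
            for c in rho_cols:
                rec[c] = src.at[site, c]
        recs.append(rec)
    return pd.DataFrame(recs)
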