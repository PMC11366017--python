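"""Data model and I/O for methylation count data.

Conventions used throughout the package:

* CpG sites are keyed by ``(chrom, pos)`` with ``pos`` the 1-based position of
  the C on the forward strand; collections of sites are pandas MultiIndexes
  named ``("chrom", "pos")`` ordered by (chrom lexical, pos ascending).
* Methylation is carried internally as a *fraction* in [0, 1]; percent values
  are converted at the I/O boundary.
* Missing observations are explicit (``NaN``), never encoded as 0%
  methylation — sparsity is the central difficulty the predictor addresses.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("epiage")

SITE_INDEX_NAMES = ("chrom", "pos")

#: default per-dataset QC thresholds
MIN_COVERAGE = 5
MIN_SITE_SAMPLE_FRAC = 0.8
MAX_SAMPLE_MISSING = 0.25
PCA_SD = 2.0


class CpgSite(NamedTuple):
    """A forward-strand CpG locus; the universal site key."""

    chrom: str
    pos: int


def site_index(sites: Iterable[tuple[str, int]]) -> pd.MultiIndex:
    """Build the canonical (chrom, pos) MultiIndex, sorted."""
    idx = pd.MultiIndex.from_tuples(
        [(str(c), int(p)) for c, p in sites], names=SITE_INDEX_NAMES
    )
    return idx.sortlevel()[0]


def site_label(site: tuple[str, int]) -> str:
    return f"{site[0]}:{site[1]}"


@dataclass
class MethylomeProfile:
    """One query methylome: sparse map of CpG site -> methylation fraction.

    ``calls`` is a float Series indexed by (chrom, pos).  Single-cell
    profiles are predominantly binary but fractional values are permitted
    (CpGs covered by more than one read).
    """

    calls: pd.Series
    source_kind: str = "bulk"  # bulk | pseudobulk | single_cell

    def __post_init__(self) -> None:
        if self.source_kind not in ("bulk", "pseudobulk", "single_cell"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        self.calls = self.calls.astype(float)
        if len(self.calls) and not self.calls.index.is_monotonic_increasing:
            self.calls = self.calls.sort_index()
        vals = self.calls.to_numpy()
        if np.any(np.isnan(vals)) or np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("profile values must be fractions in [0, 1]")

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class BulkDataset:
    """Samples x sites methylation counts with per-sample metadata.

    ``meta`` is indexed by sample_id with columns ``age_weeks``,
    ``dataset_id``, ``tissue`` and optional ``cell_type``.  ``meth`` and
    ``total`` are float frames (samples x sites, NaN where uncovered).
    """

    meta: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("age_weeks", "dataset_id", "tissue"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "cell_type" not in self.meta.columns:
            self.meta = self.meta.assign(cell_type=pd.NA)
        if (self.meta["age_weeks"] <= 0).any():
            raise ValueError("age_weeks must be positive")
        if not self.meth.index.equals(self.meta.index) or not self.total.index.equals(
            self.meta.index
        ):
            raise ValueError("count frames must be indexed by the metadata samples")
        if not self.meth.columns.equals(self.total.columns):
            raise ValueError("meth and total must share the same site columns")
        with np.errstate(invalid="ignore"):
            m, t = self.meth.to_numpy(), self.total.to_numpy()
            if np.any(np.isnan(m) != np.isnan(t)):
                raise ValueError("meth and total must share the same missing pattern")
            bad = ~np.isnan(t) & ((t <= 0) | (m < 0) | (m > t))
            if bad.any():
                raise ValueError("invalid counts: need 0 <= meth <= total, total > 0")

    @property
    def sites(self) -> pd.MultiIndex:
        return self.meth.columns

    @property
    def samples(self) -> pd.Index:
        return self.meta.index

    def fractions(self) -> pd.DataFrame:
        """Observed methylation fractions (NaN where uncovered)."""
        return self.meth / self.total

    def subset_sites(self, sites: pd.MultiIndex | list) -> "BulkDataset":
        return BulkDataset(self.meta, self.meth.loc[:, sites], self.total.loc[:, sites])

    def subset_samples(self, samples) -> "BulkDataset":
        return BulkDataset(
            self.meta.loc[samples], self.meth.loc[samples], self.total.loc[samples]
        )


# ---------------------------------------------------------------------------
# Bismark-style coverage files
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_coverage_counts(path) -> pd.DataFrame:
    """Read a coverage file into per-site counts.

    The dialect is tab-separated with >= 6 columns: chrom, start, end,
    percent methylation, count methylated, count unmethylated (1-based
    inclusive coordinates).  Returns a frame indexed by (chrom, pos) with
    integer columns ``meth`` and ``total``; zero-depth rows are dropped.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed row at line {lineno}: "
                                 f"expected >=6 tab-separated fields")
            try:
                chrom = parts[0]
                pos = int(parts[1])
                # floats allowed: profiles round-trip as weight-1 pseudo-counts
                meth = float(parts[4])
                unmeth = float(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            if meth + unmeth == 0:
                continue
            rows.append((chrom, pos, meth, meth + unmeth))
    if not rows:
        return pd.DataFrame(
            {"meth": pd.Series(dtype=float), "total": pd.Series(dtype=float)},
            index=site_index([]),
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df = df.set_index(["chrom", "pos"]).sort_index()
    return df


def read_coverage(path, scale: str = "percent") -> MethylomeProfile:
    """Read a coverage file as a methylome profile (fractions in [0, 1]).

    ``scale`` names how the 4th column is encoded (percent or fraction);
    fractions are always recomputed from the counts, so the parameter only
    matters for files written without counts by other tools.
    """
    if scale not in ("percent", "fraction"):
        raise ValueError("scale must be 'percent' or 'fraction'")
    counts = read_coverage_counts(path)
    calls = counts["meth"] / counts["total"]
    calls.name = None
    return MethylomeProfile(calls=calls, source_kind="bulk")


def write_coverage(path, counts: pd.DataFrame | MethylomeProfile,
                   scale: str = "percent") -> None:
    """Write counts (or a profile, with unit pseudo-depth) as a coverage file."""
    if isinstance(counts, MethylomeProfile):
        frac = counts.calls
        counts = pd.DataFrame({"meth": frac, "total": 1.0})
        # profiles carry fractions, not reads: emit fractional "counts" so the
        # round-trip through read_coverage reproduces the calls exactly
        fmt_meth = [repr(float(v)) for v in counts["meth"]]
    else:
        fmt_meth = [str(int(v)) for v in counts["meth"]]
    factor = 100.0 if scale == "percent" else 1.0
    with _open_text(path, "wt") as fh:
        for (chrom, pos), row, ms in zip(counts.index, counts.itertuples(index=False), fmt_meth):
            frac = row.meth / row.total
            unmeth = row.total - row.meth
            if float(unmeth) == int(unmeth):
                unmeth = int(unmeth)
            fh.write(f"{chrom}\t{pos}\t{pos}\t{frac * factor:.10g}\t{ms}\t{unmeth}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV (sample_id, age_weeks, dataset_id, tissue[, cell_type])."""
    meta = pd.read_csv(path, dtype={"sample_id": str, "dataset_id": str})
    required = {"sample_id", "age_weeks", "dataset_id", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "cell_type" not in meta.columns:
        meta["cell_type"] = pd.NA
    return meta.set_index("sample_id")


def assemble_dataset(meta: pd.DataFrame, counts_by_sample: dict[str, pd.DataFrame]) -> BulkDataset:
    """Join per-sample coverage count frames into one BulkDataset."""
    missing = set(meta.index) - set(counts_by_sample)
    if missing:
        raise ValueError(f"no coverage data for samples: {sorted(missing)}")
    all_sites = site_index(
        set().union(*(set(counts_by_sample[s].index) for s in meta.index))
    )
    meth = pd.DataFrame(np.nan, index=meta.index, columns=all_sites)
    total = pd.DataFrame(np.nan, index=meta.index, columns=all_sites)
    for s in meta.index:
        c = counts_by_sample[s]
        meth.loc[s, c.index] = c["meth"].to_numpy(dtype=float)
        total.loc[s, c.index] = c["total"].to_numpy(dtype=float)
    return BulkDataset(meta=meta, meth=meth, total=total)


# ---------------------------------------------------------------------------
# Forward-strand collapse
# ---------------------------------------------------------------------------

def collapse_to_forward(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse stranded CpG methylation calls onto the forward strand.

    ``records`` has columns chrom, pos, strand (+/-), meth, unmeth and an
    optional ``context`` column; rows whose context is not CpG (``CpG``/
    ``CG``) are removed as ambiguous.  A reverse-strand call at position p+1
    is summed onto the forward C at p.  A reverse call with no forward
    partner is reassigned to pos-1 (the CpG context guarantees a forward C
    one base upstream) with a logged warning.

    Returns a (chrom, pos)-indexed frame with summed ``meth``/``total``.
    """
    rec = records.copy()
    if "context" in rec.columns:
        keep = rec["context"].str.upper().isin(["CPG", "CG"])
        rec = rec[keep]
    if not set(rec["strand"]).issubset({"+", "-"}):
        raise ValueError("strand must be '+' or '-'")

    fwd = rec[rec["strand"] == "+"]
    rev = rec[rec["strand"] == "-"].copy()
    fwd_keys = set(zip(fwd["chrom"], fwd["pos"]))
    if len(rev):
        partnered = [
            (c, p - 1) in fwd_keys for c, p in zip(rev["chrom"], rev["pos"])
        ]
        n_orphan = len(partnered) - int(np.sum(partnered))
        if n_orphan:
            logger.warning(
                "%d reverse-strand calls had no forward partner; "
                "reassigned to pos-1", n_orphan,
            )
        rev["pos"] = rev["pos"] - 1

    merged = pd.concat([fwd, rev], ignore_index=True)
    if merged.empty:
        return pd.DataFrame(
            {"meth": pd.Series(dtype=int), "total": pd.Series(dtype=int)},
            index=site_index([]),
        )
    merged["total"] = merged["meth"] + merged["unmeth"]
    out = merged.groupby(["chrom", "pos"])[["meth", "total"]].sum().sort_index()
    out.index.names = SITE_INDEX_NAMES
    return out


# ---------------------------------------------------------------------------
# Per-dataset QC
# ---------------------------------------------------------------------------

class DatasetFailedQC(RuntimeError):
    """All samples of a (dataset, tissue) group were removed during QC."""


@dataclass
class QCReport:
    """Every removal performed by :func:`qc_dataset`, with its reason."""

    dropped_sites: list = field(default_factory=list)      # (site, reason)
    dropped_samples: list = field(default_factory=list)    # (sample_id, reason)
    n_sites_in: int = 0
    n_sites_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0


def qc_dataset(
    ds: BulkDataset,
    min_cov: int = MIN_COVERAGE,
    site_frac: float = MIN_SITE_SAMPLE_FRAC,
    max_sample_missing: float = MAX_SAMPLE_MISSING,
    pca_sd: float = PCA_SD,
) -> tuple[BulkDataset, QCReport]:
    """Quality-control one (dataset, tissue) group of bulk samples.

    Steps, in order: (1) keep sites with depth >= ``min_cov`` in at least
    ``site_frac`` of the samples; (2) drop samples missing more than
    ``max_sample_missing`` of the kept sites; (3) subset to sites covered
    in every remaining sample; (4) PCA on the methylation fractions and
    drop samples outside mean +/- ``pca_sd``*SD on PC1 or PC2.
    """
    if len(ds.samples) < 3:
        raise ValueError("QC requires at least 3 samples (PCA)")
    report = QCReport(n_sites_in=len(ds.sites), n_samples_in=len(ds.samples))

    total = ds.total
    ok = (total >= min_cov).sum(axis=0) / len(ds.samples) >= site_frac
    for s in ds.sites[~ok]:
        report.dropped_sites.append((s, f"<{min_cov}X in {site_frac:.0%} of samples"))
    ds = ds.subset_sites(ds.sites[ok.to_numpy()])
    if len(ds.sites) == 0:
        raise DatasetFailedQC("no sites survive the coverage filter")

    miss = ds.total.isna().mean(axis=1)
    bad_samples = miss > max_sample_missing
    for s in ds.samples[bad_samples]:
        report.dropped_samples.append((s, f"missingness {miss[s]:.0%} > {max_sample_missing:.0%}"))
    keep = ds.samples[~bad_samples.to_numpy()]
    if len(keep) == 0:
        raise DatasetFailedQC("all samples exceed the missingness threshold")
    ds = ds.subset_samples(keep)

    fully = ds.total.notna().all(axis=0)
    for s in ds.sites[~fully]:
        report.dropped_sites.append((s, "not covered in all retained samples"))
    ds = ds.subset_sites(ds.sites[fully.to_numpy()])
    if len(ds.sites) == 0:
        raise DatasetFailedQC("no sites covered in all retained samples")

    if len(ds.samples) >= 3:
        frac = ds.fractions().to_numpy()
        # intended path: fully covered sites, so imputation is a no-op
        col_mean = np.nanmean(frac, axis=0)
        frac = np.where(np.isnan(frac), col_mean, frac)
        n_pc = min(2, len(ds.samples) - 1, frac.shape[1])
        scores = PCA(n_components=n_pc).fit_transform(frac)
        outlier = np.zeros(len(ds.samples), dtype=bool)
        for j in range(n_pc):
            mu, sd = scores[:, j].mean(), scores[:, j].std(ddof=1)
            if sd > 0:
                outlier |= np.abs(scores[:, j] - mu) > pca_sd * sd
        for s in ds.samples[outlier]:
            report.dropped_samples.append((s, f"PC score outside mean +/- {pca_sd}*SD"))
        if outlier.all():
            raise DatasetFailedQC("all samples flagged as PCA outliers")
        ds = ds.subset_samples(ds.samples[~outlier])

    report.n_sites_out = len(ds.sites)
    report.n_samples_out = len(ds.samples)
    return ds, report


def qc_by_group(ds: BulkDataset, **kwargs) -> tuple[list[BulkDataset], dict]:
    """Apply :func:`qc_dataset` per (dataset_id, tissue) group."""
    out, reports = [], {}
    for (dsid, tissue), meta in ds.meta.groupby(["dataset_id", "tissue"], sort=True):
        sub = ds.subset_samples(meta.index)
        covered = sub.total.notna().any(axis=0)
        sub = sub.subset_sites(sub.sites[covered.to_numpy()])
        clean, rep = qc_dataset(sub, **kwargs)
        out.append(clean)
        reports[(dsid, tissue)] = rep
    return out, reports
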