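"""Distance-based age scoring of methylome profiles against a trained clock.

A query profile is compared with the expected methylation matrix at every
grid age.  The score of an age is the summed log similarity over usable
clock sites, ln(1 - |observed - expected| + epsilon); on binary single-cell
calls the per-site term reduces to the Bernoulli log-likelihood of the
observed state, so the rule covers continuous bulk profiles and binary
methylomes alike.  The predicted age is the grid argmax.  Uncovered main
sites are substituted by their highest-ranked covered backup, each scored
against its own expected row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockModel
from .io import MethylomeProfile

EPSILON = 1e-3        # floor inside the log; bounds a single site's influence
MIN_SITES_BULK = 1
MIN_SITES_SINGLE_CELL = 40  # below this, single-cell predictions are unreliable


class NoUsableSites(RuntimeError):
    """The profile covers neither main nor backup version of any clock site."""


@dataclass
class ResolvedSite:
    main: tuple
    used: tuple
    fraction: float

    @property
    def is_backup(self) -> bool:
        return self.used != self.main


def resolve_sites(profile: MethylomeProfile, model: ClockModel) -> list[ResolvedSite]:
    """Map each main clock site to the site actually usable in the profile.

    The main site is used when covered; otherwise the first covered backup
    (in backup rank order) stands in; otherwise the main site is omitted.
    """
    calls = profile.calls
    covered = set(calls.index)
    out: list[ResolvedSite] = []
    for s in model.main_sites:
        if s in covered:
            out.append(ResolvedSite(s, s, float(calls[s])))
            continue
        for b in model.backups.get(s, []):
            if b in covered:
                out.append(ResolvedSite(s, b, float(calls[b])))
                break
    return out


def score_age(resolved: list[ResolvedSite], expected: pd.DataFrame, age: float,
              epsilon: float = EPSILON) -> float:
    """Score one grid age: sum of ln(1 - |observed - expected| + epsilon).

    Higher is better; a perfect match scores n * ln(1 + epsilon), the strict
    per-site maximum.  For a binary call b the term equals ln(e + epsilon)
    when b = 1 and ln(1 - e + epsilon) when b = 0, the (floored) Bernoulli
    log-likelihood of the observed state at expected fraction e.
    """
    if not resolved:
        raise NoUsableSites("no usable sites")
    cols = np.asarray(expected.columns, dtype=float)
    i = int(np.argmin(np.abs(cols - age)))
    if abs(cols[i] - age) > 1e-6:
        raise KeyError(f"age {age} is not a grid age")
    col = expected.iloc[:, i]
    obs = np.array([r.fraction for r in resolved])
    exp = np.array([col[r.used] for r in resolved])
    return float(np.sum(np.log1p(epsilon - np.abs(obs - exp))))


@dataclass
class AgePrediction:
    predicted_age_weeks: float
    score_profile: pd.Series           # grid age -> score
    n_sites_used: int
    n_backup_substitutions: int
    passed_min_sites: bool
    degenerate: bool = False           # all grid ages tied


def _score_matrix(obs: np.ndarray, exp_rows: np.ndarray, epsilon: float) -> np.ndarray:
    """Scores over all grid ages for one profile (sites x ages expected rows)."""
    return np.log1p(epsilon - np.abs(obs[:, None] - exp_rows)).sum(axis=0)


def score_binary_cells(cells: np.ndarray, exp_rows: np.ndarray,
                       epsilon: float = EPSILON) -> np.ndarray:
    """Vectorised scoring of many binary cells on a fixed site set.

    For a binary call b at a site with expected fraction e the per-site
    score ln(1 - |b - e| + eps) is ln(e + eps) when b = 1 and
    ln(1 - e + eps) when b = 0, so the total over sites is a pair of matrix
    products.  ``cells`` is (n_cells x n_sites) in {0, 1}, ``exp_rows`` is
    (n_sites x n_ages); returns (n_cells x n_ages) scores identical to
    scoring each cell with :func:`score_age`.
    """
    l1 = np.log(exp_rows + epsilon)
    l0 = np.log1p(epsilon - exp_rows)
    return cells @ l1 + (1.0 - cells) @ l0


def predict_from_scores(scores: np.ndarray, grid: np.ndarray) -> float:
    """Grid argmax (best similarity) with ties broken to the youngest age."""
    return float(grid[int(np.argmax(scores))])


def predict_age(profile: MethylomeProfile, model: ClockModel,
                min_sites: int = MIN_SITES_BULK, epsilon: float = EPSILON,
                strict: bool = False) -> AgePrediction:
    """Predict the epigenetic age of one methylome profile.

    ``min_sites`` is a reliability gate (recommended 40 for single cells):
    predictions below it are flagged via ``passed_min_sites`` rather than
    suppressed, unless ``strict`` is set.  A profile covering no clock site
    raises :class:`NoUsableSites`.
    """
    resolved = resolve_sites(profile, model)
    if not resolved:
        raise NoUsableSites("profile covers no clock site (main or backup)")
    passed = len(resolved) >= min_sites
    if strict and not passed:
        raise NoUsableSites(
            f"only {len(resolved)} usable sites < min_sites={min_sites}"
        )
    grid = model.age_grid
    obs = np.array([r.fraction for r in resolved])
    exp_rows = model.expected.loc[[r.used for r in resolved]].to_numpy()
    scores = _score_matrix(obs, exp_rows, epsilon)
    degenerate = bool(np.allclose(scores, scores[0]))
    return AgePrediction(
        predicted_age_weeks=predict_from_scores(scores, grid),
        score_profile=pd.Series(scores, index=grid),
        n_sites_used=len(resolved),
        n_backup_substitutions=sum(r.is_backup for r in resolved),
        passed_min_sites=passed,
        degenerate=degenerate,
    )


@dataclass
class PseudoBulk:
    """Per-site mean methylation over the single cells of one group."""

    profile: MethylomeProfile
    member_ids: list = field(default_factory=list)


def pseudo_bulk(cells: dict[str, MethylomeProfile],
                group_by: dict[str, str]) -> dict[str, PseudoBulk]:
    """Aggregate single cells into pseudo-bulk profiles per group (donor).

    Each site's value is the mean over the member cells covering it; sites
    covered by no member are absent.
    """
    groups: dict[str, list[str]] = {}
    for cell_id in cells:
        groups.setdefault(group_by[cell_id], []).append(cell_id)
    out = {}
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} has no cells")
        stacked = pd.concat(
            {m: cells[m].calls for m in members}, axis=1
        )
        mean = stacked.mean(axis=1, skipna=True).dropna()
        out[g] = PseudoBulk(
            profile=MethylomeProfile(calls=mean, source_kind="pseudobulk"),
            member_ids=sorted(members),
        )
    return out


def predictions_table(preds: dict[str, AgePrediction]) -> pd.DataFrame:
    """Flat per-sample prediction table for TSV export."""
    rows = []
    for sid, p in preds.items():
        rows.append({
            "sample_id": sid,
            "predicted_age_weeks": p.predicted_age_weeks,
            "n_sites_used": p.n_sites_used,
            "n_backup_substitutions": p.n_backup_substitutions,
            "passed_min_sites": p.passed_min_sites,
        })
    return pd.DataFrame(rows)
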