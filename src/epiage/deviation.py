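"""Significance of a single cell's age deviation via matched simulation.

Whether a cell's predicted age differs from its chronological age more than
technically expected is decided empirically: simulate many binary cells from
the expected methylation profile at the chronological age, restricted to
exactly the clock sites usable in the cell of interest, predict each, and
locate the real prediction in that null distribution.  A cell is called
*older* (resp. *younger*) when fewer than ``alpha`` of the simulated
predictions lie strictly above (resp. below) the real one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import ClockModel
from .io import MethylomeProfile, site_index
from .predict import (EPSILON, NoUsableSites, predict_from_scores,
                      resolve_sites, score_binary_cells)

N_SIMS = 1000
ALPHA = 0.05
MIN_SIMS = 100


@dataclass
class DeviationResult:
    cell_id: str
    expected_age_weeks: float
    predicted_age_weeks: float
    frac_sims_higher: float
    frac_sims_lower: float
    verdict: str                 # older | younger | within
    n_sims: int
    n_sites_used: int
    seed: int


def _expected_column(expected: pd.DataFrame, age: float) -> pd.Series:
    cols = np.asarray(expected.columns, dtype=float)
    i = int(np.argmin(np.abs(cols - age)))
    if abs(cols[i] - age) > 1e-6:
        raise ValueError(f"age {age} is not on the expected-matrix grid")
    return expected.iloc[:, i]


def simulate_matched_cell(expected: pd.DataFrame, age: float,
                          covered_sites: list[tuple],
                          rng_seed: int) -> MethylomeProfile:
    """One simulated binary cell matching the expected profile at ``age``.

    Each covered site is an independent Bernoulli draw with success
    probability equal to the expected methylation fraction at (site, age).
    """
    col = _expected_column(expected, age)
    missing = [s for s in covered_sites if s not in col.index]
    if missing:
        raise KeyError(f"sites absent from the expected matrix: {missing[:3]}")
    p = col.loc[covered_sites].to_numpy(dtype=float)
    rng = np.random.default_rng(rng_seed)
    calls = (rng.random(len(p)) < p).astype(float)
    return MethylomeProfile(
        calls=pd.Series(calls, index=site_index(covered_sites)),
        source_kind="single_cell",
    )


def deviation_test(cell: MethylomeProfile, expected_age: float,
                   model: ClockModel, n_sims: int = N_SIMS,
                   alpha: float = ALPHA, rng_seed: int = 0,
                   epsilon: float = EPSILON,
                   cell_id: str = "") -> DeviationResult:
    """Empirical test of one cell's age deviation.

    The null is conditioned on the sites actually used in scoring the cell
    (after backup resolution), so it matches the scoring geometry.  Tail
    fractions use strict inequality: simulated predictions exactly equal to
    the real one count toward neither tail.  All ``n_sims`` simulations are
    drawn from one generator seeded with ``rng_seed`` (simulation i consumes
    the i-th block of the stream), so results are reproducible per
    (cell, seed).
    """
    if n_sims < MIN_SIMS:
        raise ValueError(f"n_sims must be >= {MIN_SIMS} for a usable tail estimate")
    expected_age = model.grid_age(expected_age)
    resolved = resolve_sites(cell, model)
    if not resolved:
        raise NoUsableSites("cell covers no clock site")
    used = [r.used for r in resolved]
    exp_rows = model.expected.loc[used].to_numpy()   # sites x grid ages
    grid = model.age_grid

    obs = np.array([r.fraction for r in resolved])
    real_scores = np.log1p(epsilon - np.abs(obs[:, None] - exp_rows)).sum(axis=0)
    real_pred = predict_from_scores(real_scores, grid)

    age_idx = int(np.argmin(np.abs(grid - expected_age)))
    p_null = exp_rows[:, age_idx]
    rng = np.random.default_rng(rng_seed)
    sims = (rng.random((n_sims, len(used))) < p_null).astype(float)
    sim_scores = score_binary_cells(sims, exp_rows, epsilon)
    sim_preds = grid[np.argmax(sim_scores, axis=1)]

    frac_higher = float(np.mean(sim_preds > real_pred))
    frac_lower = float(np.mean(sim_preds < real_pred))
    if frac_higher < alpha and frac_lower < alpha:
        # pathologically concentrated null: call the more extreme tail
        verdict = "older" if frac_higher <= frac_lower else "younger"
    elif frac_higher < alpha:
        verdict = "older"
    elif frac_lower < alpha:
        verdict = "younger"
    else:
        verdict = "within"
    return DeviationResult(
        cell_id=cell_id,
        expected_age_weeks=float(expected_age),
        predicted_age_weeks=float(real_pred),
        frac_sims_higher=frac_higher,
        frac_sims_lower=frac_lower,
        verdict=verdict,
        n_sims=n_sims,
        n_sites_used=len(used),
        seed=int(rng_seed),
    )


def deviation_table(results: list[DeviationResult]) -> pd.DataFrame:
    rows = [{
        "cell_id": r.cell_id,
        "expected_age_weeks": r.expected_age_weeks,
        "predicted_age_weeks": r.predicted_age_weeks,
        "frac_sims_higher": r.frac_sims_higher,
        "frac_sims_lower": r.frac_sims_lower,
        "verdict": r.verdict,
        "n_sims": r.n_sims,
        "seed": r.seed,
    } for r in results]
    return pd.DataFrame(rows)
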