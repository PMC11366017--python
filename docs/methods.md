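# Methods

## Model

`epiage` predicts epigenetic age by direct comparison with an expected
methylation-vs-age table rather than through a fixed regression over a
mandatory site set. The assumptions are:

1. At a clock CpG, the population methylation fraction changes monotonically
   with age on the logit scale, linearly in one of three age
   transformations: `T(a) = a`, `ln a` or `√a` (ages in weeks, strictly
   positive).
2. Bulk read counts at a site are binomial given that fraction; a
   single-cell call is a Bernoulli draw from it.
3. Datasets differ by an additive logit-scale offset (a batch fixed effect)
   that is constant over age within a dataset.
4. Missingness is non-informative: which sites a query covers carries no
   age information.

Assumption 2 is what makes one scoring rule serve both data types: the
log-similarity `ln(1 − |obs − exp| + ε)` of a binary call equals the
(floored) Bernoulli log-likelihood of the observed state, while for a
continuous bulk fraction it is a smooth, strictly decreasing function of
the residual that peaks exactly at a perfect match. Scores are summed over
usable sites and the predicted age is the grid argmax. A log of the raw
absolute difference (without the `1 −`) would *not* work on binary data:
`|b − E|` is the probability of the opposite call, so minimising its log
rewards ages with extreme expected values and drives every binary cell to a
grid edge.

## Pipeline

Training runs: per-(dataset, tissue) QC → cross-dataset candidate filter →
per-dataset Spearman ρ with age → sign-consistency filter and ranking by
|mean ρ| → proximity pruning with backup bookkeeping → per-site binomial
GLM under the three transformations → expected matrix tabulation.

Details worth knowing:

* **QC** keeps sites at ≥5× depth in ≥80% of samples, drops samples missing
  >25% of kept sites, subsets to sites covered in all remaining samples,
  and removes samples beyond mean ± 2 SD on PC1 or PC2 of the methylation
  fractions. Outlier trimming at ±2 SD is not idempotent in general (each
  pass recomputes mean and SD), and with ≤5 samples it can never fire
  (max |z| ≤ (n−1)/√n < 2); QC is meant to run once per raw dataset.
* **Candidate filter**: a dataset "covers" a site if any sample observes
  it; per-dataset missingness is assessed only over covering datasets,
  overall missingness over all samples of all datasets.
* **Pruning** scans in rank order (highest |mean ρ| first); a site within
  5 kb of an already-retained main on the same chromosome with
  Δ|ρ| < 0.1 becomes that main's backup. Greedy-by-rank makes the retained
  set deterministic; rank ties break by (chrom, pos). Backups get their own
  fitted models and expected rows — a substituted backup is scored against
  its own row, since its trajectory, however similar, is not its main's.
* **Pseudo-bulk advisory datasets** (`advisory_ids`) take part in coverage
  counting and the sign filter but are excluded from the ranking mean, so
  non-RRBS evidence can veto a site without steering the selection.
* **GLM**: methylated/unmethylated counts, logit link, dataset fixed effect
  (first dataset alphabetically is the reference at 0). "Best
  transformation" means smallest mean residual deviance — a scale shared
  by the three fits. Observations with fractions but no counts enter with
  an effective total of 1 read (weight-1 pseudo-observations).
* **Expected matrix**: weekly grid over [min observed age − 1, max + 1]
  (lower bound clipped to one step so `ln a` stays defined); each value is
  `σ(β₀ + β₁ T(a) + γ̄)` with γ̄ the unweighted mean dataset effect
  (reference included at 0), so predictions target a typical dataset and
  are invariant to the reference choice. Values are clipped to
  [10⁻⁶, 1 − 10⁻⁶] against separation; rows are monotone in age, with
  plateaus only at the clip bounds.

## Tunable parameters

| parameter | default | unit | why |
|---|---|---|---|
| `n_sites` | 750 | clock sites | cross-validated optimum on the training cohorts; configurable, CV utility included |
| `window_bp` / `delta` | 5000 / 0.1 | bp / \|ρ\| | pruning: nearby sites with near-equal age information are redundant |
| `min_studies` | 2 | datasets | a site seen in one study cannot be checked for batch confounding |
| `max_per_dataset_missing` / `max_overall_missing` | 0.25 / 0.33 | fraction | candidate-site missingness bounds |
| `grid_step` | 1.0 | weeks | weekly resolution; the grid is the hypothesis set of the argmax |
| `epsilon` | 10⁻³ | — | floor inside the log: keeps a single opposite-pole site from dominating (−ln ε bounds its influence) and makes a perfect match a strict maximum |
| `min_sites` | 1 bulk / 40 single-cell | sites | below ~40 covered sites single-cell error grows steeply; the gate flags rather than suppresses (strict mode suppresses) |
| `n_sims` / `alpha` | 1000 / 0.05 | — | deviation-test null size and per-tail level; <100 simulations is refused |
| `k_folds` | 10 | folds | CV default; leave-one-dataset-out offered as `mode="lodo"` |

## Deviation test

The null is conditioned on the exact site set used in scoring the cell
(after backup resolution), so it reflects the cell's own coverage geometry.
Tail fractions use strict inequality; simulated predictions exactly equal
to the real one count toward neither tail. On a 1-week grid ties are
common, and strict tails make each one-sided test *liberal* at the ties'
expense (a tied mass just above the cutoff is excluded from the tail but
included in the flag region); with ~100 covered sites the null prediction
spread is ~10 weeks, the tie mass at the 5% quantiles is small, and the
measured per-tail flag rate stays near the nominal 5% (see
`scripts/acceptance.py`). Two caveats:

* Near the grid boundary the argmax truncates: null predictions pile up on
  the first/last grid age, tails collapse, and flag rates inflate.
  Calibration is therefore assessed at interior ages; verdicts for cells
  whose chronological age sits within a few null-SDs of the grid edge
  should be read with care.
* The two one-sided tests at `alpha` each give a family rate ≈ 2·alpha
  under the null. The test is per-cell; no across-cell multiplicity
  control is applied — that is left to the caller.

All `n_sims` simulations of one cell are drawn from a single generator
seeded with the cell's base seed (simulation *i* consumes the *i*-th block
of the stream), so a (cell, seed) pair reproduces bit-identically. In the
rare case that both tails fall below `alpha` (a pathologically concentrated
null), the more extreme tail wins.

## Synthetic data

The generator emulates exactly the structure of assumptions 1–4: uniform
whole-week ages; a configurable fraction of sites with logit-linear
trajectories under a random transform (slopes scaled so all three
transforms span the same logit range over the cohort ages, keeping effect
sizes comparable); i.i.d. N(0, σ²) dataset offsets; Poisson per-site read
depth with binomial methylated counts; uniform dropout. Single cells are
one Bernoulli read per covered site, either from a bulk sample's observed
fractions (`downsample_to_cell`) or from an expected-matrix column
(`simulate_cohort_cells`), with sites chosen uniformly.

Reference conditions: 2 datasets × 40 samples, ages 3–100 weeks, 2000
candidate CpGs of which 25% age-associated, identity-scale slopes
0.01–0.05 logit/week (≈1–5 logits over the age range), dataset-effect SD
0.5 logits, mean depth 50×, 10% dropout.

What it does **not** emulate — hence what passing tests do not show about
real data: structured (restriction-site and GC-driven) coverage that is
correlated across samples and cells; clustered CpG positions and correlated
methylation within islands; cell-type composition shifts with age;
bisulfite non-conversion and mapping artefacts; non-monotone age
trajectories. In particular, uniform dropout makes the "sites present in
all samples" QC subset far harsher than on real RRBS, where coverage is
strongly correlated across samples — on synthetic cohorts either skip QC
(`--no-qc`) or keep cohorts wide and shallow.

## Numerical choices and degenerate inputs

* Argmax ties (e.g. a fully flat expected matrix) resolve to the youngest
  grid age and the prediction is flagged `degenerate`.
* Sites whose GLM fails to converge under all three transforms are dropped
  with a log entry (`SiteUnusable`); a main site's backups are dropped with
  it rather than promoted, keeping the selection a pure function of the
  ranking.
* Spearman ρ is undefined (missing) under <3 complete pairs or zero
  variance; such sites simply leave that dataset's entry empty.
* A reverse-strand CpG call with no forward partner is reassigned to
  pos − 1 (the CpG context guarantees a forward C one base upstream) with a
  warning, rather than silently dropped.
* Zero-depth coverage rows are dropped at parse time; missing observations
  are NaN throughout, never 0% methylation.
* CV pools held-out pairs over folds before taking the median (one MAE per
  site count); best-count ties go to the smaller count.

## Problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at the
reference conditions above (60 training / 20 held-out bulks, a 750-site
clock), with 200 cells per coverage level in the coverage–accuracy sweep,
1000 null cells × 1000 simulations for calibration, 200 cells per offset
for power, and 100 replicates for GLM recovery — sizes chosen so the whole
suite completes in about a minute on one CPU while keeping Monte-Carlo
error well inside the asserted margins.

## Limitations

* Ages are predicted on the grid only; no continuous interpolation and no
  analytic uncertainty intervals (the deviation test is the calibrated
  alternative).
* The clock is tissue-specific by construction; training mixes tissues
  only via the (dataset, tissue) QC grouping, and a model trained on one
  tissue should not be applied to another.
* Site selection ranks by marginal age correlation; jointly informative
  but marginally weak sites are invisible to it.
* The dataset fixed effect absorbs additive batch shifts only;
  age-by-dataset interactions are not modelled.
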