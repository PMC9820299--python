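# Methods

This note records the models implemented in `wqsource`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Water-quality index engine

The index is the weighted mean of per-parameter sub-indices,
`WQI = Σ Cᵢ Pᵢ / Σ Pᵢ`. Sub-indices come from piecewise-linear breakpoint
curves (concentration → quality score in [0, 100]); beyond the first/last
breakpoint the curve clamps to that breakpoint's value, and non-monotone
curves are supported for range-optimal parameters (pH, water temperature).
Missing measurements are excluded from numerator and denominator alike, so
the index remains a proper weighted mean of whatever was measured.

The shipped default table covers the 14 routinely monitored parameters.
Weights follow the drinking-water-relevance convention of this index
family: trace metals (Fe, Mn), CODMn, NH₃-N and faecal coliform carry
weight 3, dissolved oxygen 4 (it is the single most diagnostic parameter
for aquatic health), and the remaining parameters 1–2. Curve breakpoints
are anchored on the GB3838-2002 class-I–V standards where those exist
(e.g. TN class III = 1.0 mg/L maps near the middle of the scale). These
entries are conventions, not measurements; everything is overridable via a
YAML spec file and no algorithm depends on the particular values.

Grades: Excellent ≥ 91, Good ≥ 71, Moderate ≥ 51, Poor ≥ 26, else Very
poor, applied to the unrounded value. The printed integer bands
(91–100, 71–90, …) leave real-valued gaps; thresholding the unrounded
value preserves the printed bands on integers and totally orders all
reals, so the five grades exactly partition [0, 100].

Screening statistics report per-parameter (overall and per-station) mean,
SD, CV (percent, undefined for zero-mean series) and the fraction of
samples worse than each class threshold in the parameter's harmful
direction (above for pollutants, below for DO).

## Regression forest and feature importance

Trees grow by exhaustive search over candidate thresholds — midpoints
between consecutive distinct sorted feature values — minimizing the
sample-weighted child impurity `(n_left·H_left + n_right·H_right)/N_s`
with the MSE impurity `H`. Leaves predict the training mean. Growth
limits are the standard regression defaults: unlimited depth, ≥ 2 samples
to split, ≥ 1 per leaf. Each split draws a random feature subset of size
`max(1, ⌊m/3⌋)` (the regression-forest convention); each of the 500
default trees trains on an independent bootstrap resample, and the
ensemble predicts the tree mean.

Node importance is the weighted impurity decrease
`n_k = w_k H_k − w_left H_left − w_right H_right` with all weights taken
relative to the tree's total training count — the standard
mean-decrease-impurity convention, which makes the per-tree importances
telescope exactly to (root impurity − leaf-weighted impurity sum).
Per-feature sums are normalized to one per tree and averaged across
trees, so the forest importance vector sums to one whenever any tree
split; a forest of pure leaves reports an explicitly undefined vector
rather than zeros pretending to be information.

Tie-breaking is deterministic: lowest feature index, then lowest
threshold, with scores within `1e-12 + 1e-9·|s|` treated as tied so the
rule is stable under floating-point summation order. Evaluation metrics
(R², MSE, MAE, MAPE in percent) are computed on a held-out split drawn by
uniform random assignment, 9:1 by default; MAPE is flagged undefined when
any true value is zero. Reported sub-model metrics always come from the
test split, and output metadata says so.

## Minimal-parameter surrogates

Parameters are ranked by descending importance (alphabetical on ties, for
determinism). For each subset size k the top-k prefix is refit as a fresh
forest predicting the WQI, scored on the same train/test partition so
rows are comparable. The "feature importance" column is the subset's
summed importance from the all-parameter model (the reading that
reproduces the monotone cumulative pattern; recomputing per sub-model
would not be cumulative). "Comprehensive evaluation" of the ladder is
operationalized as: the smallest subset whose four metrics are all within
a configurable slack of the per-metric best; zero slack returns the
metric-optimal row, and if no row dominates on all four metrics, R²
decides.

## Positive matrix factorization

`X = G F + E` with `G, F ≥ 0`, minimizing `Q = Σ((X − GF)/U)²`.
Uncertainties follow the usual receptor-modelling convention:
`u = sqrt((ef·x)² + (mdl/2)²)` for measured entries (default error
fraction 0.1 per species) and `u = (5/6)·mdl` for below-detection entries
reported as mdl/2. Entries below detection are substituted at mdl/2 by
the censoring step, matching that uncertainty rule.

The optimizer alternates exact nonnegative weighted least-squares solves
for the rows of G and columns of F; each half-step solves its subproblem
to optimality, so Q is non-increasing by construction. Convergence is
declared when the relative drop of Q falls below the tolerance. Defaults:
20 starts, tolerance 1e-8, iteration cap 5000; the pipeline passes a cap
of 400 and tolerance 1e-7, which this optimizer reaches comfortably
(alternating exact solves converge in a few hundred alternations, and the
last decades of the 1e-8 tail change the solution by less than the data
uncertainty). Start 0 is a deterministic nonnegative-double-SVD
initialization on the column-scaled matrix; the remaining starts seed the
profiles from random data rows. Both probe the dominant basin far more
reliably than uniform random factors, which on campaign-scale problems
found it in only a minority of runs; the best-Q start is kept either way.

Solutions are reported canonically: profile rows scaled to unit sum (the
mass lives in G) and factors ordered by total modeled mass, descending.
Species shares `c_ji` are column-normalized modeled mass; species with
zero modeled mass get NaN columns rather than an exception. pH and water
temperature enter the factorization as ordinary columns, as is common
practice for this analysis chain, with the documented caveat that neither
is a mass concentration, so their "source shares" are statistical
associations, not mass apportionment. The factorization runs on pooled
multi-station data with every species weighted "strong" (no
weak/bad down-weighting); run metadata records this. A helper sweep over
candidate factor counts reports Q and Q/dof (dof = nm − p(n+m)). No
rotational tooling is provided; canonical ordering only.

## Apportionment of WQI variation

`p_j = (1 − MAPE) Σᵢ fnᵢ c_ji`, reported in percent with the
all-parameter surrogate's MAPE (consumed as a fraction, reported in
percent) as the closing model-error line, so the table totals 100 %
exactly whenever the importances sum to one and each species column of c
sums to one. Parameters carrying importance but absent from the PMF
species set appear as an explicit "uncovered importance" line instead of
being silently renormalized. Factors are named by dominance rules — a
factor earns a label when its mean share over the rule's species reaches
the threshold (e.g. faecal coliform ≥ 0.6 → microbial contamination;
mean of Fe, Mn shares ≥ 0.6 → heavy metal pollution) — with
"unexplained variability" as the fallback.

## Synthetic monitoring campaigns

The generator emulates a monthly campaign at stations ordered upstream to
downstream. Mass-species concentrations are `X = G F` plus multiplicative
lognormal measurement noise (CV 0.1 by default): concentration data are
positive and right-skewed, and a multiplicative model keeps nonnegativity
without truncation artifacts. Source activities combine a base level, a
seasonal sinusoid (amplitude < 1 so activity stays positive), a
per-station gradient multiplier emulating downstream deterioration, and
per-sample lognormal variability. pH and water temperature are not
source-mass species, so they come from separate bounded processes (AR(1)
around 6.95 clipped to a weakly acidic range; a seasonal sinusoid around
20 °C) and simply appear as two further columns.

The default study conditions plant five sources over the 14 parameters —
microbial (faecal coliform-dominated), diffuse agricultural (TN, NO₃-N,
SO₄²⁻, Cl⁻, F⁻), a natural/seasonal background carrying DO and organics,
an urban nutrient source (TP, NH₃-N), and a heavy-metal source (Fe, Mn)
growing strongly downstream. Profile columns are rescaled so long-run
species means match realistic surface-water targets (e.g. TN 1.54 mg/L,
DO 8 mg/L, faecal coliform 9×10³ colonies/L). Profiles are strongly
dominated (small Dirichlet remainder) and activities vary independently
per sample with per-source CVs (microbial 0.9 — faecal inputs are
episodic — down to 0.25 for the stable background). These choices are
what make the planted structure identifiable: a receptor model can only
resolve sources that vary independently and own distinguishing species;
with near-collinear activities or heavily overlapping profiles, distinct
factorizations fit equally well and no solver could score recovery. A
missing-at-random dropout rate is exposed (default 0: a complete
4 × 107 campaign has 428 samples) since real campaigns rarely state their
completeness.

What the generator does **not** emulate: hydrological routing and
rainfall-runoff dynamics, serial correlation of source activities beyond
the seasonal cycle, correlated censoring, inter-annual trends, laboratory
batch effects, or geochemical speciation. Passing recovery tests
therefore show the chain is correct and well-conditioned under the stated
generative assumptions — not that five sources of this shape exist in any
particular river.

## Problem sizes and numerical choices

Tests and the acceptance script run the chain at the campaign scale the
package targets (428 samples × 14 parameters; 500 trees in the acceptance
script, 40–60 in tests where only ranking behaviour matters; 20 PMF
starts for recovery runs, fewer in toy tests). Degenerate inputs are
contracts, not crashes: constant responses give single-leaf trees,
zero-mean series give undefined CV, zero-modeled-mass species give
undefined share columns, and an all-leaf forest gives an undefined
importance vector. Determinism is end-to-end: every stage's randomness
derives from explicit seeds, and rerunning the pipeline with one seed
reproduces every output file byte for byte (the run manifest therefore
records seeds, settings and input hashes, but no timestamps).

## Known limitations

- The default normalization curves and weights are conventions of this
  WQI family, not fitted quantities; analyses should review them per
  basin.
- Mean-decrease-impurity importance is biased toward high-cardinality
  features and splits importance among correlated ones (Fe and Mn share a
  planted source here); ranks, not values, should be interpreted.
- PMF solutions are unique only up to the identifiability conditions
  discussed above; Q/dof near 1 indicates consistency with the stated
  uncertainties, not proof of the factor count. No bootstrap/displacement
  uncertainty estimation is provided.
- The apportionment inherits both the surrogate's error (explicitly, via
  the MAPE term) and any PMF mis-rotation (implicitly).
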