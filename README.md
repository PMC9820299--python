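# wqsource

Water-quality index scoring, key-parameter selection and pollution-source
apportionment for river monitoring data — a reusable implementation of the
analysis chain commonly applied to multi-year station campaigns: score each
sample with a weighted water-quality index, find the few parameters that
drive the index with a regression forest, resolve latent pollution sources
with positive matrix factorization, and attribute the index's variation to
those sources. A synthetic campaign generator with planted ground truth
makes every stage testable end to end.

It is aimed at environmental data analysts working with routine surface-water
monitoring tables (station × month × parameter concentrations such as pH,
DO, TN, NH₃-N, CODMn, faecal coliform, Fe, Mn, …).

## The methods

**Water quality index.** Each parameter concentration is mapped by a
breakpoint curve onto a sub-index `Cᵢ ∈ [0, 100]` and the index is the
weighted mean

```
WQI = Σᵢ Cᵢ Pᵢ / Σᵢ Pᵢ
```

with small integer weights `Pᵢ` expressing drinking-water relevance.
Scores grade into Excellent (≥ 91), Good (≥ 71), Moderate (≥ 51),
Poor (≥ 26) and Very poor.

**Key-parameter selection.** A regression forest (500 trees by default,
MSE impurity, exhaustive midpoint split search) is trained to predict the
WQI from raw concentrations. Mean-decrease-impurity feature importances
`fnᵢ` (normalized to sum to one) rank the parameters; nested prefix
subsets of the ranking are refit as reduced "WQI_min" surrogates and scored
by R², MSE, MAE and MAPE on a held-out split.

**Source apportionment.** The sample × species matrix is decomposed as
`X = G F + E` with `G ≥ 0` (source contributions) and `F ≥ 0` (source
profiles), minimizing the uncertainty-weighted objective
`Q = Σ (E/U)²` by alternating nonnegative weighted least squares over
multiple starts. The share of species *i* owed to source *j* is
`c_ji = Σₙ G_nj F_ji / Σ_j' Σₙ G_nj' F_j'i` (columns sum to one).

**Attribution of WQI variation.** Importances and source shares combine,
with the surrogate model's error as a correction factor, into per-source
percentages

```
p_j = (1 − MAPE) × Σᵢ fnᵢ c_ji
```

so that `Σ_j p_j + MAPE = 100 %` exactly.

## Worked example

Scoring a single sample:

```python
import wqsource as wq

specs = wq.default_specs()
record = {"pH": 6.9, "WT": 21.0, "DO": 8.2, "TN": 1.6, "NH3-N": 0.21,
          "NO3-N": 0.85, "TP": 0.07, "CODMn": 2.1, "Cl": 11.0, "SO4": 14.0,
          "F.coli": 12000.0, "Fe": 1.8, "Mn": 0.55, "F": 0.24}
res = wq.compute_wqi(record, specs)
print(res.value, res.grade)        # 71.8 Good
print(res.sub_indices["Mn"])       # 28.0  (0.55 mg/L Mn is a poor sub-score)
```

The full chain on a simulated 4-station × 107-month campaign:

```
$ wqsource run-all -o demo --seed 7 --n-trees 60 --pmf-starts 4
chosen parameters: Fe + Mn + WT + CODMn + F.coli
artifacts in demo
```

`demo/selection.csv` then holds the incremental surrogate ladder — test R²
climbs from 0.01 (Fe + Mn alone) through 0.68, 0.77, 0.85 to 0.95 for the
all-parameter reference — and `demo/apportionment.csv` the source
accounting, e.g.

```
source,contribution_percent
heavy metal pollution,35.13
unexplained variability,22.42
non-point source agricultural pollution,17.42
nutrient contamination,14.74
microbial contamination,9.22
model error,1.07
```

which totals 100 % by construction. Stage-wise subcommands
(`simulate`, `wqi`, `train`, `select`, `pmf`, `apportion`) operate on each
other's files; `wqsource write-specs` exports the editable parameter
table (weights, curves, class standards, detection limits).

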