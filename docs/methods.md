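# Methods

This note records the models implemented, the choices made where the
standard methods leave freedom, and what the synthetic-data experiments do
and do not demonstrate.

## Data model

One record per (district, year): land area (km²), older-population
coefficient (% of permanent residents aged 60+), older-population density
(persons 60+/km²), optional per-capita disposable income (yuan),
per-thousand care-resource indicators, and optional composite demand and
resource scores in [0, 1]. Optional values are represented as absent, never
as zero, so share-based statistics are not silently distorted. District
labels are matched case-insensitively after trimming; the packaged tables
canonicalize one inconsistently printed district name ("Zengchen" →
"Zengcheng"). All packaged table values are stored exactly as printed
(4-decimal fidelity) and never re-derived.

Spatial weights are supplied, not derived from geometry: GAL files (both the
bare-count and the GeoDa 4-token header) or an undirected 3-column edge
list, which produce identical matrices for the same graph. Weights must be
nonnegative with a zero diagonal.

## Entropy-weight composites

The entropy weight method is used in its canonical form: per-column min-max
normalization (benefit columns ascending, cost columns reversed), a
positivity offset ε (default 1e-4) added so ln 0 never occurs, Shannon
entropy of the column shares, and weights proportional to the information
content 1 − e_j. Constant columns carry no information and receive weight 0;
if every column is constant the weights fall back to uniform. Composite
scores are weighted sums of the normalized cells.

Choices left open by the method and resolved here:

* **Normalization + aggregation.** Min-max plus weighted sum, the textbook
  formulation. A distance-based aggregation (TOPSIS-like) would also be
  defensible; the weighted sum is simpler and monotone in every benefit
  indicator.
* **Offset.** ε = 1e-4, configurable. Published composite tables bottom out
  at exactly 0.0001, consistent with this convention.
* **Pooling.** Weights are computed per year (cross-section) by default,
  since published scores are reported per year without a stated pooling
  rule; a pooled-panel mode (normalize over all district-years, CLI flag
  `--pooled`) is provided.
* **Orientation.** All aging/resource indicators default to benefit
  (higher = more demand / more resources), overridable per column.

Raw indicator data behind the published composite scores are not printed in
the source tables, so those composites are consumed as inputs; the entropy
module is validated on closed-form cases and synthetic panels (weights sum
to one, permutation equivariance, scale invariance, monotonicity, ranking
recovery of a monotone latent).

## Spatial autocorrelation

Global Moran's I uses the standard cross-product form. (The source's
display equation omits the w_ij(x_i−x̄)(x_j−x̄) cross-product from the
numerator; its own verbal description and [−1, 1] range identify the
standard statistic, which is what is implemented.) E(I) = −1/(n−1) and the
Cliff–Ord closed-form variances under both the normality and the
randomization (kurtosis-corrected) assumptions are provided; randomization
is the default, as it conditions on the observed values.

Inference conventions:

* **Tail.** One-tailed upper p-values by default — the substantive
  hypothesis in aging-concentration studies is positive clustering —
  with `less`, `two-sided` and an adaptive `auto` tail selectable. The
  adaptive tail is deliberately *not* the default: choosing the tail from
  the observed statistic doubles the null rejection rate and would break
  the size calibration below.
* **Permutation rule.** p = (1 + count)/(n_perm + 1), the add-one rule that
  makes the test exact-in-distribution. Default n_perm = 999, default seed
  20150101; every simulation consumes an explicit seed.
* **Local Moran.** I_i = (d_i/m2) Σ_j w_ij d_j with m2 = Σd²/n on
  row-standardized weights, so Σ_i I_i = n·I_global holds as an identity
  (checked numerically). Significance by conditional permutation (hold i,
  permute the rest into its neighbor slots). Cluster labels: significant
  HH = hot, LL = cold, HL/LH = outliers.
* **Gi\*.** Self-included star convention. A constant attribute is returned
  as all-zero scores (the 0/0 limit) rather than an error: a flat field has
  no hot spots.

The published Moran's I values for the study region are not reproducible —
the spatial weight matrix used there is unpublished, and the printed
p-values match neither a one- nor a two-tailed normal tail — so validation
is by construction: exact equivalence with a naive O(n²) double-loop oracle
on all small graphs, an independently coded moment oracle for the Z test,
permutation size within [0.03, 0.07] at nominal 0.05, and power ≥ 80%
against a SAR alternative at ρ = 0.8 on a 7×7 lattice. The replication-style
default for user data is a queen-contiguity binary matrix, row-standardized,
and any supplied GAL/edge-list matrix is accepted.

## Concentration, RI and the typology

R_i = (v_i/Σv)/(ter_i/Σter) is share-based, hence invariant to rescaling
all values, and satisfies Σ_i areaShare_i·R_i = 1 exactly (tested at 1e-9).
RI_i = Rdemand_i/Rres_i; classification uses the printed inequalities with
both boundaries coordinated: RI < 1 ahead, 1 ≤ RI ≤ 3 coordinated, RI > 3
lagging. Zero resource concentration with positive demand yields RI = +∞
(classified lagging, with a warning); 0/0 is flagged undefined and excluded
from classification. Printed tables are rendered at 4 decimals, rounded
half-away-from-zero; internal computation is full precision.

Two quirks of the published tables are handled explicitly:

* The published **resource-concentration column does not follow the
  share-ratio formula** applied to its own printed resource scores and
  areas (e.g. Conghua prints 1.6593 where the formula gives ≈ 0.29). The
  demand column does follow the formula exactly. The pipeline implements
  the formula as defined and additionally accepts externally supplied
  concentration columns, which is how the published RI and typology are
  reproduced; no guess is made about how the published resource column was
  produced.
* The **density classifier** places 80 persons/km² in the medium band. The
  verbal band definition reads "80 to 100 → relatively high", but the
  study's own worked classification assigns a district at exactly 80 to
  medium; the worked classification wins, documented as a quirk. Aging
  stages use half-open bands [0,5), [5,7), [7,10), [10,14), [14,∞).

Recomputing RI from 4-decimal printed concentration columns can only agree
with the printed RI within the propagated half-ulp bound
(5e-5/Rlog + 5e-5/Rres relative); for districts whose printed resource
concentration is as small as 0.0005 that bound is ~10%, so those quotients
are checked against that bound rather than a fixed tolerance.

## Association

Simple product-moment correlation with the two-tailed t test (n−2 df) and a
least-squares line; r² = r² by construction. No outlier handling (the
published analysis retained its extreme district); a log-scale option exists
for exploration. Of the published pair (r = −0.4146, R² = 0.1734), the two
are mutually inconsistent ((−0.4146)² = 0.1719) while recomputation gives
r ≈ −0.4164 with square 0.1734, so R² is the checkable figure.

## Synthetic panels

The generator emulates the structure the analysis assumes:

* **Graph.** Rook-lattice, ring, or connected random-geometric adjacency
  (mean degree ≈ 5), binary symmetric.
* **Aging field.** SAR process x = μ + (I − ρW_rs)⁻¹ε, ε ~ N(0,1), affinely
  mapped into [5, 35]%; ρ ∈ (−1, 1) is admissible for row-standardized
  weights. Default ρ = 0.5 (clear positive clustering).
* **Areas.** Lognormal, drawn once per panel (areas are time-invariant);
  defaults (log-mean 5.8, log-sd 1.3) give a median ≈ 330 km² spanning
  about two orders of magnitude, like the study region's 33.8–1974.5 km².
* **Core–periphery.** The core_fraction (default 0.3) of districts around
  the best-connected node receives the smallest areas; populations are
  comparable across districts, so older-population density — and with it
  demand — peaks in the small-area core. demand_score is the min-max
  normalized log density.
* **Mismatch.** resource_score = α − β·demand + N(0, noise_sd), clipped to
  (0, 1], with α = 0.7 and β = mismatch_beta (default 0.5, i.e. resources
  deployed away from demand, as observed empirically). Ground-truth labels
  apply the concentration/RI pipeline to the noiseless fields, so truth is
  self-consistent by construction.
* Defaults: n = 11 districts, noise_sd = 0.05, seed 20150101; one seeded
  generator per call, no global state.

What the synthetic experiments show — and do not:

* **Typology recovery** (≥ 95% agreement at noise_sd = 0.02, n = 50, 100
  seeds) shows the pipeline's classification is stable under small
  measurement noise away from the RI = 1 and RI = 3 boundaries. Real
  composite-score uncertainty may be larger and spatially correlated.
* **Correlation recovery** (sign of the demand–resource concentration
  correlation equals −sign(β)) is demonstrated at modest area heterogeneity
  (area log-sd 0.2). At the default two-orders-of-magnitude area spread the
  property cannot hold: both concentration indices share a 1/areaShare
  factor whose variation dwarfs the bounded (0, 1] scores, forcing a
  positive raw-value Pearson regardless of β. This is a real caveat for
  interpreting raw-value correlations of concentration indices, not merely
  a generator artifact.
* The generator is cross-sectional (no births/deaths/migration dynamics)
  and does not emulate reporting error in areas or populations.

## Problem sizes and runtimes

The calibration experiments use a 7×7 rook lattice with 199-permutation
tests (1000 null replicates for size, 200 SAR replicates for power) and
50-district panels over 100 seeds for typology recovery; permutation
batches are vectorized (one matrix product per batch), so the full test
suite completes in a few seconds on one CPU.

## Known limitations

* The published global Moran's I table is not reproducible without the
  original weight matrix; the package documents its own values alongside
  the printed ones without asserting equality.
* Published composite-score tables are consumed as data because the raw
  indicator values behind them are unpublished.
* No geometry handling: contiguity must be supplied as GAL/edge list, and
  no choropleth rendering is provided — outputs are tables suitable for
  external GIS.
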