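# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `spatialtma`. It is the package's own account of its science;
every empirical statement here is computed by the test suite or by
`scripts/acceptance.py`.

## Synthetic TMA cohort model

The generator emulates the structure of a tissue-microarray study of solid
tumors: `n_patients` patients each contribute `cores_per_patient` (default 2,
"duplicate cores") circular cores of radius `core_radius` (default 0.3 mm,
i.e. a typical 0.6 mm TMA core; the value is configurable because real
designs vary).

**Geometry.** Each core contains `n_nests` epithelial "tumor nests": discs
with radii drawn uniformly from `nest_radius_range` (default 0.05–0.12 mm)
and centres placed uniformly such that each nest lies inside the core.
Compartment membership is a pure point-in-disc test; the epithelial area is
the area of the nest union (computed with shapely disc polygons at 256
segments per quarter circle, relative error < 1e-5) and the stromal area is
defined as the disc area minus the epithelial area, so the two compartments
sum to the core area *exactly* — the same areas are the denominators of all
density computations (geometry conservation).

**Cells.** Background cells follow a homogeneous Poisson process per
compartment: counts ~ Poisson(intensity × area), positions uniform by
rejection sampling. Defaults of 2500 (epithelium) and 1500 (stroma)
cells/mm² are order-of-magnitude choices for nucleated-cell densities in
FFPE carcinoma sections; no published per-compartment densities exist for
the motivating cohort, so both remain configurable, and the scaled-down
cohorts used in long-running tests use lower intensities (350–900 cells/mm²)
purely to bound runtime. No hard-core repulsion is modelled: neighborhood
detection depends on composition, not on sub-cellular spacing. Phenotypes
are drawn i.i.d. from per-compartment mixtures; the default epithelial
mixture is 88% tumor (PanCK) cells, the default stromal mixture is
immune-rich with all eight immune classes represented, matching the
qualitative observation that immune cells are denser in stroma.

**Hotspots (planted neighborhoods).** Each hotspot places `cell_count` cells
uniformly in a disc of radius `radius` (default 0.05 mm) around an anchor:
a random point on a random nest boundary (default — CD16a⁺ aggregates
concentrate at the stroma/epithelium junction), a random stromal or
epithelial point, or a fixed (x, y) used by tests to build well-separated
archetypes. Hotspot cells carry their own phenotype composition and a
ground-truth hotspot id; their compartment is decided by their sampled
position, never by hotspot membership, so compartment stays purely
geometric. The per-patient planted coverage recorded in the ground truth is
the mean over the patient's cores of the hotspot-cell fraction, an exact
bookkeeping identity tested to 1e-12. An optional per-patient uniform
multiplier on hotspot cell counts (`patient_hotspot_scale`) creates
between-patient coverage variance when a coverage–survival effect is
planted; it defaults to off.

**Marker signals.** Every cell gets binary positivity calls consistent with
its phenotype (CD94 additionally appears as a Bernoulli(0.3) modifier on
myeloid and T cells, mirroring its role as a recorded attribute rather than
a class). For exercising the clustering route, `marker_intensities` draws
two-component lognormal signals (positive component LogNormal(2.5, 0.25),
negative LogNormal(0.3, 0.25)); continuous-signal realism beyond this
two-component model (spectral bleed-through, segmentation errors, spatial
intensity gradients) is deliberately out of scope, so clustering-route
results on synthetic data are an upper bound on real-data performance.

**Survival.** Event times are exponential with hazard h₀·exp(Xβ); the
coefficient dictionary may reference clinical covariates (age per year,
binary stage/debulking/chemo-sensitivity, grade-3 indicator) and
planted-coverage terms (continuous total coverage, or the above-cohort-mean
indicator). Censoring is uniform on a window (default 0–120 months);
OS and PFS use separate baseline hazards (defaults 0.015 and 0.030 /month).
Richer baselines (Weibull, piecewise) and dependent censoring are
non-goals. A zero-width censoring window is permitted but flagged
degenerate.

**Randomness.** One master seed; every consumer draws from a named
`SeedSequence` substream keyed by (stage, patient index, core index), so
cohorts are bit-reproducible and insensitive to generation order.

## Phenotyping

Gating is an ordered list of first-match-wins rules ending in a catch-all,
which makes it a total function on binary marker vectors (verified by
exhaustive enumeration: 32 combinations for the 5-marker panel, 128 for the
7-marker panel). The 5-marker hierarchy: panCK⁺ → epithelial regardless of
other markers; then CD68 (myeloid), CD3 (T), CD94 (NK), CD16a single
positives; all-negative → Other. CD16a splits the myeloid/T/NK classes into
CD16a⁻/CD16a⁺ variants because those variants are analyzed separately
downstream; CD94 on myeloid/T cells is stored as a boolean attribute only.
The 7-marker panel adds CD163 as a myeloid split and CD8 as a T-cell split,
with CD163 and CD8 single-positive classes gated after the NK/CD16a rules;
this ordering is config-driven since only the output categories, not the
rule order, are fixed by convention.

The clustering route log-normalizes signals (log(1+x), monotone and defined
at zero), k-means clusters them (k-means++ init, best of 10 restarts,
unscaled features), picks the cluster count at the knee of the inertia
curve — the point of maximum distance to the chord between the curve's
endpoints after normalizing both axes to [0, 1]; flat curves fall back to
the smallest candidate — and thresholds each cluster's mean signal into a
binary vector that is gated as above. Default thresholds are per-marker
Otsu on the normalized signal, re-centred between the nearest samples on
either side of the Otsu cut (when two components are separated by an empty
gap, all cuts in the gap tie on the Otsu objective and the histogram argmax
sits at the gap's lower edge, which misclassifies upper-tail negatives);
thresholds can be overridden per marker. A marker with no true positive
population can still defeat any automatic threshold — a known limitation of
threshold-based gating, which is why explicit thresholds win over defaults.

## Neighbor profiles and cellular neighborhoods

For each cell, the k nearest neighbors by Euclidean distance on the X/Y
coordinates are found within the same core only (neighbor search never
crosses cores), the cell itself excluded. Ties at equal distance are broken
by cell id, making profiles fully deterministic; the implementation uses a
tree-based search with an exact full-distance re-resolution of any row whose
k-th and (k+1)-th candidate distances tie (and of rows with coincident
points), and is tested for exact equality against a brute-force
distance-matrix oracle, including on integer lattices where ties are dense.
Cores with fewer than k+1 cells are excluded entirely and logged — a
deflated neighbor count would bias the clustering — and profiles are counts
over phenotype × compartment categories (E_/S_ prefixes), because stromal
and epithelial variants of one phenotype form distinct neighborhoods; a
phenotype-only mode exists for comparison. Features are raw counts, not
frequencies: at fixed k the two differ only by scale.

Neighborhoods are k-means clusters (k-means++, best of 10 restarts,
deterministic given the seed; a MiniBatchKMeans backend is available for
very large cohorts) of the profiles pooled across the whole cohort — one
model per cohort, so labels and coverages are comparable across patients.
Composition is summarized as the mean neighbor count per category within
each neighborhood, z-scored per category across neighborhoods (population
sd; zero-sd categories get z = 0, so column means of z-scores are 0 by
construction). With n = 1 the z-scores are undefined and the raw means are
returned flagged degenerate.

**Choosing (k, n).** The diagnostic grid (defaults k ∈ {5, 10, 15, 20},
n ∈ {5…10}) fits every combination and reports, per model, the number of
"highly similar" centroid pairs (cosine ≥ 0.95 by default — the cutoff for
calling two neighborhoods redundant is a judgment call and configurable)
and whether refitting at (k, n−1) merges two previously distinct
neighborhoods, detected as a best-match collision: two of the n-model's
centroids sharing the same most-similar centroid in the (n−1)-model. The
recommendation is the largest n (then smallest k) that is flag-free and
whose n−1 refit merges — i.e. grow n until just before clusters start
splitting into near-duplicates. "Clusters of interest" is ultimately
observer-defined, so the recommendation is advisory and the chosen (k, n)
remains a config value.

**Naming.** Neighborhoods are named by rules over their composition: immune
fraction (non-PanCK, non-Other share of mean neighbor counts) below 0.2 →
"cold epithelium"/"cold stroma" by dominant compartment; top enriched
category a CD16a class → "CD16a enriched ⟨compartment⟩"; the rest ranked by
total immune enrichment into one "immune-rich" and "immune-moderate"
neighborhoods. Manual overrides always win; empty neighborhoods keep the
fallback "N⟨i⟩". Duplicated names are disambiguated with a numeric suffix.

**Coverage.** Per-core coverage is the fraction of that core's profiled
cells in each neighborhood (rows sum to 1 exactly); patient coverage is the
unweighted mean over the patient's non-excluded cores, matching the
averaging of duplicate cores used for densities. Coverage ratios with a
zero denominator are missing (never infinite), with the count logged.

## Statistics layer

* **Densities**: counts / compartment area per core, averaged over the
  patient's valid cores; zero cells is density 0, zero area with cells
  present skips the core compartment with a log entry.
* **Dichotomization**: median and mean splits put ties low (high = strictly
  above the statistic); quartile mode labels only Q1 (≤ first quartile) and
  Q4 (> third quartile), middle half missing. All-identical values are a
  flagged degenerate split. Whether ties at the median should go high or low
  is not determined by convention; low was chosen for determinism and is
  documented rather than argued.
* **Cox models**: partial likelihood with Breslow tie handling (statsmodels
  PHReg), five-year horizon as administrative censoring at 60 months
  (min(t, 60), events after 60 → censored), HR = exp(β̂) with Wald 95% CIs.
  Age is coded continuously per year. Zero events after truncation yields a
  missing, logged result; monotone likelihood (separation) is flagged
  `ci_unreliable` rather than reported as a finite CI. The multivariate
  model contains the variables whose univariate BH-adjusted p < 0.05
  (configurable; `None` takes all), with rank-deficient columns dropped and
  warned. Proportional-hazards diagnostics, competing risks and
  time-varying covariates are out of scope.
* **FDR**: "fdr" means Benjamini–Hochberg step-up, the standard `fdr`
  alias; no other variant is supported. Verified against the hand-applied
  step-up formula.
* **Correlation**: pairwise-complete Pearson with a minimum of 3 complete
  pairs; zero-variance variables have missing rows/columns.
* **ANOVA**: one-way via the between/within mean-square ratio; two-way with
  type-II sums of squares and interaction; a family of contrasts is
  BH-adjusted together, with empty/singleton contrasts missing rather than
  fatal.
* **Kaplan–Meier**: product-limit estimator (lifelines), truncated at the
  horizon, with risk tables.

## Problem sizes used in tests

Property checks run at sizes chosen to make their statistical claims sharp
while keeping the suite practical on one CPU: kNN-oracle equivalence on 10
cores of 300–2000 cells; planted-archetype recovery on 40 patients × 2
cores with three 120-cell archetypes over 10 seeds; Cox calibration over
200 replicates of 800 patients (binary covariate, true HR 0.75, ~30%
censoring from a uniform 0–120-month window at h₀ = 0.03/month);
end-to-end power over 20 effect replicates (600 patients, planted HR 0.7 on
the above-mean-coverage indicator) and 20 null replicates. The end-to-end
cohorts use reduced cell intensities (≈150 cells/core) — coverage fractions,
not absolute counts, drive the analysis, so the power property is unchanged.

## Known limitations

* The generator plants composition structure but not realistic spatial
  texture (no cell-size exclusion, no intensity images, no segmentation
  error); passing tests demonstrate correctness of the analysis chain, not
  robustness to upstream imaging artifacts.
* Neighborhood names are heuristics over composition summaries; on cohorts
  unlike the motivating tumor type the rules may produce generic names, and
  overrides are the intended escape hatch.
* The (k, n) recommendation inherits k-means instability near merge points;
  it is advisory by design.
* Quartile-mode Cox contrasts discard the middle half of patients, halving
  the effective sample size; this mirrors the analysis convention it
  implements rather than a statistical recommendation.
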