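# spatialtma

Spatial immune-neighborhood analysis of tissue-microarray (TMA) cell tables,
for tumor-immunology groups working with multiplex-immunofluorescence digital
pathology exports — in particular studies of the high-grade serous ovarian
carcinoma (HGSC) microenvironment, where the local co-organization of CD16a+
cells, macrophages, T cells and NK cells into "cellular neighborhoods" is
prognostic.

The package takes a per-cell segmentation export (cell id, core, patient, X/Y
coordinates, epithelium/stroma compartment, marker signals or positivity
calls) plus a patient-level clinical table, and runs the full chain:

1. **Phenotyping** — either direct gating of binary marker calls through an
   ordered, first-match-wins hierarchy (panCK⁺ → epithelial regardless of
   other markers; then CD68, CD3, CD94, CD16a classes with CD16a splitting
   each lineage; all-negative → Other), or log-normalization → k-means
   expression clustering with elbow selection → thresholding of cluster
   means → the same gating.
2. **Neighbor profiles** — for each cell, the phenotype × compartment counts
   of its *k* nearest neighbors (Euclidean, within the same core, self
   excluded; default k = 15).
3. **Cellular neighborhoods** — k-means over the pooled count profiles into
   *n* neighborhoods (default grid n = 5…10), with composition z-score
   heatmaps, centroid cosine-similarity diagnostics for choosing (k, n), and
   rule-based names ("cold epithelium", "CD16a enriched stroma", …).
4. **Coverage & ratios** — per-core and per-patient neighborhood coverage
   fractions (duplicate cores averaged) and coverage ratios such as CD16a
   enriched stroma : cold epithelium.
5. **Cohort statistics** — compartment densities (cells/mm²),
   median/mean/quartile dichotomization, univariate and multivariate Cox
   proportional-hazards models at a five-year horizon (administrative
   censoring at 60 months, Breslow ties, Wald 95% CIs), Benjamini–Hochberg
   FDR, Pearson co-infiltration matrices, one/two-way ANOVA, and
   Kaplan–Meier curves.

Because cohorts of this kind are rarely public, the package ships a
first-class **synthetic cohort generator**: duplicate ~0.6 mm cores per
patient, epithelial nests in stroma with analytic compartment areas,
homogeneous Poisson cell placement with per-compartment phenotype mixtures,
planted CD16a⁺ hotspots at nest boundaries, and exponential
proportional-hazards survival times whose linear predictor can include the
planted neighborhood coverage — so every downstream stage is testable
against known ground truth.

## Worked example

```python
import pandas as pd
import spatialtma as s

cfg = s.SimulationConfig(n_patients=40, seed=11)
cohort = s.simulate_cohort(cfg)
cells = pd.concat([cohort.cells, s.assign_phenotypes(cohort.cells)], axis=1)

pset = s.neighbor_profiles(cells, k=15)
model = s.cluster_neighborhoods(pset, n=6, seed=11)
comp = s.neighborhood_composition(model, pset)
model.names = s.annotate_neighborhoods(comp)
cov = s.coverage(model, pset)

cd16 = [i for i, v in model.names.items() if v.startswith("CD16a enriched")]
value = cov.patient[cd16].sum(axis=1)
grp = s.dichotomize(value, "mean")
clin = cohort.patients.set_index("patient_id").loc[value.index]
r = s.cox_univariate(grp.labels, clin["os_months"], clin["os_event"],
                     variable="CD16a-enriched coverage")
```

This prints (numbers from the code above, seed 11):

```
51107 cells, 80 cores, 40 patients
neighborhoods: {2: 'CD16a enriched epithelium', 3: 'cold epithelium',
                5: 'CD16a enriched stroma', 4: 'immune-rich',
                1: 'immune-moderate (2)', 0: 'immune-moderate'}
OS HR (high vs low CD16a-enriched coverage): 0.396 [0.154, 1.017],
p=0.054, n=40, events=22
```

Reading: the six annotated neighborhoods mirror the canonical HGSC
configuration (two immune-cold compartment-pure neighborhoods, two CD16a
enriched ones, two graded immune neighborhoods). Patients whose tumors carry
above-mean coverage by CD16a-enriched neighborhoods show a hazard ratio
below 1 for five-year overall survival — the direction expected when CD16a⁺
neighborhoods are protective — though at 40 patients the CI still touches 1.

## Command line

Every stage is also a CLI subcommand driven by one YAML config:

```bash
spatialtma run --config run.yaml --seed 7
```

```yaml
# run.yaml
simulate: {n_patients: 100}   # or cells_path/clinical_path for real exports
k: 15
n: 6
split_mode: mean
out_dir: my_run
seed: 7
```

`spatialtma simulate|phenotype|neighborhoods|stats|run --config … --out …
--seed …` write their CSV outputs (cell tables, profiles, labels, coverage,
composition, similarity, survival results, correlation and ANOVA tables), a
manifest with a config hash, a run log recording every exclusion, and
best-effort figures (composition heatmap, reconstructed cores, forest and
KM plots).

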