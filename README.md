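# fibroscape

A toolkit for population-level analysis of fibroblast heterogeneity in
single-cell and bulk transcriptomics, built around the computational
procedures used to characterise lung fibroblast subpopulations
(adventitial, alveolar and myofibroblast) across healthy and NSCLC tissue:

* **Stromal demarcation** — binned-control gene-module scores for
  fibroblast and mural-cell signatures, and the score-difference rule
  `fibroblast if s_fib − s_mural > 0.1 and s_fib > 0` (symmetric for mural
  cells; ambiguous cells stay unassigned).
* **Batch-effect QC** — the kNN-overlap z-score
  `z = (nOverlap − x̄_random) / σ_random`, where the null pools per-cell
  overlaps of random cell subsets of matched size; a patient/dataset group
  is flagged when its median z exceeds 1.96.
* **Sample-level marker validation** — per-(sample, cluster) pseudo-sample
  profiles, exact Wilcoxon tests across samples with Bonferroni
  adjustment, and the marker criterion *sample-level average log2FC > 1,
  adj. P < 0.01, expressed in ≥ 50 % of samples*; plus the
  clustering-resolution sweep that keeps the finest SNN/Leiden solution in
  which every cluster retains supported markers.
* **Trajectory meta-analysis** — diffusion maps with a locally adaptive
  density-normalised kernel, diffusion pseudotime with automatic tip
  selection and branch assignment, per-gene loess regression on pseudotime
  (approximate F-test), Stouffer combination of per-dataset p-values
  (`Z = Σ Φ⁻¹(1−p_d)/√D`), and consensus gene modules from Ward clustering
  on `1 − r` between median fitted profiles — named progenitor,
  early-activation, proto-differentiation and differentiation by peak
  order.
* **Deconvolution benchmarking** — signature-matrix construction with
  per-type downsampling, pseudobulk mixtures with known composition
  (1000 cells from 3 patients, 1–50 % fibroblast content), non-negative
  least squares scoring, and R² evaluation against truth.
* **Survival stratification** — maximally selected log-rank cutpoints
  (signed standardized statistic `U/√Var` over all admissible splits) and
  Cox proportional-hazards models (Efron/Breslow ties, optional 4-year
  administrative censoring horizon).
* **Histo-cytometry rules** — 8-bit pseudo-immunofluorescence conversion
  (`min(256, ⌈v/1.5·256⌉)`), 151×151 moving-average background subtraction
  with the red/brown chromogen guard, and the marker-argmax stromal
  classification (ACTA2/POSTN → myofibroblast, AOC3 → alveolar,
  CD34 → adventitial, after excluding PanCK/CD31/MCAM-positive cells).

Every stage is exercised end-to-end on synthetic data with planted ground
truth: negative-binomial counts with per-patient batch effects, planted
cell-type signatures, a bifurcating differentiation trajectory with four
temporally ordered gene modules, pseudobulk mixtures with known fractions,
and survival cohorts with a planted hazard ratio.

## Worked example

Simulate a cohort with planted fibroblast/mural identities, score both
signatures and demarcate:

```python
import fibroscape as fs
from fibroscape.containers import GeneSet

cfg = fs.CohortConfig(
    n_patients=12, cells_per_patient=500, n_genes=2000,
    cell_type_spec=[fs.CellTypeSpec("fibroblast", 0.6, 30, 1.5),
                    fs.CellTypeSpec("mural", 0.4, 30, 1.5)],
    seed=1,
)
cm = fs.generate_cohort(cfg)
sig = cm.uns["signature_genes"]          # planted truth
fib = fs.score_gene_module(cm, GeneSet("fibroblast", sig["fibroblast"]), seed=0)
mur = fs.score_gene_module(cm, GeneSet("mural", sig["mural"]), seed=1)
labels = fs.classify_stromal(fib, mur)   # margin 0.1, floor 0
print(labels.value_counts())
acc = (labels.to_numpy() == cm.cell_meta["true_type"].to_numpy()).mean()
print(f"accuracy vs planted labels: {acc:.3f}")
```

Output:

```
fibroblast    3600
mural         2400
Name: count, dtype: int64
accuracy vs planted labels: 1.000
```

The scores place each cell on the fibroblast-vs-mural axis; the
demarcation rule then reproduces the planted identity of all 6000 cells —
on real data the same rule separates fibroblasts from ACTA2-high mural
cells before any subpopulation analysis.

The same API drives the other stages, e.g.

```python
graph = fs.build_neighbor_graph(cm, k=20)
report = fs.knn_overlap_zscores(graph, cm.cell_meta["patient_id"], n_random=1000)
print(report.groups)        # group_id, n_cells, median_z, flagged
```

A thin CLI mirrors the main entry points:

```bash
fibroscape simulate cohort --out sim/ --seed 1
fibroscape demarcate --counts sim/ --fib-set fib.txt --mural-set mural.txt --out labels.csv
fibroscape survival sweep --records cohort.csv --score-col myo_pct --out sweep.csv
```

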