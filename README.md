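# dendroprov

Tree-ring analysis for provenance trials: do seed-origin populations
(provenances) of a tree species keep their distinctive growth patterns when
planted in a common garden — and does that differentiation survive on a
climatically marginal site?

The package is written for dendroecologists and forest geneticists working
with replicated provenance trials. It implements the full analysis chain on
standard inputs (Tucson/RWL ring widths, monthly climate CSVs) and ships a
synthetic two-site trial generator with known ground truth, so every
statistical property of the chain is testable without field data.

## What it computes

* **Chronology building** — cubic smoothing-spline detrending with a 50%
  frequency cutoff at 30 years (index = width / curve), AR(1) prewhitening,
  Tukey biweight mean chronologies per provenance × site, and the standard
  descriptive statistics: Gleichläufigkeit (glk), mean sensitivity (MS) and
  mean inter-series correlation (rbar).
* **Drought and climate indices** — FAO-56 extraterrestrial radiation,
  Hargreaves potential evapotranspiration
  `PET = 0.408 · 0.0023 (T_mean + 17.8) √(T_max − T_min) · R_a`,
  climatic water balance `CWB = P − PET`, SPEI-3/SPEI-6 (log-logistic fitted
  per calendar month by unbiased probability-weighted moments), a pluggable
  annual aridity index, and the 19 bioclim variables from monthly normals.
  PDSI is accepted as an external series, never computed.
* **Pairwise PCGA** — principal component gradient analysis: trees are
  ordered by the polar angle of their loadings on the first two PCs of the
  ring-index matrix; for every provenance pair a separate two-group PCGA is
  run and the gradient ranks compared with a Wilcoxon rank-sum test, giving
  a provenance × provenance p-value matrix and a scalar differentiation
  score (fraction of pairs with p < α).
* **Pointer years** — Cropper values in 5-year moving windows, Neuwirth
  intensity classes (|C| > 1 / 1.28 / 1.645), 65% series threshold per
  provenance, and common pointer years (≥ 6 of 10 provenances agreeing).
* **Grouping and ordination** — Euclidean-distance hierarchical clustering
  of chronologies (single/complete/UPGMA/Ward, linkage selected by the
  agglomerative coefficient, cluster count by the Mojena rule) and a
  standardized PCA of bioclim vectors.
* **Simulation** — monthly site climate (gamma precipitation, Gaussian
  temperature anomalies, drought years) and ring widths per tree:
  age trend × exp(climate signal), where a *marginality* parameter m blends
  each provenance's own response with a shared water-balance signal and caps
  growth Liebig-style. m = 0: provenances differentiate freely; m = 1: every
  tree rides the same limiting factor.

## Worked example

```
python analysis/01_simulate_trial.py --seed 1
python analysis/02_run_pipeline.py
```

prints (seed 1):

```
MOIST: 150 trees, differentiation score 0.911, 5 common pointer years, aridity 32.5
DRY: 150 trees, differentiation score 0.022, 4 common pointer years, aridity 22.6
clustering: Ward selected (AC 0.938), Mojena k = 2
```

Both simulated sites hold the same ten provenances, but the mild site
(marginality 0.1) separates 91% of provenance pairs by their growth
patterns while the water-limited site (marginality 0.9) separates 2%:
between-provenance differentiation collapses where a single limiting factor
dominates. The chronology dendrogram splits by site before provenance
(Mojena k = 2), mirroring the site-first grouping typical of real trials.
The sweep in `analysis/03_marginality_sweep.py` traces the full curve, and
`analysis/04_null_calibration.py` confirms the pairwise test rejects ~5% of
truly identical provenance pairs at α = 0.05. All driver outputs are
written under `results/`.

To analyse real data, point `dendroprov.pipeline.PipelineConfig` (or the
`dendroprov run --config cfg.yaml` CLI) at your own RWL files, a series
metadata CSV (`series_id, tree_id, provenance, site`) and monthly climate
CSVs.

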