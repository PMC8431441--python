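# msiith

Intra-tumor heterogeneity (ITH) analysis of MALDI mass-spectrometry-imaging
peptide images, as a tested end-to-end pipeline:

1. **Preprocessing** — mass-channel unification, SNIP-style baseline
   subtraction, log-TIC outlier-spectrum flagging (GMM or MAD rule), rigid
   integer-channel peak alignment, and TIC normalization.
2. **Spectral components** — Gaussian-mixture decomposition of the cohort
   mean spectrum (valley fragmentation + weighted EM with BIC model
   selection); each Gaussian becomes one feature, and pixel spectra are
   projected onto overlap-renormalized Gaussian weights.
3. **Segmentation** — divisive iterated k-means over the pooled
   pixel-by-component matrix with per-node ("region-driven") feature
   selection, Dunn-index k selection, and a GAP-statistic split/stop rule,
   yielding hierarchical cluster labels per level.
4. **Heterogeneity metrics** — per-ROI pairwise spectral similarity (Pearson,
   with ECDF), per-level cluster counts, and Simpson's diversity index
   (distinct-pairs estimator by default).
5. **Statistics** — Wilcoxon rank-sum (exact or tie-corrected normal) with
   Pallant's r, Kruskal–Wallis with eta-squared and the Conover–Iman
   posthoc, Cohen's-d screening of discriminatory components (cluster
   contrast AND outcome contrast), cluster-contribution comparison,
   ROI-size/cluster-count and TILs correlations.
6. **Annotation** — component-to-peptide matching against an LC-MS/MS-style
   peptide library at a relative ±0.05% mass tolerance under the [M+H]+
   convention, with per-protein summaries and decoy-rate reporting.

A synthetic cohort generator (`msiith.synth`) plants known spatial
sub-regions (Voronoi/blob geometry), region- and group-modulated peak
profiles, multiplicative TIC variation, baseline, noise, outlier pixels, and
mass-shift miscalibration, so every stage is testable against ground truth
without external data.

## CLI

All stages share an artifact directory and a YAML config
(`msiith.datatypes.PipelineConfig`); stage commands reuse whatever upstream
artifacts already exist there.

```sh
msi-ith run --seed 7 --out run/                 # full synthetic run
msi-ith simulate --seed 7 --out run/            # just generate the cohort
msi-ith segment --out run/                      # ... through segmentation
msi-ith annotate --tolerance 5e-4 --out run/
msi-ith import data/imzml_dir --format imzml --out run/   # external data
```

Inputs: continuous-mode imzML (one file per ROI plus `clinical.csv`) or the
internal HDF5 cohort container. Outputs: CSV tables per stage (QC report,
component table, per-pixel labels, per-ROI heterogeneity profiles, test
results, effect sizes, screening list, matches, protein summary) plus a
`manifest.json` with config snapshot, seed, timings, and artifact digests.

## Layout

```
src/msiith/
  datatypes.py    core types + config blocks
  io.py           HDF5 container, imzML subset, clinical CSV
  synth.py        synthetic cohorts with planted truth
  preprocess.py   spectra processing chain + QC report
  components.py   mean-spectrum GMM decomposition, feature matrix
  divik.py        divisive k-means segmentation
  metrics.py      similarity, Simpson diversity, ROI profiles
  stats.py        rank tests, effect sizes, screening
  annotate.py     peptide/protein matching
  pipeline.py     orchestration + manifest
  cli.py          click CLI (`msi-ith`)
```
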