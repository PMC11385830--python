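# emtstage

Marker-anchored EMT staging of transcriptomic data, packaged as a tested,
reusable pipeline:

- **`simdata`** — synthetic single-cell, bulk, spatial (DSP), and survival
  datasets with ground truth: NB counts (variance `mu + mu^2/theta`), a latent
  EMT axis with a rising mesenchymal marker (VIM) and falling epithelial
  markers (CDH1/EPCAM), step-like TF activations that persist once on,
  lognormal library sizes, a mitochondrial gene block, injectable QC
  outliers, paired ROI segments, and cohorts whose hazard depends on a
  signature score.
- **`sc_core`** — per-cell QC (one-sided MAD cuts: 5×MAD on log1p library
  size and detected genes, 3×MAD on mito%), gene filtering (expressed in
  more than five cells), log2 CP10K normalization (Pearson-residual option),
  top-3000 HVG selection, PCA (13 PCs by default), SNN + Leiden clustering.
- **`staging`** — ordinal stratification of cells into half-open `(a, b]`
  bins of log2 marker expression ("VIM 0-1" … "VIM 5-6"), per-stratum
  Wilcoxon rank-sum differential upregulation vs a reference stratum (exact
  enumeration for tiny groups), and TF onset/persistence classification
  (earliest stage significant at `p < 0.05`, `log2FC >= 1`).
- **`scoring`** — single-sample rank-based gene-set scores per cell (NES in
  `[-1, 1]`), per-stage medians, Spearman stage trends, a weighted gene
  signature score centered to a grand mean of zero (negative = mesenchymal),
  and the `2^-ddCt` qPCR utility.
- **`survival`** — stage signatures (up-DEGs ∩ hallmark EMT), sample-wise
  signature scoring, mean split into High/Low, Kaplan–Meier, log-rank, and a
  Cox proportional-hazards fit (Breslow ties, damped Newton).
- **`bulk_dsp`** — empirical-Bayes moderated t contrasts, Q3 normalization of
  paired Vim+/Vim− segments, per-gene paired t tests, preranked GSEA with
  gene-label permutations, and average-linkage correlation clustering.
- **`io` / `cli`** — 10x MTX triplet, GMT, TSV/CSV readers and writers, a
  strict YAML config, run manifests, and the `emtstage` command.

## CLI

```sh
emtstage simulate --n-cells 1000 --n-genes 500 --tf TFA:0.4:2 --seed 7 --out run/sim
emtstage qc    --counts run/sim/counts --out run/qc
emtstage stage --counts run/qc/filtered --marker VIM --bins 6 --out run/stage
emtstage de    --counts run/qc/filtered --out run/de
emtstage onset --counts run/qc/filtered --tf-list tfs.txt --out run/onset
emtstage score --counts run/qc/filtered --gmt hallmark.gmt --weights emt76.tsv --out run/score
emtstage survive --expr cohort.tsv --survival surv.tsv --signature sig.txt --out run/sv
emtstage bulk  --expr bulk.tsv --groups E,E,E,M,M,M --gmt hallmark.gmt --out run/bulk
emtstage dsp   --segments segments.csv --gmt hallmark.gmt --n-perm 1000 --seed 17 --out run/dsp
emtstage all   --seed 1 --out run/demo   # end-to-end demo on simulated data
```

Each subcommand writes TSV/JSON artifacts plus a `manifest.json` recording
the tool version, config hash, input checksums, and seeds.

## Conventions worth knowing

- Negative binomial is parameterized by (mean, dispersion θ) with variance
  `mu + mu^2/theta` throughout.
- Cells with zero marker expression join the lowest stratum by default
  (`exclude_zero=True` reproduces the strict `0 < x` reading).
- The "p < 0.05" upregulation gate uses BH-adjusted p by default; pass
  `--raw-p` / `use_raw_p=True` for the permissive reading.
- NES is the enrichment score divided by the global max |ES| (range
  normalization); preranked-GSEA q values are BH adjustments of permutation
  p values.
- Mean-split ties (score exactly at the mean) go to the Low group.
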