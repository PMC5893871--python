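# wavetex

Multiscale 3D-wavelet texture radiomics for multispectral histopathology
volumes.

Colorectal lesions progress through distinct grades — stroma (ST), benign
hyperplasia (BH), intraepithelial neoplasia (IN), carcinoma (CA) — whose
histological appearance differs in texture at several spatial and spectral
scales.  `wavetex` measures those differences on multispectral whole-slide
image stacks (16 narrow bands over 500–650 nm treated as a volume with the
spectral axis as depth) and evaluates how well they separate the grades.
It is aimed at digital-pathology and radiomics researchers who want a
transparent, fully scriptable texture pipeline.

## Method

For each sample the pipeline

1. **normalizes** the volume `V[x, y, z]` by its global standard deviation;
2. **segments** the tissue region with a morphological Chan–Vese active
   contour on the ×8 down-sampled band-mean image (or accepts supplied
   masks), reporting JSC/DSC/FPR/FNR agreement against ground truth:
   `JSC = |A∩B|/|A∪B|`, `DSC = 2|A∩B|/(|A|+|B|)`;
3. **decomposes** the ROI with a single-level separable 3D discrete wavelet
   transform (orthonormal Daubechies-2, periodized, 2D + 1D scheme) into
   eight octant sub-bands `{L,H}x ⊗ {L,H}y ⊗ {L,H}z` = LLL … HHH;
4. **quantifies** each octant inside the ROI with variance
   `(1/N)Σ(v−v̄)²`, Shannon entropy `−Σ pₖ log₂ pₖ` and energy `Σ pₖ²`
   over a 256-bin min–max histogram — a 24-feature vector per sample;
5. **tests** each z-scored feature with one-way ANOVA across the four
   grades under Holm–Bonferroni correction (familywise α = 0.01); and
6. **classifies** the grades with a 100-tree random forest under
   stratified 5-fold cross-validation, reporting one-vs-rest
   accuracy/sensitivity/specificity (mean ± SD over folds) and
   fold-averaged per-class AUC.

A synthetic multispectral generator with class-distinct texture (dense
small high-contrast "nuclei" blobs and steeper spectral profiles for
higher grades) provides labelled cohorts and ground-truth masks, so the
whole pipeline runs and is tested without clinical data.  See
`docs/methods.md` for modelling details and conventions.

## Worked example

Generate a 39-sample cohort (ST = 9, BH = 10, IN = 9, CA = 11) of
128 × 128 × 16 volumes and run the full pipeline:

```sh
wavetex simulate --out demo --seed 7
# wrote 39 samples; manifest at demo/manifest.csv
wavetex run-all --manifest demo/manifest.csv --out demo_run --seed 7
```

which prints

```json
{
  "accuracy_mean": 0.9071428571428571,
  "n_samples": 39,
  "n_significant": 19,
  ...
}
```

`n_significant = 19` of the 24 features differ between grades at corrected
p < 0.01 (all eight variance features are among them), and the combined
24-feature random forest reaches a one-vs-rest macro accuracy of
0.907 ± 0.072 over the five folds (sensitivity 0.775 ± 0.166, specificity
0.935 ± 0.050; plain multiclass accuracy 0.814).  Per-class fold-averaged
AUC comes out at ST 0.97, BH 0.85, IN 0.87, CA 0.99 — carcinoma texture,
with its dense fine-scale detail, is the easiest grade to recognize.
`demo_run/` holds the feature table (`features.csv` + provenance sidecar),
the significance report (`stats.json`, with −log₁₀ p-values for heatmaps)
and the cross-validation report (`cv_report.json`).

The same steps are available as library calls
(`generate_cohort → extract_feature_table → zscore_table →
significance_report / train_eval_cv`) and as separate subcommands
(`simulate`, `segment`, `extract`, `stats`, `classify`).

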