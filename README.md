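# asymscreen

Toolkit for quantifying left–right asymmetry in early-embryo data:

- **`asymscreen.screen`** — paired left/right bulk expression screen:
  mean-coverage normalization, expression flags (signal ≥ 20), P50 gene
  lists (flagged in ≥ half the samples), a moderated paired log2-ratio
  test, fold-change/p-value thresholding (FC ≥ 1.2, p ≤ 0.05),
  consensus union across engines, MA statistics, background calls
  (< 5.6), co-expression fractions and ΔΔCt relative expression.
- **`asymscreen.spots`** — 3D two-channel spot quantification:
  Laplacian-of-Gaussian spot detection, midline bisection of a region
  mask, a nuclei-based (Hoechst) side-normalization score using a
  per-side 50%-coverage threshold, and the normalized left/right log2
  ratio `log2[(S_L/(H_L·V_L)) / (S_R/(H_R·V_R))]`, plus per-stage
  summaries with exact nonparametric tests.
- **`asymscreen.morphometry`** — landmark-based heart-loop geometry:
  rigid alignment to the embryo frame (notochord → Z, dorso-ventral
  reference → +X, +Y = embryo's left), signed RV/LV axis angle,
  venous-pole displacement normalized by tube length, looping-direction
  calls and Yates-corrected direction-frequency tests. Samples with
  fewer than 18 somites are rejected by QC.
- **`asymscreen.variants`** — ultrarare-variant filter: MAC ≤ 2 in every
  population dataset AND (protein-truncating consequence OR missense /
  inframe indel with REVEL ≥ 0.932 or CADD_phred ≥ 28.1).
- **`asymscreen.stats`** — exact small-sample Mann–Whitney U and
  one-sample Wilcoxon signed-rank tests (full enumeration nulls),
  Benjamini–Hochberg adjustment, chi-squared goodness of fit with Yates
  correction.
- **`asymscreen.synthetic`** — seeded generators for every input:
  negative-binomial paired count matrices, two-channel 3D volumes with
  Gaussian nuclei and Poisson-placed transcript spots (configurable
  left/right density ratio, one-sided intensity bias, PSF, noise),
  landmark sets with known angle/offset/length, and variant tables
  covering every filter branch. Each generator returns a `GroundTruth`
  record that scores the downstream stage.
- **`asymscreen.io`** — TSV/JSON/TIFF/VCF readers and writers, YAML run
  configuration (unknown keys rejected), and a deterministic
  simulate→screen pipeline runner with a hashed output manifest.

## Command line

```bash
asymscreen simulate counts    --seed 1 --out sim/          # + truth.json
asymscreen simulate image     --preset E8.5d --seed 1 --out sim/
asymscreen simulate landmarks --seed 1 --out sim/
asymscreen simulate variants  --n 24 --seed 1 --out sim/

asymscreen screen --counts sim/counts.tsv --samples sim/samples.tsv \
    --flag-threshold 20 --min-fold 1.2 --max-p 0.05 --out screen/
asymscreen quantify-spots --image sim/embryo_volume.tif \
    --mask sim/embryo_mask.tif --meta sim/embryo_meta.json \
    --region heart_field --out quant/
asymscreen morphometry --landmarks sim/landmarks.json --out morpho/
asymscreen filter-variants --vcf sim/variants.vcf --out filtered/
asymscreen stats signed-rank --d 1,2,3
asymscreen run --config config.yaml --seed 1 --out run/
```

`simulate image --preset E8.5d` fixes the generator's true left/right
transcript-density ratio to 4.5, the stage of peak left-sided
enrichment.

## Conventions

- Image volumes are `(channel, z, y, x)` with channel 0 = nuclei and
  channel 1 = transcript; the midline plane is given as coefficients
  `(a, b, c, d)` over voxel indices, with the nonnegative side being the
  embryo's left. Voxels exactly on the plane count as left.
- The RV/LV angle is the signed angle of the RV→LV vector in the
  transverse plane, measured from the +Y (leftward) axis,
  counter-clockwise positive viewed from cranial; a normal rightward
  loop reads 0°. This convention is fixed by this package and stated
  here because the upstream literature does not pin it down.

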