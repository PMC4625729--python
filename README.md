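# ilaquant

Quantitative CT detection of interstitial lung abnormalities (ILA), and how
well it agrees with the radiologist's eye.

Interstitial lung abnormalities — non-dependent ground-glass, reticulation,
cysts or honeycombing on a chest CT — mark individuals at elevated risk of
developing clinically significant interstitial lung disease. They are usually
identified by visual read, which is slow and reader-dependent. A fully
automated alternative scores each scan by its **high attenuation areas
(HAA%)**: the percentage of lung voxels with attenuation between −600 and
−250 Hounsfield Units, the window where ground-glass and reticular changes
live (normal aerated parenchyma sits near −850 HU; blood and soft tissue near
+40 HU; emphysema below −950 HU). `ilaquant` implements that densitometric
pipeline end to end and quantifies how far a density threshold can stand in
for a visual read.

The package is aimed at quantitative-imaging and epidemiology researchers. It
provides:

- **Densitometry** — lung segmentation, HAA%, LAA-950 emphysema %
  (fraction of lung < −950 HU) and CT-derived total lung capacity
  (TLC = lung voxel count × voxel volume) from any NIfTI HU volume.
- **Agreement** — classify scans ILA-positive when HAA% ≥ a threshold
  (10 %, or a cohort percentile such as the 95th), cross-tabulate against the
  visual read, and compute Cohen's κ = (p_o − p_e)/(1 − p_e) with an
  asymptotic null-variance p-value, sensitivity/specificity/PPV/NPV, a
  rank-based c-statistic (Mann–Whitney AUC) and threshold sweeps with
  Youden's J. Subjects read as *indeterminate* can be excluded or counted as
  controls; both policies are first-class.
- **Association** — adjusted logistic odds of visual ILA per 1 % HAA,
  linear TLC change (ml) per 1 % HAA, stratified effect-modification fits
  (emphysema < / ≥ 5 %, BMI < / ≥ 30) with a pooled interaction test, and
  additive genetic models (genotype coded 0/1/2 as one numeric term).
- **Synthetic validation data** — 3-D CT phantoms whose material composition
  (ground-glass, emphysema, vessel fractions) is known exactly at the voxel
  level, and cohort simulators with configurable true effect sizes, so every
  stage is testable by parameter recovery without any real cohort.

## Worked example

Simulate a cohort of 2093 subjects at the default generating effects (true
odds ratio 2.3 per 1 % HAA, true TLC slope −351 ml per 1 % HAA), then compare
the ≥10 % HAA rule against the visual read and fit the association models:

```bash
$ ilaquant cohort simulate --out cohort.tsv --n 2093 --seed 1
cohort of 2093 subjects written to cohort.tsv (160 with visual ILA)

$ ilaquant agree cohort.tsv --threshold-pct 10
threshold 10.00% (exclude); counts a=2 b=158 c=0 d=1194
kappa 0.02 (p=0.0001106)
sensitivity 1%
specificity 100%
ppv 100%
npv 88%

$ ilaquant assoc cohort.tsv
ila_or        odds_ratio: 2.26 (95% CI 1.98-2.59, p=4.06e-33, n=1354)
tlc_slope_all ml_per_pct: -336 (95% CI -354--318, p=7.25e-227, n=2093)
genotype_haa  pct_haa_per_allele: 0.0212 (95% CI -0.122-0.165, p=0.772, n=2093)
```

Read: at a 10 % cut agreement with the visual read is slight (κ = 0.02 —
almost all visually read ILA lies below the threshold), yet HAA as a
*continuous* measure is strongly associated with ILA (fitted OR 2.26, true
2.3) and with lung-volume loss (fitted −336 ml/%, true −351); the genetic
term is null by construction (p = 0.77). Low κ alongside a strong continuous
association is the central phenomenon this package quantifies.

Phantom round trip — the generator reports voxel-counted truth, densitometry
re-measures it blind:

```bash
$ ilaquant phantom generate --out demo.nii.gz --shape 64 --ggo-fraction 0.10 --seed 1
phantom written to demo.nii.gz: true HAA 10.00%, true LAA-950 0.00%, lung volume 0.035 L
$ ilaquant densito run demo.nii.gz
volume        haa_pct  emph_pct  tlc_l   lung_voxels
demo.nii.gz   9.9219   0.0000    0.0348  34822
```

A full orchestrated run (`ilaquant pipeline run --config cfg.yaml`) emits the
cohort, an agreement report across thresholds and indeterminate policies, an
association table and density-plot data, all stamped with the seed and a
config hash; see `docs/methods.md` for the model details.

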