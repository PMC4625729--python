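# Methods

## Densitometry

All quantities are functions of the HU histogram inside a binary lung mask.

- **HAA fraction**: |{v ∈ mask : −600 ≤ HU(v) ≤ −250}| / |mask|. Both window
  endpoints are inclusive; the window is a parameter so endpoint sensitivity
  can be probed. Reported ×100 as a percent at interfaces.
- **LAA-950 (emphysema) fraction**: voxels strictly below −950 HU, the
  conventional low-attenuation-area semantics.
- **TLC**: |mask| × voxel volume (mm³) / 10⁶, in litres. No percent-of-
  predicted scaling is applied (reference equations are out of scope).

The lung mask *includes* intrapulmonary vessels. Blood attenuates near
+40 HU, far above the −250 HU ceiling, so vessels are excluded from the HAA
numerator by the window itself; keeping them in the denominator makes the
denominator the anatomic lung volume. This is a deliberate convention and
the one the fraction definitions above assume.

### Lung segmentation

The segmenter is intentionally minimal: (1) threshold HU < −320 to get
air-like voxels; (2) 6-connected components; (3) drop components touching
any face of the grid (ambient air, and an airway reaching the scan edge);
(4) keep the largest one or two remaining components (second kept if ≥ 0.3×
the largest), which drops small airway stumps; (5) binary closing (ball,
radius 2 voxels) and hole filling to re-absorb vessels and dense
ground-glass that the air threshold excluded. Failure to find any candidate
raises a "no lung detected" error rather than returning an empty mask.
On noiseless phantoms ≥ 48³ this yields Dice ≥ 0.99 against the true mask
and fraction errors below 0.01; it is a phantom-validation tool, not a
clinical segmenter (no airway tree modelling, no pleural refinement).

## Phantoms

Phantoms exist to give densitometry an exact oracle. The body fills the
whole grid at +40 HU (no exterior air — this keeps the border-component
rule meaningful); two ellipsoidal lungs at −850 HU (semi-axes 0.15/0.28/0.38
of the grid) are separated by a thin air-filled trachea cylinder that
reaches the top z-face, so the segmenter's border rule removes it. Within
the lungs, material is placed in this order from a single seeded RNG
stream: vessel cylinders (random chords, radius 1–2 voxels, +40 HU),
emphysema spheres (HU uniform in [−1000, −960]), ground-glass spheres (HU
uniform in [−600, −250]). Each material converts parenchyma voxels until
its requested fraction of lung voxels is met, and the final blob is trimmed
voxel-by-voxel (nearest to its centre kept) so the count is exact; the
returned truth fractions are nevertheless *counted* from the label map, not
echoed from the request. Gaussian HU noise (SD in HU, a proxy for the
image-noise effect of high body mass) is added last and the volume is
clipped to [−1024, 3071] and stored as integer HU, which NIfTI round-trips
exactly. Because parenchyma sits 250 HU below the window floor, added noise
can only push lung voxels *into* the HAA window on an emphysema-free
phantom — the monotone noise-inflation property the tests check.

Geometry is schematic by design; anatomically realistic lungs, scanner
reconstruction kernels and DICOM series are non-goals. Segmentation of
phantoms below ~48³ is not supported (the trachea and lungs can touch at
coarse rasterization); generation itself works from 16³ up.

## Cohort simulator

Each subject gets covariates (age ~ N(60, 9²) years, sex, race, BMI ~
N(28.5, 5.5²) kg/m², pack-years log-normal with median 30, current smoking,
emphysema % log-normal with median 2 %), a genotype drawn under
Hardy-Weinberg equilibrium (risk-allele frequency 0.11, typical of the
MUC5B promoter variant in European populations), and an HAA percentage
drawn log-normally: exp(N(ln 3.4, 0.38²)) %, plus an optional additive
genotype shift (default 0 — the null). The log-scale SD 0.38 puts the 95th
percentile near 6.3–6.4 %, matching the threshold the agreement stage
derives as a "95th-percentile" cut.

The three-level visual read is a **multinomial logit with baseline
no_ila**:

    log P(ila)/P(no_ila)  = −5.4 + ln(2.3)·HAA% + covariate terms
    log P(ind)/P(no_ila)  = −1.9 + 0.40·HAA%    + 0.5·covariate terms

Two consequences drive the design. First, conditioning a multinomial logit
on two of its categories preserves their pairwise log-odds, so the analysis
that *excludes* indeterminates recovers the generating OR of 2.3 per 1 %
HAA exactly in expectation — a sequential two-logistic scheme would not
(its exposure-dependent control selection inflates the excluded-analysis
OR). Second, the indeterminate slope (0.40) is positive but shallower than
the ILA slope (0.83), giving indeterminates intermediate HAA; pooling them
into the controls therefore attenuates the fitted OR (≈ 2.3 → ≈ 1.9 at the
defaults), the direction the policy-sensitivity tests assert. The
intercepts were calibrated once so that at n = 2093 the cohort shows ~8 %
ILA and ~36 % indeterminate reads with subgroup HAA medians near 4.8 %
(ILA) and 3.1 % (no ILA).

Effect modification is simulated by stratum-specific HAA slopes (default
ORs 1.2 below / 3.8 at-or-above 5 % emphysema, or 1.9/3.1 around BMI 30)
rather than an explicit interaction coefficient, because stratified
estimates are what the analysis stage reports.

Lung volume is linear: TLC(ml) = 6800 − 351·HAA% − 700·female −
15·(age−60) − 25·(BMI−28) + N(0, 600²). Covariate effects other than the
headline OR and slope are small nuisance values; they exist so that
"adjusted" fits genuinely adjust for something.

What the simulator does **not** emulate: familial correlation (subjects are
independent, so mixed-model machinery is unnecessary and ordinary GLMs are
correct here — a fit to real family data would need random effects),
spirometry, scanner/protocol heterogeneity, and measurement error linking a
subject's HAA% to an actual reconstructed image. Passing recovery tests
therefore shows the *estimators* are correct under the stated generating
model, not that real cohorts satisfy that model.

## Agreement statistics

Positivity is HAA% ≥ threshold (boundary positive). Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the row/column marginals; its
p-value is the two-sided asymptotic z-test of κ = 0 using the large-sample
null variance

    var₀ = [p_e + p_e² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)] / [n (1 − p_e)²].

An exact permutation p could be substituted; the asymptotic form is the
default because every table of interest here has n ≈ 2000. With any zero
marginal the p-value is reported missing; with p_e = 1 κ itself is
undefined and raises. Panel rates with zero denominators are reported as
missing, never as 0. The c-statistic is the tie-aware rank AUC
(Mann–Whitney U / n₁n₀), identical to the c-statistic of a one-predictor
logistic model. Report rounding mirrors the conventional printing: κ to
2 decimals, rates to the nearest percent. Threshold sweeps select the best
cut by maximal Youden's J on the supplied grid, ties toward the lower
threshold; the selection rule is a parameter because no single rule is
canonical.

Contingency tables built with `indeterminate_policy="as_control"` absorb
indeterminates into the no-ILA row and record how many; `"exclude"` drops
them. Exclusion is the analytic default; as_control is the default only
for report-parity tables whose published counts include indeterminates.

## Association models

Logistic (ILA vs HAA%) and linear (TLC vs HAA%) fits use statsmodels GLMs
with Wald 95 % CIs on the link scale, exponentiated for ORs. The default
adjustment set is age, sex, race, BMI, pack-years, current smoking and
emphysema % (emphysema % also serves as the COPD-severity proxy; spirometry
is not simulated). Genetic models enter genotype as a single numeric 0/1/2
term (additive coding) with an age/sex/BMI/smoking adjustment. Stratified
fits report per-stratum ORs plus a Wald p for the HAA-by-stratum
interaction from the pooled model. Logistic fits detect separation
(non-finite or absurdly large coefficients, |β| > 15) and raise instead of
returning an unbounded OR; monomorphic genotypes and empty strata/subsets
raise named errors.

## Problem sizes and numerical choices

Validation uses 20 noiseless 128³ phantoms (densitometry oracle: truth-mask
fractions within 0.005, segmented within 0.01, Dice ≥ 0.95), 100 cohorts of
n = 2093 per recovery check (95 % CI coverage required in ≥ 93/100), 200
replicates of n = 500 for the additive-model null calibration (rejections
inside the central 99 % binomial band around 5 %), and 5 replicates of
n = 6000 for the policy-attenuation direction. Seeds are explicit
everywhere; phantom generation, cohort simulation and the full pipeline are
bit-reproducible given a seed, and pipeline outputs embed the seed and a
hash of the scientific configuration.

## Known limitations

- The segmenter assumes phantom-like geometry; real chest CTs need a
  dedicated lung segmenter.
- The kappa p-value is asymptotic; for very sparse tables prefer an exact
  method.
- Wald CIs can undercover for rare outcomes at small n; the recovery tests
  operate at n ≈ 2000 where they are accurate.
- The simulator's covariate structure is intentionally simple (independent
  draws); confounding strength is mild, so adjusted and crude estimates
  differ less than they may in real cohorts.
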