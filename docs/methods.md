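# Methods

`petmr_hybrid` quantifies invasive ductal breast carcinoma (IDC) lesions from
co-registered PET / DCE-MRI / DWI volumes and relates the resulting imaging
parameters to tissue biomarkers with a fully nonparametric univariate
battery. This note records the models, the defaults and why, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Imaging model

**PET.** Lesion VOIs are segmented by a fixed threshold at 40% of the maximum
uptake inside a search region, reduced to the single 26-connected component
containing the maximum voxel. 26-connectivity is the standard choice for 3-D
hot-spot VOIs; ties at the regional maximum are seeded at the first maximal
voxel in lexicographic index order (all tied maxima end up in the VOI when
connected), making the output deterministic. Interactive "manual adjustment"
after thresholding is replaced by the search-region restriction for
reproducibility. SUVmax and SUVmean are the VOI maximum and mean of the
body-weight-normalized uptake; `suv_from_activity` converts an activity
concentration (kBq/mL) with injected dose (MBq) and body weight (kg) under
the 1 g/mL density convention.

**DCE-MRI.** A six-phase series (one pre-contrast, five post-contrast, 90 s
apart) is summarized by the per-phase VOI mean signal SI0..SI5. Five
semi-quantitative descriptors are computed:

- E1 = 100 (SI1 − SI0) / SI0 — first post-contrast enhancement, %
- ESER = 100 (SI1 − SI0) / (SI2 − SI0) — early signal enhancement ratio
- Slope = 100 (SI5 − mean(SI1, SI2)) / mean(SI1, SI2) — late slope, %
- SPER = (SIpeak − SI0) / (SI5 − SI0) — peak enhancement ratio
- SFER = (SI1 − SI0) / (SI5 − SI0) — first enhancement ratio

SIpeak is the maximum over all six phases, pre-contrast included (the
verbatim definition); a consequence is that non-enhancing curves can produce
SPER ≤ 0, which is reported, not clamped. Each descriptor with an undefined
denominator (SI0 = 0, SI2 = SI0, mean(SI1,SI2) = 0, SI5 = SI0) is flagged
invalid (NaN) for that lesion only; the lesion stays in the analysis for its
other parameters. All five descriptors are invariant to a common scaling of
the signal, so they carry no arbitrary scanner units.

The time-intensity curve (TIC) is classified from Slope: wash-out below
−10%, persistent above +10%, plateau in between. The plateau interval is
closed on both boundaries ([−10, 10]) so the three classes partition the
line and the boundary behaviour is explicit.

**DWI/ADC.** ADC maps use the two-point mono-exponential model,
ADC = ln(S_low/S_high) / (b_high − b_low), expressed in 1e-6 mm²/s so that
hybrid SUV/ADC magnitudes land on the ~1e-3 scale. Voxels with non-positive
signal or a negative ADC (signal rising with b) are flagged invalid and
excluded from VOI statistics; a lesion with no valid ADC voxel is excluded
with a logged reason. Rigid mask transfer between DWI volumes applies a
*given* rotation/translation by nearest-neighbour resampling (estimation of
the transform is out of scope).

**Hybrids.** Fourteen hybrid parameters combine PET with MRI: SUVmax and
SUVmean each multiplied by E1, ESER, SPER and SFER (descriptors that rise in
malignant lesions) and divided by Slope, ADCmin and ADCmean (quantities that
fall). Every hybrid therefore increases with malignancy; only raw ADCmin and
ADCmean carry direction −1 in the feature metadata, which the ROC stage uses
for orientation. The inventory is fixed: 9 single + 14 hybrid = 23.

## Biomarker rules

ER/PgR are positive when strictly above 0%; Ki67 is positive at ≥ 20%; HER2
is negative at score 0/1+, positive at 3+, and resolved by FISH at 2+ (an
unresolved 2+ leaves HER2 undetermined and the subtype unclassified).
Surrogate subtypes: luminal A/B are hormone-receptor-positive, HER2-negative,
split on the Ki67 flag; hormone-positive HER2-positive lesions are luminal B
HER2+; hormone-negative lesions split into triple negative and HER2+.
Only luminal A vs B enters the statistics — the extended classes are cohort
bookkeeping, so no Ki67 condition is imposed on luminal B HER2+.

## Statistics

All tests are nonparametric. Spearman correlation uses average ranks for
ties; its p-value comes from the t approximation above n = 10 and from exact
permutation enumeration at n ≤ 10. Mann-Whitney U switches from the exact
distribution to the tie- and continuity-corrected normal approximation at a
combined n of 20 (the common convention; both branches are oracle-tested).
The Hodges-Lehmann estimate (HLE) is the median of all n1·n2 pairwise
differences, reported as reference group minus aggressive group (so SUV-type
parameters give negative shifts for G1 vs G3, ADC positive). Its confidence
interval is the Moses order-statistic construction: with D the sorted
pairwise differences and k the largest integer with P(U ≤ k) ≤ α/2, the
interval is (D(k+1), D(n1·n2−k)); the exact U distribution (computed by the
Gaussian-binomial recurrence) is used up to 400 pairwise differences, the
normal approximation beyond, and samples too small to support the level
return the full difference range.

Family-wise control is Bonferroni: factor 126 (= 9 × 14) for the
single-vs-hybrid correlation matrix, factor 23 (= 9 + 14) for every
biomarker association. The HLE confidence level matches the corrected
per-comparison level, 1 − 0.05/23 = 0.99783 (displayed as 99.8%); the
internal computation uses the unrounded level.

ROC analysis orients each score by its direction metadata with the
aggressive group (G2/G3, Ki67-positive, luminal B) as the positive class; no
automatic flipping, so an AUC below 0.5 is reported honestly. The AUC is the
trapezoidal area, its CI uses the DeLong placement-variance estimator
(deterministic, the de facto standard), and the operating cutoff maximizes
Youden's J over midpoints between adjacent distinct scores, with ties broken
toward higher sensitivity and then the lower cutoff. Sensitivity,
specificity, PPV and NPV are computed from the confusion matrix at that
cutoff. Missing values are deleted pairwise per parameter throughout.

A Kolmogorov-Smirnov normality screen is deliberately omitted: every
downstream test is nonparametric, so a normality gate would have no
consumer.

## Synthetic cohorts

The generator exists so every stage is testable without clinical data. One
latent aggressiveness score a ~ N(0,1) per lesion drives three latent
Gaussians (Ki67, SUV, ADC) through a one-factor model with loadings chosen
so the implied pairwise Pearson correlations equal 2·sin(π·ρ/6) for the
configured Spearman targets (default +0.46 for Ki67-SUVmean, −0.28 for
Ki67-ADCmin). Marginals are imposed by rank mapping — the i-th ranked latent
value receives the marginal quantile at (i − 0.5)/n — which preserves rank
correlations exactly and makes the composition deterministic per seed:
grades always split 52/76/31 at n = 159 (largest-remainder allocation on a
noisy copy of a, noise SD 0.5), and exactly 71/159 lesions are
Ki67-positive.

Marginal scales, free by design (only directions and correlation magnitudes
are calibrated): Ki67 lognormal with σ = 0.65 and median ≈ 18% (placing the
20% cutoff at the 55.3rd percentile); SUVmean lognormal, median 3.2, σ = 0.5
(range ≈ 1.5–12, typical of FDG-avid malignant breast lesions); SUVmax =
SUVmean × U(1.4, 2.0); ADCmin truncated normal (1000 ± 170, bounds
600–1700 × 1e-6 mm²/s, typical malignant range); ADCmean = ADCmin ×
U(1.2, 1.5). Hormone receptors are near-saturated (1.9% / 1.3% negatives),
HER2 3+ rare (8.8%), both independent of aggressiveness, as are the TIC
archetypes (mix 0.35 / 0.26 / 0.39 wash-out / plateau / persistent) — DCE
descriptors therefore carry no biomarker signal, which is exactly the
pattern the battery should find.

`subtype_auc_target` defaults to None because the luminal A/B separation of
the SUV-driven scores is already implied by the correlation targets (AUC
≈ 0.72 at the defaults). Setting a target adds an analytic location shift to
the SUV latent of Ki67-positive lesions, with the copula correlation
re-solved (treating the shifted latent as approximately Gaussian) so the
rank-correlation target is preserved.

The image renderer produces ≤ 32³-voxel phantoms at 2 mm isotropic spacing:
an ellipsoidal lesion with a Gaussian radial uptake profile whose maximum is
the lesion's true SUV peak; DCE phases following a canonical archetype curve
scaled voxel-wise by the profile (so ratio-based TIC descriptors are exact at
zero noise); a DWI pair encoding an ADC field that rises from the configured
floor at the core; PET noise zero-mean Gaussian with SD proportional to
√signal, MR noise Rician (magnitude of a complex Gaussian). No anatomical
background, motion, scanner PSF or partial-volume effects are simulated —
passing tests show the pipeline's arithmetic and statistics are correct
under the stated model, not that the parameters are robust to real
acquisition physics.

## Problem sizes

Default analyses run at n = 159 lesions. Calibration recovery averages 200
cohorts; ROC summaries average 100; the null family-wise error simulation
uses 500 replicates of the 23-test Ki67 family; interval coverage uses 1000
replicates at n = 30 per group. These sizes hold Monte-Carlo error well
below the decision margins while keeping a full run in tens of seconds.

## Known limitations

- The generator realizes associations through a single latent factor;
  real multi-pathway biology (e.g. HER2-driven uptake) is not modelled.
- Exact Spearman permutation p-values at n = 9–10 enumerate up to 3.6M
  permutations and take seconds; use the t branch when speed matters.
- The Moses interval uses the normal approximation beyond 400 pairwise
  differences; coverage is validated by simulation, not exact there.
- Non-luminal subtypes are generated only via the (rare) overlap of ER- and
  PgR-negativity, so triple-negative lesions are scarcer than in typical
  clinical series; they play no role in the statistics.
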