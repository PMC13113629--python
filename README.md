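# petmr-hybrid

Hybrid PET/MRI quantification of invasive ductal breast carcinoma (IDC)
lesions, for imaging scientists who want a reproducible, scriptable version
of the common clinical-research workflow: segment a lesion on each modality,
extract single-modality and hybrid imaging parameters, and test their
associations with tissue biomarkers.

From co-registered lesion volumes — a PET SUV volume, a six-phase DCE-MRI
series and a DWI pair (b = 0 / 1000 s/mm²) — the package computes **9
single-modality parameters**: SUVmax, SUVmean; the semi-quantitative
time-intensity-curve (TIC) descriptors

- E₁ = 100·(SI₁−SI₀)/SI₀,
- ESER = 100·(SI₁−SI₀)/(SI₂−SI₀),
- Slope = 100·(SI₅−mean(SI₁,SI₂))/mean(SI₁,SI₂),
- SPER = (SI_peak−SI₀)/(SI₅−SI₀),
- SFER = (SI₁−SI₀)/(SI₅−SI₀);

and ADCmin, ADCmean from the two-point mono-exponential ADC map. It then
builds **14 hybrid parameters** — SUV{max,mean} × {E₁, ESER, SPER, SFER} and
SUV{max,mean} / {Slope, ADCmin, ADCmean} — each oriented to increase with
malignancy. PET VOIs use a fixed 40%-of-maximum threshold (26-connected
component containing the maximum); TICs are classed wash-out / plateau /
persistent at Slope = ∓10%.

The statistics mirror the standard univariate battery: Spearman rank
correlations with ER%, PgR% and Ki67%, Mann-Whitney U comparisons across
grade (G1/G2/G3), Ki67 (≥ 20% vs < 20%) and surrogate subtype (luminal A vs
B) with Hodges-Lehmann shift estimates and 99.8% Moses intervals
(= 95% split across the 23-parameter inventory), Bonferroni factors
126 = 9×14 and 23 = 9+14, and ROC analysis with DeLong AUC intervals and
Youden-index operating points.

Because clinical PET/MRI cohorts are rarely shareable, a calibrated
synthetic-cohort generator (`petmr_hybrid.synthetic`) is a first-class
component: one latent aggressiveness factor drives Ki67, SUV and ADC with
exactly-recovered rank-correlation targets, and an image-level renderer
produces small lesion phantoms with Rician MR and Poisson-like PET noise.
See `docs/methods.md` for the model and all defaults.

## Worked example

`examples/04_run_statistics.py` simulates a 159-lesion cohort under the
default calibration, extracts the 23 parameters and runs the battery:

```
Spearman with Ki67% (adjusted p, factor 23):
  SUVmean        rho = +0.421   p_adj = 7.252e-07
  ADCmin         rho = -0.191   p_adj = 0.3606
  SUVmax/ADCmin  rho = +0.422   p_adj = 6.893e-07
  ESER           rho = -0.030   p_adj = 1
luminal A vs B, SUVmax/ADCmin: HLE = -0.002533 (99.8% CI -0.004136 to -0.001024), p_adj = 1.271e-05
ROC luminal A vs B, SUVmax/ADCmin: AUC = 0.743, sens = 76.6%, spec = 65.4% at cutoff 0.004977
```

Reading this: in one simulated cohort the proliferation index correlates
moderately with FDG uptake and with the SUVmax/ADCmin hybrid, while the
DCE-only descriptor (ESER) carries no signal after correction — the
structure the generator is calibrated to. The negative Hodges-Lehmann shift
says the hybrid score is typically ~0.0025 lower in luminal A than in
luminal B lesions (ADC is in 1e-6 mm²/s, hence the 1e-3 scale), and at the
Youden cutoff the hybrid separates the two subtypes with AUC ≈ 0.74.

The other examples cover cohort simulation, phantom rendering + segmentation,
feature extraction and the one-call pipeline. A thin CLI wraps the same
functions:

```bash
petmr-hybrid run-all --n-lesions 159 --seed 7 --out-dir run
petmr-hybrid simulate --n-lesions 50 --seed 1 --out cohort.csv
petmr-hybrid segment-pet pet.nii.gz region.nii.gz --threshold-fraction 0.40
```

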