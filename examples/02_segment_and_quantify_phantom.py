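"""Render one noiseless lesion phantom, segment it and extract parameters.

Shows the image-level path: a PET hot spot segmented at 40% of its maximum,
a six-phase DCE series summarized into TIC descriptors, and an ADC map from
the two-point mono-exponential DWI model.
"""

from petmr_hybrid import SyntheticConfig, adc_map, segment_pet_voi
from petmr_hybrid.quantify import adc_params, dce_params, pet_params, tic_summary
from petmr_hybrid.synthetic import LatentLesion, render_lesion_volumes

config = SyntheticConfig(seed=3, pet_noise_sd_scale=0.0, mr_rician_sigma=0.0)
lesion = LatentLesion(
    lesion_id="demo", aggressiveness=1.0, grade="G3", ki67_pct=35.0, er_pct=80.0,
    pgr_pct=60.0, her2_score="0", fish_amplified=None, tic_archetype="wash-out",
    true_suv_peak=6.5, true_adc_floor=850.0,
)
pet, series, (b0, b1000), truth = render_lesion_volumes(lesion, config)

voi = segment_pet_voi(pet, truth, threshold_fraction=0.40)
p = pet_params(pet, voi)
d = dce_params(tic_summary(series, truth))
a = adc_params(adc_map(b0, b1000), truth)

print(f"PET VOI: {voi.n_voxels} voxels (truth mask: {truth.n_voxels})")
print(f"SUVmax = {p.suv_max:.2f}, SUVmean = {p.suv_mean:.2f}")
print(f"Slope = {d.slope:.1f}% -> TIC type '{d.curve_type}'")
print(f"ADCmin = {a.adc_min:.0f} x 1e-6 mm^2/s")
print("-> at zero noise the VOI recovers the ground truth exactly: the peak")
print("   SUV, the sub-(-10%) wash-out slope and the configured ADC floor.")
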