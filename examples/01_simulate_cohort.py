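"""Generate a synthetic IDC lesion cohort and inspect its composition.

The generator drives Ki67, SUV and ADC from one latent aggressiveness score
through a Gaussian copula, so the configured rank correlations are recovered
exactly in expectation while every marginal (grade split, Ki67-positive
share, SUV/ADC scales) is fixed by rank mapping.
"""

from petmr_hybrid import SyntheticConfig, generate_cohort
from petmr_hybrid.stats import spearman

cohort = generate_cohort(SyntheticConfig(n_lesions=159, seed=7))

print(f"lesions: {len(cohort)}")
print("grade counts:", cohort["grade"].value_counts().sort_index().to_dict())
print(f"Ki67-positive share: {100 * cohort['ki67_pos'].mean():.1f}%")
print("subtypes:", cohort["subtype"].value_counts().to_dict())
rho, _ = spearman(cohort["ki67_pct"], cohort["suv_mean"])
print(f"Spearman(Ki67%, SUVmean) in this cohort: {rho:.3f}")
print("-> one seed's estimate of the configured 0.46 Ki67-uptake association;")
print("   the grade split and Ki67-positive share are identical in every seed.")
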