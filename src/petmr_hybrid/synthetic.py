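"""Synthetic multiparametric PET/MRI breast-lesion cohorts and phantoms.

A single latent "aggressiveness" score per lesion drives the proliferation
index (Ki67), the FDG uptake (increasing) and the diffusion floor
(decreasing) through a one-factor Gaussian copula. Marginals are imposed by
rank-mapping (inverse-transform on plug-in uniform positions), which (a)
makes every cohort's marginal composition deterministic — e.g. the share of
Ki67-positive lesions is the same in every seed — and (b) preserves the
calibrated rank correlations exactly, because Spearman correlation depends on
ranks alone.

Default composition mirrors a realistic invasive-ductal-carcinoma cohort:
grades split 32.7 / 47.8 / 19.5%, 44.7% Ki67-positive lesions, near-saturated
hormone receptors, rare HER2 3+, and a time-intensity-curve archetype mix
with a sizeable persistent fraction. Rank-correlation targets default to the
moderate Ki67-SUV (+0.46) and weaker Ki67-ADC (-0.28) associations typical of
this setting.

The image-level generator renders small ellipsoidal lesion phantoms (PET hot
spot with Gaussian-profile uptake and sqrt-signal Gaussian noise; DCE phases
following the lesion's archetype; a DWI pair consistent with the lesion's ADC
floor under the two-point mono-exponential model, with Rician noise on all MR
volumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import histopath
from .volumes import DceSeries, ImageVolume, LesionMask

GRADE_NAMES = ("G1", "G2", "G3")

# -- fixed marginal shapes (chosen once; see docs/methods.md) ----------------
KI67_SIGMA = 0.65
KI67_POSITIVE_RATE = 0.447  # P(Ki67 >= 20)
KI67_MU = math.log(20.0) - KI67_SIGMA * sps.norm.ppf(1.0 - KI67_POSITIVE_RATE)
SUVMEAN_MEDIAN = 3.2
SUVMEAN_SIGMA = 0.5
SUVMAX_RATIO_RANGE = (1.4, 2.0)
ADCMIN_LOC, ADCMIN_SCALE = 1000.0, 170.0  # 1e-6 mm^2/s
ADCMIN_BOUNDS = (600.0, 1700.0)
ADCMEAN_RATIO_RANGE = (1.2, 1.5)
ER_NEGATIVE_RATE = 0.019
PGR_NEGATIVE_RATE = 0.013
ER_BETA = (2.0, 0.45)
PGR_BETA = (0.95, 0.6)
HER2_PROPORTIONS = {"0": 0.774, "1+": 0.107, "2+": 0.031, "3+": 0.088}
GRADE_NOISE_SD = 0.5  # latent noise between aggressiveness and grade
KI67_LOADING = 0.8  # factor loading of the Ki67 latent on aggressiveness

#: canonical noiseless TIC per archetype (used by the phantom renderer);
#: late slopes are -20%, 0% and +34% respectively.
CANONICAL_TIC = {
    "wash-out": (100.0, 190.0, 210.0, 190.0, 175.0, 160.0),
    "plateau": (100.0, 185.0, 205.0, 200.0, 196.0, 195.0),
    "persistent": (100.0, 150.0, 170.0, 185.0, 200.0, 215.0),
}


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose population Spearman
    correlation equals ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort."""

    n_lesions: int = 159
    grade_proportions: tuple[float, float, float] = (0.327, 0.478, 0.195)
    tic_archetype_mix: tuple[float, float, float] = (0.35, 0.26, 0.39)  # wash-out, plateau, persistent
    ki67_suv_target_rho: float = 0.46
    ki67_adc_target_rho: float = -0.28
    subtype_auc_target: float | None = None  # None: implied by the rho targets
    pet_noise_sd_scale: float = 0.05
    mr_rician_sigma: float = 3.0
    phase_interval_s: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 2:
            raise ValueError("n_lesions must be >= 2")
        for name in ("grade_proportions", "tic_archetype_mix"):
            probs = getattr(self, name)
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be three non-negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if any(p == 0 for p in self.grade_proportions):
            # aggressiveness effects are always configured through the grade link
            raise ValueError("degenerate config: a grade proportion is 0 while grade effects are configured")
        for name in ("ki67_suv_target_rho", "ki67_adc_target_rho"):
            rho = getattr(self, name)
            if not -1 <= rho <= 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
            if abs(_spearman_to_pearson(rho)) > KI67_LOADING + 1e-12:
                raise ValueError(f"{name}={rho} exceeds the attainable range of the one-factor model")
        if self.subtype_auc_target is not None and not 0.5 < self.subtype_auc_target < 1:
            raise ValueError("subtype_auc_target must lie in (0.5, 1)")
        if self.pet_noise_sd_scale < 0 or self.mr_rician_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if self.phase_interval_s <= 0:
            raise ValueError("phase interval must be positive")


@dataclass
class LatentLesion:
    """Latent state of one synthetic lesion."""

    lesion_id: str
    aggressiveness: float
    grade: str
    ki67_pct: float
    er_pct: float
    pgr_pct: float
    her2_score: str
    fish_amplified: bool | None
    tic_archetype: str
    true_suv_peak: float
    true_adc_floor: float

    @classmethod
    def from_row(cls, row) -> "LatentLesion":
        fish = row["fish_amplified"]
        if pd.isna(fish):
            fish = None
        else:
            fish = bool(fish)
        return cls(
            lesion_id=str(row["lesion_id"]),
            aggressiveness=float(row["aggressiveness"]),
            grade=str(row["grade"]),
            ki67_pct=float(row["ki67_pct"]),
            er_pct=float(row["er_pct"]),
            pgr_pct=float(row["pgr_pct"]),
            her2_score=str(row["her2_score"]),
            fish_amplified=fish,
            tic_archetype=str(row["tic_archetype"]),
            true_suv_peak=float(row["suv_max"]),
            true_adc_floor=float(row["adc_min"]),
        )


def _largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Integer class counts summing to n, closest to n * proportions."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _rank_map(z: np.ndarray, ppf) -> np.ndarray:
    """Impose a marginal by inverse-transform on plug-in uniforms of ranks."""
    n = z.size
    ranks = sps.rankdata(z, method="ordinal")
    return ppf((ranks - 0.5) / n)


def _ki67_positive_count(n: int) -> int:
    """Number of lesions with Ki67 >= 20 under the rank-mapped marginal."""
    u_cut = sps.norm.cdf((math.log(20.0) - KI67_MU) / KI67_SIGMA)
    return int(np.sum((np.arange(1, n + 1) - 0.5) / n >= u_cut))


def _solve_subtype_shift(rho_s_target: float, auc_target: float | None) -> tuple[float, float]:
    """Copula correlation and positive-class shift realizing the targets.

    Returns (pearson r between the Ki67 and SUV latents, delta added to the
    SUV latent of Ki67-positive lesions). With no AUC target the shift is 0
    and r is the exact sin-transformed Spearman target. With a target, delta
    is solved from the binormal two-group model of the SUV latent across the
    Ki67 dichotomy, and r is re-solved (treating the shifted latent as
    approximately Gaussian) so the rank-correlation target is preserved.
    """
    r0 = _spearman_to_pearson(rho_s_target)
    if auc_target is None:
        return r0, 0.0
    p = KI67_POSITIVE_RATE
    c = sps.norm.ppf(1.0 - p)
    phi_c = sps.norm.pdf(c)
    m1 = phi_c / p
    m0 = -phi_c / (1.0 - p)
    v1 = 1.0 + c * phi_c / p - m1 * m1
    v0 = 1.0 - c * phi_c / (1.0 - p) - m0 * m0

    def auc_of(r: float, delta: float) -> float:
        mean_gap = r * (m1 - m0) + delta
        var_sum = (1 - r * r + r * r * v1) + (1 - r * r + r * r * v0)
        return float(sps.norm.cdf(mean_gap / math.sqrt(var_sum)))

    def rho_eff(r: float, delta: float) -> float:
        # effective Spearman of (ki67 latent, shifted SUV latent)
        cov = r + delta * phi_c
        var = 1.0 + delta * delta * p * (1 - p) + 2.0 * r * delta * phi_c
        return 6.0 / math.pi * math.asin(min(1.0, max(-1.0, cov / math.sqrt(var))) / 2.0)

    r, delta = r0, 0.0
    for _ in range(50):  # fixed-point on the 2x2 system
        mean_gap_needed = sps.norm.ppf(auc_target) * math.sqrt(
            (1 - r * r + r * r * v1) + (1 - r * r + r * r * v0)
        )
        delta_new = mean_gap_needed - r * (m1 - m0)
        # re-solve r so the rank-correlation target is preserved
        lo, hi = -0.999, 0.999
        from scipy.optimize import brentq

        f = lambda rr: rho_eff(rr, delta_new) - rho_s_target
        try:
            r_new = brentq(f, lo, hi, xtol=1e-10)
        except ValueError:
            r_new = r
        if abs(r_new - r) < 1e-10 and abs(delta_new - delta) < 1e-10:
            r, delta = r_new, delta_new
            break
        r, delta = r_new, delta_new
    return r, delta


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a feature-level synthetic cohort.

    One row per lesion with latent fields, histopathology (including derived
    flags and subtype), and the VOI-level raw measurements the quantification
    stage consumes (suv_max/suv_mean, adc_min/adc_mean, si0..si5).
    """
    n = config.n_lesions
    rng = np.random.default_rng(config.seed)

    a = rng.standard_normal(n)  # aggressiveness
    e_k, e_s, e_a, e_g = (rng.standard_normal(n) for _ in range(4))

    r_suv, delta = _solve_subtype_shift(config.ki67_suv_target_rho, config.subtype_auc_target)
    r_adc = _spearman_to_pearson(config.ki67_adc_target_rho)
    lam_k = KI67_LOADING
    lam_s = r_suv / lam_k
    lam_a = r_adc / lam_k

    z_k = lam_k * a + math.sqrt(1 - lam_k**2) * e_k
    z_s = lam_s * a + math.sqrt(max(0.0, 1 - lam_s**2)) * e_s
    z_a = lam_a * a + math.sqrt(max(0.0, 1 - lam_a**2)) * e_a

    if delta != 0.0:
        n_pos = _ki67_positive_count(n)
        pos = sps.rankdata(z_k, method="ordinal") > n - n_pos
        z_s = z_s + delta * pos

    # grade: exact class counts, allocated by a noisy aggressiveness score
    counts = _largest_remainder_counts(n, config.grade_proportions)
    g_score = a + GRADE_NOISE_SD * e_g
    order = np.argsort(g_score, kind="stable")
    grade = np.empty(n, dtype=object)
    grade[order[: counts[0]]] = "G1"
    grade[order[counts[0] : counts[0] + counts[1]]] = "G2"
    grade[order[counts[0] + counts[1] :]] = "G3"

    # marginals by rank mapping
    ki67 = np.minimum(100.0, np.exp(KI67_MU + KI67_SIGMA * _rank_map(z_k, sps.norm.ppf)))
    suv_mean = np.exp(math.log(SUVMEAN_MEDIAN) + SUVMEAN_SIGMA * _rank_map(z_s, sps.norm.ppf))
    suv_max = suv_mean * rng.uniform(*SUVMAX_RATIO_RANGE, size=n)
    tn = sps.truncnorm(
        (ADCMIN_BOUNDS[0] - ADCMIN_LOC) / ADCMIN_SCALE,
        (ADCMIN_BOUNDS[1] - ADCMIN_LOC) / ADCMIN_SCALE,
        loc=ADCMIN_LOC,
        scale=ADCMIN_SCALE,
    )
    adc_min = _rank_map(z_a, tn.ppf)
    adc_mean = adc_min * rng.uniform(*ADCMEAN_RATIO_RANGE, size=n)

    # hormone receptors and HER2: independent of aggressiveness (bookkeeping)
    er = 100.0 * sps.beta(*ER_BETA).ppf((sps.rankdata(rng.standard_normal(n), method="ordinal") - 0.5) / n)
    pgr = 100.0 * sps.beta(*PGR_BETA).ppf((sps.rankdata(rng.standard_normal(n), method="ordinal") - 0.5) / n)
    n_er_neg = int(round(ER_NEGATIVE_RATE * n))
    n_pgr_neg = int(round(PGR_NEGATIVE_RATE * n))
    er[rng.choice(n, size=n_er_neg, replace=False)] = 0.0
    pgr[rng.choice(n, size=n_pgr_neg, replace=False)] = 0.0

    her2_counts = _largest_remainder_counts(n, list(HER2_PROPORTIONS.values()))
    her2 = np.repeat(list(HER2_PROPORTIONS.keys()), her2_counts)
    her2 = her2[rng.permutation(n)]
    fish = np.array([False if s == "2+" else None for s in her2], dtype=object)

    tic_counts = _largest_remainder_counts(n, config.tic_archetype_mix)
    archetype = np.repeat(["wash-out", "plateau", "persistent"], tic_counts)
    archetype = archetype[rng.permutation(n)]

    # VOI-level TIC raw measurements per archetype (independent of aggressiveness)
    si0 = rng.uniform(80.0, 120.0, size=n)
    e1_pct = rng.uniform(80.0, 220.0, size=n)
    si1 = si0 * (1.0 + e1_pct / 100.0)
    si2 = si1 * (1.0 + rng.uniform(-0.05, 0.25, size=n))
    slope_pct = np.empty(n)
    slope_pct[archetype == "wash-out"] = rng.uniform(-28.0, -12.0, size=int((archetype == "wash-out").sum()))
    slope_pct[archetype == "plateau"] = rng.uniform(-8.0, 8.0, size=int((archetype == "plateau").sum()))
    slope_pct[archetype == "persistent"] = rng.uniform(12.0, 45.0, size=int((archetype == "persistent").sum()))
    early = 0.5 * (si1 + si2)
    si5 = early * (1.0 + slope_pct / 100.0)
    si3 = si2 + (si5 - si2) * rng.uniform(0.2, 0.5, size=n)
    si4 = si2 + (si5 - si2) * rng.uniform(0.5, 0.9, size=n)

    table = pd.DataFrame(
        {
            "lesion_id": [f"L{i:04d}" for i in range(n)],
            "aggressiveness": a,
            "grade": grade,
            "ki67_pct": ki67,
            "er_pct": er,
            "pgr_pct": pgr,
            "her2_score": her2,
            "fish_amplified": fish,
            "tic_archetype": archetype,
            "suv_max": suv_max,
            "suv_mean": suv_mean,
            "adc_min": adc_min,
            "adc_mean": adc_mean,
            "si0": si0,
            "si1": si1,
            "si2": si2,
            "si3": si3,
            "si4": si4,
            "si5": si5,
        }
    )
    table["true_suv_peak"] = table["suv_max"]
    table["true_adc_floor"] = table["adc_min"]
    return histopath.augment_cohort(table)


# ---------------------------------------------------------------------------
# Image-level phantoms


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def render_lesion_volumes(
    lesion: LatentLesion,
    config: SyntheticConfig,
    shape: tuple[int, int, int] = (24, 24, 24),
    semi_axes_vox: tuple[float, float, float] = (5.0, 4.0, 3.0),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, DceSeries, tuple[ImageVolume, ImageVolume], LesionMask]:
    """Render the PET volume, DCE series, DWI pair and truth mask of a lesion.

    The lesion is an ellipsoid centred on the grid. PET uptake has a Gaussian
    radial profile with maximum ``true_suv_peak`` at the centre; DCE voxel
    curves follow the canonical archetype TIC scaled by a radial profile
    (ratio-based TIC descriptors are therefore exact at zero noise); the DWI
    pair encodes an ADC field rising from ``true_adc_floor`` at the core.
    """
    if any(s > 32 for s in shape):
        raise ValueError("phantom grids are capped at 32 voxels per axis")
    if any(2 * ax + 3 > s for ax, s in zip(semi_axes_vox, shape)):
        raise ValueError("grid too small to contain the lesion")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    center = (np.asarray(shape) - 1) / 2.0
    # centre on an integer voxel so the exact peak value is attained
    center = np.floor(center)
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[k] - center[k]) / semi_axes_vox[k]) ** 2 for k in range(3))
    inside = r2 <= 1.0
    mask = LesionMask(inside, spacing, (0.0, 0.0, 0.0), provenance="truth")

    profile = np.exp(-r2)  # 1 at the core, ~0.37 at the ellipsoid boundary

    pet_bg = 0.3
    # r2 = 0 at the (integer) centre voxel, so the maximum equals the peak
    pet = np.where(inside, pet_bg + (lesion.true_suv_peak - pet_bg) * profile, pet_bg)
    if config.pet_noise_sd_scale > 0:
        pet = pet + rng.normal(0.0, 1.0, shape) * config.pet_noise_sd_scale * np.sqrt(np.maximum(pet, 0.0))
    pet_vol = ImageVolume(pet, spacing, (0.0, 0.0, 0.0), "PET_SUV")

    tic = CANONICAL_TIC[lesion.tic_archetype]
    dce_bg = 30.0
    phases = []
    for si in tic:
        vol = np.where(inside, si * profile, dce_bg)
        phases.append(ImageVolume(_rician(vol, config.mr_rician_sigma, rng), spacing, (0.0, 0.0, 0.0), "DCE_SI"))
    series = DceSeries(phases, config.phase_interval_s)

    adc_field = np.where(inside, lesion.true_adc_floor * (1.0 + 0.6 * r2), 1800.0)
    s0 = np.where(inside, 800.0, 400.0)
    s1000 = s0 * np.exp(-1000.0 * adc_field * 1e-6)
    dwi_b0 = ImageVolume(_rician(s0, config.mr_rician_sigma, rng), spacing, (0.0, 0.0, 0.0), "DWI")
    dwi_b1000 = ImageVolume(_rician(s1000, config.mr_rician_sigma, rng), spacing, (0.0, 0.0, 0.0), "DWI")

    return pet_vol, series, (dwi_b0, dwi_b1000), mask
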