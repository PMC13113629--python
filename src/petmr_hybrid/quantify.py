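"""Imaging-parameter extraction: 9 single-modality + 14 hybrid PET/MRI values.

Single-modality inventory: SUVmax, SUVmean (PET); E1, ESER, Slope, SPER, SFER
(semi-quantitative DCE-MRI time-intensity-curve descriptors); ADCmin, ADCmean
(DWI). Hybrids multiply SUV by the TIC descriptors that increase in malignant
lesions (E1, ESER, SPER, SFER) and divide SUV by those that decrease (Slope,
ADCmin, ADCmean), so that every hybrid value grows with malignancy.

Parameters with an undefined denominator are marked invalid (NaN) per lesion
and per parameter; the lesion is retained for all other parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volumes import DceSeries, ImageVolume, LesionMask

SINGLE_PARAMS = (
    "SUVmax",
    "SUVmean",
    "E1",
    "ESER",
    "Slope",
    "SPER",
    "SFER",
    "ADCmin",
    "ADCmean",
)

HYBRID_PARAMS = (
    "SUVmax*E1",
    "SUVmean*E1",
    "SUVmax*ESER",
    "SUVmean*ESER",
    "SUVmax/Slope",
    "SUVmean/Slope",
    "SUVmax*SPER",
    "SUVmean*SPER",
    "SUVmax*SFER",
    "SUVmean*SFER",
    "SUVmax/ADCmin",
    "SUVmean/ADCmin",
    "SUVmax/ADCmean",
    "SUVmean/ADCmean",
)

FEATURE_NAMES = SINGLE_PARAMS + HYBRID_PARAMS

#: +1 if higher values indicate malignancy/aggressiveness, -1 otherwise.
#: Only the raw ADC statistics decrease in aggressive tissue; every hybrid is
#: constructed to increase.
FEATURE_DIRECTIONS = {name: (-1 if name in ("ADCmin", "ADCmean") else +1) for name in FEATURE_NAMES}

TIC_CLASSES = ("wash-out", "plateau", "persistent")


class LesionExcludedError(ValueError):
    """A lesion cannot enter the analysis; carries the exclusion reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class TICSummary:
    """Mean VOI signal intensity at each of the six DCE phases."""

    si: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        self.si = tuple(float(v) for v in self.si)
        if len(self.si) != 6:
            raise ValueError("a TIC summary holds exactly six phase means")
        if not all(math.isfinite(v) for v in self.si):
            raise ValueError("phase means must be finite")

    @property
    def si_peak(self) -> float:
        """Peak (maximum) enhancement among the six phases, pre-contrast
        included."""
        return max(self.si)

    def __getitem__(self, k: int) -> float:
        return self.si[k]


@dataclass
class DceParams:
    e1: float
    eser: float
    slope: float
    sper: float
    sfer: float
    curve_type: str | None = None

    def __post_init__(self) -> None:
        if self.curve_type is None:
            self.curve_type = classify_tic(self.slope)


@dataclass
class PetParams:
    suv_max: float
    suv_mean: float


@dataclass
class AdcParams:
    adc_min: float
    adc_mean: float


@dataclass
class FeatureVector:
    """The 23 named imaging parameters of one lesion (NaN = invalid)."""

    values: dict[str, float]
    curve_type: str | None = None

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature inventory mismatch: missing={missing}, extra={extra}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def n_single(self) -> int:
        return len(SINGLE_PARAMS)

    @property
    def n_hybrid(self) -> int:
        return len(HYBRID_PARAMS)


def tic_summary(series: DceSeries, mask: LesionMask) -> TICSummary:
    """Per-phase mean signal intensity inside the VOI."""
    if mask.shape != series.grid.shape:
        raise ValueError("mask is not on the DCE grid")
    if not mask.data.any():
        raise ValueError("empty mask")
    return TICSummary(tuple(float(ph.data[mask.data].mean()) for ph in series.phases))


def e1(t: TICSummary) -> float:
    """First post-contrast signal-enhancement percentage,
    100 * (SI1 - SI0) / SI0."""
    if t[0] == 0:
        return math.nan
    return 100.0 * (t[1] - t[0]) / t[0]


def eser(t: TICSummary) -> float:
    """Early signal enhancement ratio, 100 * (SI1 - SI0) / (SI2 - SI0)."""
    if t[2] == t[0]:
        return math.nan
    return 100.0 * (t[1] - t[0]) / (t[2] - t[0])


def slope(t: TICSummary) -> float:
    """Late slope in percent: 100 * (SI5 - mean(SI1, SI2)) / mean(SI1, SI2)."""
    early = 0.5 * (t[1] + t[2])
    if early == 0:
        return math.nan
    return 100.0 * (t[5] - early) / early


def sper(t: TICSummary) -> float:
    """Signal peak enhancement ratio, (SIpeak - SI0) / (SI5 - SI0)."""
    if t[5] == t[0]:
        return math.nan
    return (t.si_peak - t[0]) / (t[5] - t[0])


def sfer(t: TICSummary) -> float:
    """Signal first enhancement ratio, (SI1 - SI0) / (SI5 - SI0)."""
    if t[5] == t[0]:
        return math.nan
    return (t[1] - t[0]) / (t[5] - t[0])


def classify_tic(slope_value: float) -> str | None:
    """Curve-type partition by the late slope: wash-out below -10%, plateau
    within [-10%, 10%] (closed on both boundaries), persistent above 10%."""
    if not math.isfinite(slope_value):
        return None
    if slope_value < -10.0:
        return "wash-out"
    if slope_value <= 10.0:
        return "plateau"
    return "persistent"


def dce_params(t: TICSummary) -> DceParams:
    return DceParams(e1(t), eser(t), slope(t), sper(t), sfer(t))


def pet_params(pet: ImageVolume, mask: LesionMask) -> PetParams:
    if mask.shape != pet.shape:
        raise ValueError("mask is not on the PET grid")
    vals = pet.data[mask.data]
    if vals.size == 0:
        raise ValueError("empty mask")
    return PetParams(float(vals.max()), float(vals.mean()))


def adc_params(adc: ImageVolume, mask: LesionMask) -> AdcParams:
    """Min/mean ADC over valid (finite) voxels; lesions without any valid ADC
    voxel are excluded."""
    if mask.shape != adc.shape:
        raise ValueError("mask is not on the ADC grid")
    vals = adc.data[mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise LesionExcludedError("unsatisfied fat suppression / no valid ADC voxels")
    return AdcParams(float(vals.min()), float(vals.mean()))


def suv_from_activity(conc_kbq_ml: float, injected_mbq: float, weight_kg: float) -> float:
    """Body-weight-normalized SUV from an activity concentration.

    SUV = C[kBq/mL] * weight[kg] / injected[MBq]; the kBq/MBq and g/mL factors
    cancel under the 1 g/mL tissue-density convention.
    """
    if conc_kbq_ml <= 0 or injected_mbq <= 0 or weight_kg <= 0:
        raise ValueError("activity concentration, dose and weight must be positive")
    return conc_kbq_ml * weight_kg / injected_mbq


def hybrid_params(p: PetParams, d: DceParams, a: AdcParams) -> dict[str, float]:
    """The 14 hybrid PET/MRI products and ratios.

    An invalid component (NaN) or a zero denominator propagates to NaN for the
    affected hybrids only.
    """
    out: dict[str, float] = {}
    for suv_name, suv in (("SUVmax", p.suv_max), ("SUVmean", p.suv_mean)):
        for comp_name, comp in (("E1", d.e1), ("ESER", d.eser), ("SPER", d.sper), ("SFER", d.sfer)):
            out[f"{suv_name}*{comp_name}"] = suv * comp
        for comp_name, comp in (("Slope", d.slope), ("ADCmin", a.adc_min), ("ADCmean", a.adc_mean)):
            out[f"{suv_name}/{comp_name}"] = suv / comp if (math.isfinite(comp) and comp != 0) else math.nan
    return {name: out[name] for name in HYBRID_PARAMS}


def assemble_features(
    pet: PetParams | None,
    dce: DceParams | None,
    adc: AdcParams | None,
) -> FeatureVector:
    """Full 23-entry feature vector for one lesion.

    A missing modality excludes the lesion outright (with a reason mirroring
    the clinical workflow); per-parameter invalidity within a present modality
    only invalidates the affected entries.
    """
    if pet is None or dce is None:
        raise LesionExcludedError("not visible in DCE or in PET")
    if adc is None:
        raise LesionExcludedError("unsatisfied fat suppression / no valid ADC voxels")
    values: dict[str, float] = {
        "SUVmax": pet.suv_max,
        "SUVmean": pet.suv_mean,
        "E1": dce.e1,
        "ESER": dce.eser,
        "Slope": dce.slope,
        "SPER": dce.sper,
        "SFER": dce.sfer,
        "ADCmin": adc.adc_min,
        "ADCmean": adc.adc_mean,
    }
    values.update(hybrid_params(pet, dce, adc))
    return FeatureVector(values, curve_type=dce.curve_type)


def features_from_measurements(row) -> FeatureVector:
    """Feature vector from VOI-level raw measurements (a mapping or pandas row
    with keys si0..si5, suv_max, suv_mean, adc_min, adc_mean)."""
    required = ["si0", "si1", "si2", "si3", "si4", "si5", "suv_max", "suv_mean", "adc_min", "adc_mean"]
    vals = {}
    for key in required:
        v = row[key] if not hasattr(row, "get") else row.get(key, math.nan)
        vals[key] = float(v) if v is not None else math.nan
    if any(not math.isfinite(vals[k]) for k in ("suv_max", "suv_mean")) or any(
        not math.isfinite(vals[f"si{i}"]) for i in range(6)
    ):
        raise LesionExcludedError("not visible in DCE or in PET")
    if not math.isfinite(vals["adc_min"]) or not math.isfinite(vals["adc_mean"]):
        raise LesionExcludedError("unsatisfied fat suppression / no valid ADC voxels")
    tic = TICSummary(tuple(vals[f"si{i}"] for i in range(6)))
    return assemble_features(
        PetParams(vals["suv_max"], vals["suv_mean"]),
        dce_params(tic),
        AdcParams(vals["adc_min"], vals["adc_mean"]),
    )
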