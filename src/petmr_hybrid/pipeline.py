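"""End-to-end orchestration: simulate -> segment -> quantify -> statistics.

A run is reproducible from its persisted flat key=value config; every lesion
that drops out is logged with a machine-readable reason, and the flow summary
(totals by reason plus the retained count) mirrors a clinical
inclusion/exclusion flowchart.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import histopath
from .quantify import (
    FEATURE_NAMES,
    LesionExcludedError,
    adc_params,
    dce_params,
    features_from_measurements,
    pet_params,
    tic_summary,
)
from .segmentation import adc_map, segment_pet_voi
from .stats import DEFAULT_CI_LEVEL, run_univariate_battery
from .synthetic import LatentLesion, SyntheticConfig, generate_cohort, render_lesion_volumes

#: exclusion reason categories
REASON_NO_ADC = "unsatisfied fat suppression / no valid ADC voxels"
REASON_NOT_VISIBLE = "not visible in DCE or in PET"
REASON_INCOMPLETE_HISTO = "incomplete histopathology"

HISTO_COLUMNS = ["lesion_id", "grade", "er_pct", "pgr_pct", "ki67_pct", "her2_score", "fish_amplified"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort_csv: str | None = None  # when set, load instead of simulating
    threshold_fraction: float = 0.40
    b_low: float = 0.0
    b_high: float = 1000.0
    render_images: bool = False  # exercise the image-level path (slower)
    ci_level: float = DEFAULT_CI_LEVEL
    output_dir: str = "petmr_run"

    def to_flat(self) -> dict[str, str]:
        flat = {
            "cohort_csv": self.cohort_csv or "",
            "threshold_fraction": repr(self.threshold_fraction),
            "b_low": repr(self.b_low),
            "b_high": repr(self.b_high),
            "render_images": str(self.render_images),
            "ci_level": repr(self.ci_level),
            "output_dir": self.output_dir,
        }
        s = self.synthetic
        flat.update(
            {
                "n_lesions": str(s.n_lesions),
                "grade_proportions": ",".join(repr(p) for p in s.grade_proportions),
                "tic_archetype_mix": ",".join(repr(p) for p in s.tic_archetype_mix),
                "ki67_suv_target_rho": repr(s.ki67_suv_target_rho),
                "ki67_adc_target_rho": repr(s.ki67_adc_target_rho),
                "subtype_auc_target": "" if s.subtype_auc_target is None else repr(s.subtype_auc_target),
                "pet_noise_sd_scale": repr(s.pet_noise_sd_scale),
                "mr_rician_sigma": repr(s.mr_rician_sigma),
                "phase_interval_s": repr(s.phase_interval_s),
                "seed": str(s.seed),
            }
        )
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "RunConfig":
        def triple(s: str):
            return tuple(float(v) for v in s.split(","))

        syn = SyntheticConfig(
            n_lesions=int(flat.get("n_lesions", 159)),
            grade_proportions=triple(flat.get("grade_proportions", "0.327,0.478,0.195")),
            tic_archetype_mix=triple(flat.get("tic_archetype_mix", "0.35,0.26,0.39")),
            ki67_suv_target_rho=float(flat.get("ki67_suv_target_rho", 0.46)),
            ki67_adc_target_rho=float(flat.get("ki67_adc_target_rho", -0.28)),
            subtype_auc_target=(float(flat["subtype_auc_target"]) if flat.get("subtype_auc_target") else None),
            pet_noise_sd_scale=float(flat.get("pet_noise_sd_scale", 0.05)),
            mr_rician_sigma=float(flat.get("mr_rician_sigma", 3.0)),
            phase_interval_s=float(flat.get("phase_interval_s", 90.0)),
            seed=int(flat["seed"]),
        )
        return cls(
            synthetic=syn,
            cohort_csv=flat.get("cohort_csv") or None,
            threshold_fraction=float(flat.get("threshold_fraction", 0.40)),
            b_low=float(flat.get("b_low", 0.0)),
            b_high=float(flat.get("b_high", 1000.0)),
            render_images=flat.get("render_images", "False") == "True",
            ci_level=float(flat.get("ci_level", DEFAULT_CI_LEVEL)),
            output_dir=flat.get("output_dir", "petmr_run"),
        )


def write_flat_config(flat: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}={v}\n" for k, v in sorted(flat.items())))


def read_flat_config(path: str | Path) -> dict[str, str]:
    flat = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        flat[key.strip()] = value.strip()
    return flat


def extract_features_table(cohort: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature rows and exclusion log from a cohort table.

    In the feature-level path the cohort's VOI-level raw measurements are
    consumed directly; in the image-level path each lesion is rendered,
    PET-segmented at the configured threshold and quantified from its volumes.
    """
    rows = []
    exclusions = []
    for _, row in cohort.iterrows():
        if any(pd.isna(row.get(c)) for c in ("grade", "er_pct", "pgr_pct", "ki67_pct", "her2_score")):
            exclusions.append({"lesion_id": row["lesion_id"], "reason": REASON_INCOMPLETE_HISTO})
            continue
        try:
            if config.render_images:
                lesion = LatentLesion.from_row(row)
                pet_vol, series, (b0, b1000), truth = render_lesion_volumes(lesion, config.synthetic)
                voi = segment_pet_voi(pet_vol, truth, config.threshold_fraction)
                adc_vol = adc_map(b0, b1000, config.b_low, config.b_high)
                fv_pet = pet_params(pet_vol, voi)
                fv_dce = dce_params(tic_summary(series, truth))
                fv_adc = adc_params(adc_vol, truth)
                from .quantify import assemble_features

                fv = assemble_features(fv_pet, fv_dce, fv_adc)
            else:
                fv = features_from_measurements(row)
        except LesionExcludedError as err:
            exclusions.append({"lesion_id": row["lesion_id"], "reason": err.reason})
            continue
        rec = {"lesion_id": row["lesion_id"], **fv.values, "curve_type": fv.curve_type}
        rows.append(rec)
    features = pd.DataFrame(rows, columns=["lesion_id", *FEATURE_NAMES, "curve_type"])
    excl = pd.DataFrame(exclusions, columns=["lesion_id", "reason"])
    return features, excl


def cohort_flow_summary(inclusion: pd.DataFrame, total: int | None = None) -> dict:
    """Totals by exclusion reason and the final retained count.

    ``inclusion`` holds one row per excluded lesion with a ``reason`` column;
    ``total`` defaults to excluded + retained rows when a ``retained`` count
    cannot be inferred, so pass the full cohort size explicitly when the table
    only lists exclusions.
    """
    by_reason = inclusion["reason"].value_counts().to_dict() if len(inclusion) else {}
    n_excluded = int(sum(by_reason.values()))
    if total is None:
        total = n_excluded
    retained = total - n_excluded
    if retained < 0:
        raise ValueError("more exclusions than lesions")
    return {"total": int(total), "excluded_by_reason": by_reason, "n_excluded": n_excluded, "retained": int(retained)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes cohort.csv, features.csv, correlations.csv, cross_correlations.csv,
    comparisons.csv, roc.csv, exclusions.csv, flow.json, config.txt and a
    plain-text summary into ``config.output_dir``. Returns the in-memory
    results keyed by the same names.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv)
        cohort = histopath.augment_cohort(cohort)
    else:
        cohort = generate_cohort(config.synthetic)
    features, exclusions = extract_features_table(cohort, config)
    flow = cohort_flow_summary(exclusions, total=len(cohort))
    histo = cohort[cohort["lesion_id"].isin(features["lesion_id"])][
        [c for c in cohort.columns if c in HISTO_COLUMNS + ["er_pos", "pgr_pos", "ki67_pos", "her2_pos", "subtype"]]
    ]
    battery = run_univariate_battery(features, histo, ci_level=config.ci_level)

    cohort.to_csv(out / "cohort.csv", index=False)
    features.to_csv(out / "features.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    battery.correlations.to_csv(out / "correlations.csv", index=False)
    if battery.cross_correlations is not None:
        battery.cross_correlations.to_csv(out / "cross_correlations.csv", index=False)
    battery.comparisons.to_csv(out / "comparisons.csv", index=False)
    if battery.roc is not None:
        battery.roc.to_csv(out / "roc.csv", index=False)
    (out / "flow.json").write_text(json.dumps(flow, indent=2, sort_keys=True))
    write_flat_config(config.to_flat(), out / "config.txt")

    lines = [
        f"lesions simulated/loaded: {flow['total']}",
        f"lesions retained: {flow['retained']}",
        *(f"excluded ({k}): {v}" for k, v in sorted(flow["excluded_by_reason"].items())),
        f"feature inventory: {len(FEATURE_NAMES)} parameters per lesion",
        f"comparisons: {len(battery.comparisons)} parameter x contrast rows",
    ]
    for w in battery.warnings:
        lines.append(f"warning: {w}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "cohort": cohort,
        "features": features,
        "exclusions": exclusions,
        "flow": flow,
        "battery": battery,
    }
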