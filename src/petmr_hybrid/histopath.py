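"""Tissue-biomarker dichotomization and surrogate molecular subtype rules.

ER and PgR are positive when strictly above 0%; Ki67 is positive at >= 20%;
HER2 is negative at score 0/1+, positive at 3+, and resolved by FISH
amplification at 2+ (undetermined without a FISH result). Surrogate subtypes
follow the standard immunohistochemistry conventions; only luminal A and
luminal B enter the statistics, the remaining classes are cohort bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GRADES = ("G1", "G2", "G3")
HER2_SCORES = ("0", "1+", "2+", "3+")
KI67_CUTOFF = 20.0

SUBTYPES = (
    "luminalA",
    "luminalB",
    "luminalB_her2pos",
    "triple_negative",
    "her2pos",
    "unclassified",
)


@dataclass
class HistopathRecord:
    grade: str
    er_pct: float
    pgr_pct: float
    ki67_pct: float
    her2_score: str
    fish_amplified: bool | None = None

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}")
        self.her2_score = str(self.her2_score)
        if self.her2_score not in HER2_SCORES:
            raise ValueError(f"HER2 score must be one of {HER2_SCORES}")
        for name in ("er_pct", "pgr_pct", "ki67_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")

    @property
    def er_pos(self) -> bool:
        return self.er_pct > 0

    @property
    def pgr_pos(self) -> bool:
        return self.pgr_pct > 0

    @property
    def ki67_pos(self) -> bool:
        return self.ki67_pct >= KI67_CUTOFF

    @property
    def her2_pos(self) -> bool | None:
        """None when a 2+ score lacks a FISH result (undetermined)."""
        if self.her2_score in ("0", "1+"):
            return False
        if self.her2_score == "3+":
            return True
        return self.fish_amplified  # 2+: FISH decides; None if absent


def dichotomize(record: HistopathRecord) -> dict[str, bool | None]:
    """Derived positivity flags for one record."""
    return {
        "er_pos": record.er_pos,
        "pgr_pos": record.pgr_pos,
        "ki67_pos": record.ki67_pos,
        "her2_pos": record.her2_pos,
    }


def surrogate_subtype(record: HistopathRecord) -> str:
    """Surrogate molecular subtype from the derived flags.

    luminal A: ER and/or PgR positive, HER2 negative, Ki67 < 20%;
    luminal B: ER and/or PgR positive, HER2 negative, Ki67 >= 20%;
    luminal B HER2+: hormone-receptor positive with HER2 positive;
    triple negative / HER2+: hormone-receptor negative, split on HER2.
    An undetermined HER2 status leaves the record unclassified.
    """
    her2 = record.her2_pos
    if her2 is None:
        return "unclassified"
    hr_pos = record.er_pos or record.pgr_pos
    if hr_pos:
        if her2:
            return "luminalB_her2pos"
        return "luminalB" if record.ki67_pos else "luminalA"
    return "her2pos" if her2 else "triple_negative"


def augment_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived flag and subtype columns to a cohort table.

    Expects columns grade, er_pct, pgr_pct, ki67_pct, her2_score and an
    optional fish_amplified column.
    """
    out = table.copy()
    flags = []
    subtypes = []
    for _, row in table.iterrows():
        fish = row.get("fish_amplified", None)
        if pd.isna(fish):
            fish = None
        else:
            fish = bool(fish)
        rec = HistopathRecord(
            grade=row["grade"],
            er_pct=float(row["er_pct"]),
            pgr_pct=float(row["pgr_pct"]),
            ki67_pct=float(row["ki67_pct"]),
            her2_score=str(row["her2_score"]),
            fish_amplified=fish,
        )
        flags.append(dichotomize(rec))
        subtypes.append(surrogate_subtype(rec))
    for key in ("er_pos", "pgr_pos", "ki67_pos", "her2_pos"):
        out[key] = [f[key] for f in flags]
    out["subtype"] = subtypes
    return out
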