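"""Error counts and asymmetry/productivity/efficiency coefficients.

Scoring is per-side, per-trial, independent:

* a presented side absent from the report is a miss — counted into LSU/RSU on
  unilateral trials, LSB/RSB on bilateral trials, and into the presented
  position's omission counter;
* a reported side with no circle there is a spatial hallucination (allochiria
  index), counted into RH/LH — such opportunities exist only on unilateral
  trials of the opposite side;
* a digit report that is wrong or indefinite is a digit error, counted into
  NIR/NIL by the presented side on unilateral trials and into NIB on
  bilateral trials.

Seven coefficients summarize the counts.  With ``BP`` bilateral trials and
``LP`` lateralized presentations per side (33 and 54 for the standard
protocol):

    KA_bilateral  = (LSB - RSB) / (2*BP - RSB - LSB)
    KPrR_bilateral = (BP - RSB) / BP
    KPrL_bilateral = (BP - LSB) / BP
    KA_all  = (LSB + LSU - RSB - RSU) / (2*LP - RSB - RSU - LSB - LSU)
    KEf_all = (D - H) / (D + H),  D = 2*LP - all misses,  H = RH + LH
    KPrR_all = (LP - RSB - RSU) / LP
    KPrL_all = (LP - LSB - LSU) / LP

KA coefficients live in [-1, 1] (0 = no lateral bias, +1 = complete left
neglect); KPr in [0, 1] (share of circles caught on a side); KEf in (-1, 1]
(detections vs mislocalizations).  A zero denominator yields the tagged
missing value ``None`` with a warning, never a silent clamp.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

from .protocol import (
    ProtocolConstants,
    configurations_by_id,
    derive_constants,
    positions_by_id,
    SIX_PRESENTATION_IDS,
)
from .session import INDEFINITE, SessionRecord, validate_session

#: flat-export column order, matching the raw-database vocabulary
SCORE_COLUMNS = [
    "RSU", "LSU", "RSB", "LSB", "RH", "LH", "NIR", "NIL", "NIB",
    "KA_bilateral", "KPrR_bilateral", "KPrL_bilateral",
    "KA_all", "KEf_all", "KPrR_all", "KPrL_all",
]


class UndefinedCoefficientWarning(UserWarning):
    """A coefficient's denominator was zero; the value is reported as None."""


@dataclass
class ScoreSheet:
    """All per-session variables: counts, per-position omissions, coefficients."""

    position_omissions: dict[int, int]
    position_max: dict[int, int]
    RSU: int
    LSU: int
    RSB: int
    LSB: int
    RH: int
    LH: int
    NIR: int
    NIL: int
    NIB: int
    KA_bilateral: float | None
    KPrR_bilateral: float | None
    KPrL_bilateral: float | None
    KA_all: float | None
    KEf_all: float | None
    KPrR_all: float | None
    KPrL_all: float | None
    constants: ProtocolConstants
    subject_id: str = ""

    def as_row(self) -> dict:
        """Flat dict of the summary counts and coefficients."""
        row = {"subject_id": self.subject_id}
        for name in SCORE_COLUMNS:
            row[name] = getattr(self, name)
        for pid in sorted(self.position_omissions):
            row[f"pos_{pid}"] = self.position_omissions[pid]
        return row

    def to_json(self) -> str:
        row = self.as_row()
        row["position_max"] = {str(k): v for k, v in self.position_max.items()}
        row["BP"] = self.constants.bp
        row["LP"] = self.constants.lp
        return json.dumps(row, indent=1)


def _undefined(name: str) -> None:
    warnings.warn(f"{name} is undefined (zero denominator)", UndefinedCoefficientWarning,
                  stacklevel=3)
    return None


def ka_bilateral(LSB: int, RSB: int, BP: int) -> float | None:
    """Asymmetry of misses under bilateral presentation, in [-1, 1]."""
    if not (0 <= LSB <= BP and 0 <= RSB <= BP):
        raise ValueError("miss counts must lie in [0, BP]")
    denom = 2 * BP - RSB - LSB
    if denom == 0:
        return _undefined("KA_bilateral")
    return (LSB - RSB) / denom


def ka_all(LSU: int, LSB: int, RSU: int, RSB: int, LP: int) -> float | None:
    """Overall miss asymmetry over unilateral + bilateral trials, in [-1, 1]."""
    if not (0 <= LSU + LSB <= LP and 0 <= RSU + RSB <= LP):
        raise ValueError("per-side miss totals must lie in [0, LP]")
    denom = 2 * LP - RSB - RSU - LSB - LSU
    if denom == 0:
        return _undefined("KA_all")
    return (LSB + LSU - RSB - RSU) / denom


def kef_all(LSU: int, LSB: int, RSU: int, RSB: int, RH: int, LH: int,
            LP: int) -> float | None:
    """Efficiency: detections vs spatial-mislocalization reports, in (-1, 1]."""
    if min(LSU, LSB, RSU, RSB, RH, LH) < 0:
        raise ValueError("counts must be non-negative")
    if LSU + LSB > LP or RSU + RSB > LP:
        raise ValueError("per-side miss totals must lie in [0, LP]")
    detections = 2 * LP - RSB - RSU - LSB - LSU
    hallucinations = RH + LH
    denom = detections + hallucinations
    if denom == 0:
        return _undefined("KEf_all")
    return (detections - hallucinations) / denom


def kpr(side: Literal["left", "right"], scope: Literal["bilateral", "all"],
        sheet: "ScoreSheet") -> float:
    """Productivity: share of circles caught on a side, in [0, 1]."""
    miss_bi = sheet.LSB if side == "left" else sheet.RSB
    miss_uni = sheet.LSU if side == "left" else sheet.RSU
    if scope == "bilateral":
        return (sheet.constants.bp - miss_bi) / sheet.constants.bp
    return (sheet.constants.lp - miss_bi - miss_uni) / sheet.constants.lp


def _kpr_from_counts(miss_bi: int, miss_uni: int, bp: int, lp: int,
                     scope: str) -> float:
    if scope == "bilateral":
        return (bp - miss_bi) / bp
    return (lp - miss_bi - miss_uni) / lp


def score_session(record: SessionRecord) -> ScoreSheet:
    """Score a full session into a :class:`ScoreSheet`.

    Raises ``ValueError`` if the record fails validation. BP and LP are
    recounted from the record's own schedule so truncated or non-standard
    protocols score correctly.
    """
    problems = validate_session(record)
    if problems:
        raise ValueError("invalid session: " + "; ".join(problems))
    constants = derive_constants(record.schedule)
    configs = configurations_by_id()
    positions = positions_by_id()

    presentation_counts = {pid: 0 for pid in positions}
    omissions = {pid: 0 for pid in positions}
    RSU = LSU = RSB = LSB = RH = LH = NIR = NIL = NIB = 0

    for trial, resp in zip(record.schedule.trials, record.responses):
        config = configs[trial.config_id]
        shown = {positions[pid].side for pid in config.position_ids}
        bilateral = config.bilateral
        for pid in config.position_ids:
            side = positions[pid].side
            presentation_counts[pid] += 1
            if side not in resp.reported_sides:
                omissions[pid] += 1
                if side == "left":
                    if bilateral:
                        LSB += 1
                    else:
                        LSU += 1
                else:
                    if bilateral:
                        RSB += 1
                    else:
                        RSU += 1
        for side in resp.reported_sides - shown:
            if side == "right":
                RH += 1
            else:
                LH += 1
        digit_error = resp.reported_digit == INDEFINITE or resp.reported_digit != trial.digit
        if digit_error:
            if bilateral:
                NIB += 1
            elif shown == {"right"}:
                NIR += 1
            else:
                NIL += 1

    bp, lp = constants.bp, constants.lp
    sheet = ScoreSheet(
        position_omissions=omissions,
        position_max=presentation_counts,
        RSU=RSU, LSU=LSU, RSB=RSB, LSB=LSB, RH=RH, LH=LH,
        NIR=NIR, NIL=NIL, NIB=NIB,
        KA_bilateral=ka_bilateral(LSB, RSB, bp),
        KPrR_bilateral=_kpr_from_counts(RSB, RSU, bp, lp, "bilateral"),
        KPrL_bilateral=_kpr_from_counts(LSB, LSU, bp, lp, "bilateral"),
        KA_all=ka_all(LSU, LSB, RSU, RSB, lp),
        KEf_all=kef_all(LSU, LSB, RSU, RSB, RH, LH, lp),
        KPrR_all=_kpr_from_counts(RSB, RSU, bp, lp, "all"),
        KPrL_all=_kpr_from_counts(LSB, LSU, bp, lp, "all"),
        constants=constants,
        subject_id=record.subject_id,
    )
    return sheet


def omission_percentages(sheet: ScoreSheet) -> dict[int, float]:
    """Per-position omissions as percent of that position's presentations.

    For the standard protocol the maxima are 6 (positions 2, 5, 7, 9, 12, 14)
    and 9 (all others).
    """
    out = {}
    for pid, count in sheet.position_omissions.items():
        mx = sheet.position_max.get(pid, 0)
        out[pid] = 100.0 * count / mx if mx else 0.0
    return out
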