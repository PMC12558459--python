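"""Generative model of dual-task performance for testing every analysis
stage without clinical data.

A subject is a :class:`PatientProfile` of Bernoulli parameters. Each
presented circle is detected independently with probability

    p = p_base(side) * vertical_penalty^[y < 0] * extinction_penalty^[bilateral & left]

so a left-lateralized deficit is a low ``p_base_left``, a lower-field bias a
``vertical_penalty`` below 1, and visual extinction (left circles lost only
under bilateral competition) an ``extinction_penalty`` below 1. On unilateral
trials the absent side is falsely reported ("hallucinated", the allochiria
index) with its own per-opportunity probability. The central digit is
reported correctly with a per-trial-kind probability; a failed digit report
is, with equal probability, a uniformly wrong digit or an indefinite answer.

``expected_scoresheet`` gives the analytic expectations of all nine counts
(sums of Bernoulli means over a schedule) and plug-in coefficients; the
Monte-Carlo tests check the simulator against it. Two built-in presets,
calibrated in closed form against published group-mean productivity
coefficients (neglect group: KPrL_bilateral 0.097, KPrL_all 0.145,
KPrR_all 0.800; no-neglect group: 0.759, 0.767, 0.881), generate cohorts
with and without neglect structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .protocol import (
    Schedule,
    TargetPosition,
    configurations_by_id,
    derive_constants,
    generate_main_schedule,
    positions_by_id,
)
from .session import INDEFINITE, SessionRecord, TrialResponse


@dataclass(frozen=True)
class PatientProfile:
    """Bernoulli parameters governing one subject's responses."""

    p_base_left: float = 1.0
    p_base_right: float = 1.0
    vertical_penalty: float = 1.0
    extinction_penalty: float = 1.0
    h_right: float = 0.0
    h_left: float = 0.0
    d_correct_uni: float = 1.0
    d_correct_bi: float = 1.0
    label: Literal["neglect", "no_neglect"] = "no_neglect"

    def __post_init__(self):
        for name in ("p_base_left", "p_base_right", "vertical_penalty",
                     "extinction_penalty", "h_right", "h_left",
                     "d_correct_uni", "d_correct_bi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def detection_probability(profile: PatientProfile, position: TargetPosition,
                          bilateral: bool) -> float:
    """Detection probability for one presented circle."""
    p = profile.p_base_left if position.side == "left" else profile.p_base_right
    if position.y_cm < 0:
        p *= profile.vertical_penalty
    if bilateral and position.side == "left":
        p *= profile.extinction_penalty
    return p


def simulate_session(profile: PatientProfile, schedule: Schedule,
                     seed: int) -> SessionRecord:
    """Simulate one fully seeded session on the given schedule."""
    rng = np.random.default_rng(seed)
    configs = configurations_by_id()
    positions = positions_by_id()
    responses: list[TrialResponse] = []
    for trial in schedule.trials:
        config = configs[trial.config_id]
        reported: set[str] = set()
        shown_sides = set()
        for pid in config.position_ids:
            pos = positions[pid]
            shown_sides.add(pos.side)
            if rng.random() < detection_probability(profile, pos, config.bilateral):
                reported.add(pos.side)
        if not config.bilateral:
            absent = ({"left", "right"} - shown_sides).pop()
            h = profile.h_right if absent == "right" else profile.h_left
            if rng.random() < h:
                reported.add(absent)
        d_correct = profile.d_correct_bi if config.bilateral else profile.d_correct_uni
        if rng.random() < d_correct:
            digit: int | str = trial.digit
        elif rng.random() < 0.5:
            digit = INDEFINITE
        else:
            wrong = [d for d in (1, 2, 3, 4) if d != trial.digit]
            digit = int(wrong[rng.integers(3)])
        responses.append(TrialResponse(frozenset(reported), digit))
    return SessionRecord(
        subject_id=f"sim-{profile.label}-{seed}",
        schedule=schedule,
        responses=responses,
        metadata={"group": profile.label, "profile_seed": seed},
    )


def expected_scoresheet(profile: PatientProfile, schedule: Schedule) -> dict:
    """Analytic expectations of all counts plus plug-in coefficients.

    Coefficients are the scoring formulas evaluated at the expected counts —
    a plug-in approximation, not the exact expectation of a ratio.
    """
    configs = configurations_by_id()
    positions = positions_by_id()
    constants = derive_constants(schedule)
    e = {k: 0.0 for k in ("LSU", "LSB", "RSU", "RSB", "RH", "LH",
                          "NIR", "NIL", "NIB")}
    e_pos = {pid: 0.0 for pid in positions}
    for trial in schedule.trials:
        config = configs[trial.config_id]
        shown_sides = set()
        for pid in config.position_ids:
            pos = positions[pid]
            shown_sides.add(pos.side)
            q_miss = 1.0 - detection_probability(profile, pos, config.bilateral)
            e_pos[pid] += q_miss
            key = ("L" if pos.side == "left" else "R") + ("SB" if config.bilateral else "SU")
            e[key] += q_miss
        if config.bilateral:
            e["NIB"] += 1.0 - profile.d_correct_bi
        else:
            absent = ({"left", "right"} - shown_sides).pop()
            e["RH" if absent == "right" else "LH"] += (
                profile.h_right if absent == "right" else profile.h_left)
            e["NIR" if shown_sides == {"right"} else "NIL"] += 1.0 - profile.d_correct_uni
    bp, lp = constants.bp, constants.lp
    # plug-in coefficients: the count formulas evaluated at real-valued means
    LSB, RSB, LSU, RSU = e["LSB"], e["RSB"], e["LSU"], e["RSU"]
    denom_bi = 2 * bp - RSB - LSB
    denom_all = 2 * lp - RSB - RSU - LSB - LSU
    det = denom_all
    hal = e["RH"] + e["LH"]
    coeffs = {
        "KA_bilateral": (LSB - RSB) / denom_bi if denom_bi else None,
        "KPrR_bilateral": (bp - RSB) / bp,
        "KPrL_bilateral": (bp - LSB) / bp,
        "KA_all": (LSB + LSU - RSB - RSU) / denom_all if denom_all else None,
        "KEf_all": (det - hal) / (det + hal) if det + hal else None,
        "KPrR_all": (lp - RSB - RSU) / lp,
        "KPrL_all": (lp - LSB - LSU) / lp,
    }
    return {**e, "position_omissions": e_pos, **coeffs, "BP": bp, "LP": lp}


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class GroupSpec:
    """Per-parameter (mean, sd) of a group's profile distribution.

    Subject parameters are drawn as normal(mean, sd) truncated to [0, 1].
    """

    means: PatientProfile
    sds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    n_neglect: int
    n_control: int
    neglect: GroupSpec
    control: GroupSpec
    seed: int = 0

    def __post_init__(self):
        if self.n_neglect < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")


def calibrate_detection(kprl_bilateral: float, kprl_all: float, kprr_all: float,
                        vertical_penalty: float) -> tuple[float, float, float]:
    """Closed-form inversion of the plug-in productivity coefficients.

    On the standard schedule each hemifield receives 21 unilateral
    presentations (6 in the lower band) and 33 bilateral presentations (12 in
    the lower band), so with p = p_base_left, v = vertical_penalty and
    e = extinction_penalty:

        KPrL_bilateral = p*e*(21 + 12 v) / 33
        KPrL_all       = p*((15 + 6 v) + e*(21 + 12 v)) / 54
        KPrR_all       = p_base_right*(36 + 18 v) / 54

    Returns (p_base_left, p_base_right, extinction_penalty).
    """
    v = vertical_penalty
    bi = 21 + 12 * v
    uni = 15 + 6 * v
    pe = 33 * kprl_bilateral / bi
    p_left = (54 * kprl_all - 33 * kprl_bilateral) / uni
    if p_left <= 0:
        raise ValueError("targets are inconsistent: non-positive p_base_left")
    extinction = min(1.0, pe / p_left)
    p_right = min(1.0, 54 * kprr_all / (36 + 18 * v))
    return p_left, p_right, extinction


def _neglect_preset() -> GroupSpec:
    p_l, p_r, ext = calibrate_detection(0.097, 0.145, 0.800, vertical_penalty=0.85)
    means = PatientProfile(
        p_base_left=p_l, p_base_right=p_r, vertical_penalty=0.85,
        extinction_penalty=ext,
        h_right=1.632 / 21, h_left=0.132 / 21,
        d_correct_uni=1 - (10.500 + 9.816) / 42, d_correct_bi=1 - 12.421 / 33,
        label="neglect",
    )
    sds = {"p_base_left": 0.10, "p_base_right": 0.10, "vertical_penalty": 0.05,
           "extinction_penalty": 0.15, "h_right": 0.05, "h_left": 0.005,
           "d_correct_uni": 0.15, "d_correct_bi": 0.15}
    return GroupSpec(means=means, sds=sds)


def _control_preset() -> GroupSpec:
    p_l, p_r, ext = calibrate_detection(0.759, 0.767, 0.881, vertical_penalty=0.9)
    means = PatientProfile(
        p_base_left=p_l, p_base_right=p_r, vertical_penalty=0.9,
        extinction_penalty=ext,
        h_right=0.391 / 21, h_left=0.125 / 21,
        d_correct_uni=1 - (3.984 + 3.609) / 42, d_correct_bi=1 - 5.250 / 33,
        label="no_neglect",
    )
    sds = {"p_base_left": 0.12, "p_base_right": 0.07, "vertical_penalty": 0.05,
           "extinction_penalty": 0.03, "h_right": 0.02, "h_left": 0.005,
           "d_correct_uni": 0.10, "d_correct_bi": 0.10}
    return GroupSpec(means=means, sds=sds)


def study_cohort_spec(n_neglect: int = 38, n_control: int = 64,
                      seed: int = 0) -> CohortSpec:
    """The built-in calibrated cohort: 38 neglect-like and 64 control-like
    subjects by default, mirroring the validation study's group sizes."""
    return CohortSpec(n_neglect=n_neglect, n_control=n_control,
                      neglect=_neglect_preset(), control=_control_preset(),
                      seed=seed)


def cohort_spec_from_file(path) -> CohortSpec:
    """Load a cohort spec from a YAML or JSON config file.

    Recognized keys: ``n_neglect``, ``n_control``, ``seed``, and optional
    ``neglect`` / ``control`` blocks with ``means`` and ``sds`` mappings that
    override the built-in preset parameter-by-parameter.
    """
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    cfg = (json.loads(text) if str(path).endswith(".json")
           else yaml.safe_load(text)) or {}

    def build_group(base: GroupSpec, block: dict | None) -> GroupSpec:
        if not block:
            return base
        means = replace(base.means, **block.get("means", {}))
        sds = {**base.sds, **block.get("sds", {})}
        return GroupSpec(means=means, sds=sds)

    return CohortSpec(
        n_neglect=int(cfg.get("n_neglect", 38)),
        n_control=int(cfg.get("n_control", 64)),
        neglect=build_group(_neglect_preset(), cfg.get("neglect")),
        control=build_group(_control_preset(), cfg.get("control")),
        seed=int(cfg.get("seed", 0)),
    )


def draw_profile(group: GroupSpec, rng: np.random.Generator) -> PatientProfile:
    """Draw one subject's profile from a group's truncated-normal spread."""
    kwargs = {}
    for name, sd in group.sds.items():
        mean = getattr(group.means, name)
        kwargs[name] = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
    return replace(group.means, **kwargs)


def simulate_cohort(spec: CohortSpec,
                    schedule: Schedule | None = None
                    ) -> list[tuple[SessionRecord, str]]:
    """Simulate a labelled cohort; one session per subject.

    All subjects share one schedule (a fresh seeded main schedule unless one
    is given); profiles and response noise are drawn from a seed sequence so
    the whole cohort is reproducible from ``spec.seed``.
    """
    if schedule is None:
        schedule = generate_main_schedule(spec.seed)
    ss = np.random.SeedSequence(spec.seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    out: list[tuple[SessionRecord, str]] = []
    session_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(spec.n_neglect + spec.n_control)]
    i = 0
    for group, n in ((spec.neglect, spec.n_neglect), (spec.control, spec.n_control)):
        for _ in range(n):
            profile = draw_profile(group, profile_rng)
            record = simulate_session(profile, schedule, session_seeds[i])
            record.subject_id = f"sim-{profile.label}-{i:03d}"
            out.append((record, profile.label))
            i += 1
    return out
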