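"""Stimulus geometry and trial-schedule generation for the dual-task
neglect-screening protocol.

The display holds 14 possible circle positions, 7 per hemifield, arranged in
three vertical bands (upper / middle / lower) at three horizontal
eccentricities. A trial shows either one circle (unilateral) or two circles,
one per side (bilateral), together with a central digit. The main series
presents each of the 25 distinct target configurations exactly three times,
giving 75 trials: 42 unilateral and 33 bilateral, and 54 lateralized circle
presentations per side.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

Side = Literal["left", "right"]
Band = Literal["upper", "middle", "lower"]

#: viewing distance assumed by the protocol, cm
VIEWING_DISTANCE_CM = 60.0

#: fixed trial timings, ms
FIXATION_MS = 1000
STIMULUS_MS = 100
MASK_MS = 2000

#: target circle diameter, mm
CIRCLE_DIAMETER_MM = 8

# (id, x_cm, y_cm); x < 0 is left of center, y > 0 is above center
_POSITION_TABLE = [
    (1, -13.5, 8.0),
    (2, -13.5, 0.0),
    (3, -13.5, -8.0),
    (4, -7.5, 4.0),
    (5, -7.5, 0.0),
    (6, -7.5, -4.0),
    (7, -1.5, 0.0),
    (8, 13.5, 8.0),
    (9, 13.5, 0.0),
    (10, 13.5, -8.0),
    (11, 7.5, 4.0),
    (12, 7.5, 0.0),
    (13, 7.5, -4.0),
    (14, 1.5, 0.0),
]

# bilateral pairings: seven mirror-symmetric pairs and four diagonal pairs
_VERTICAL_SYMMETRIC_PAIRS = [(i, i + 7) for i in range(1, 8)]
_DIAGONAL_PAIRS = [(1, 10), (3, 8), (4, 13), (6, 11)]

#: positions shown 6 times in the main series; all others are shown 9 times
SIX_PRESENTATION_IDS = frozenset({2, 5, 7, 9, 12, 14})


@dataclass(frozen=True)
class TargetPosition:
    """One of the 14 possible circle locations, in cm from screen center."""

    id: int
    x_cm: float
    y_cm: float

    @property
    def side(self) -> Side:
        return "left" if self.x_cm < 0 else "right"

    @property
    def band(self) -> Band:
        if self.y_cm > 0:
            return "upper"
        if self.y_cm < 0:
            return "lower"
        return "middle"


@dataclass(frozen=True)
class Configuration:
    """A set of one or two simultaneously shown positions."""

    config_id: int
    position_ids: frozenset[int]
    kind: Literal["unilateral", "bilateral_vertical_symmetric", "bilateral_diagonal"]

    @property
    def bilateral(self) -> bool:
        return len(self.position_ids) == 2


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus event of a schedule."""

    trial_index: int
    config_id: int
    digit: int
    fixation_ms: int = FIXATION_MS
    stimulus_ms: int = STIMULUS_MS
    mask_ms: int = MASK_MS
    circle_diameter_mm: int = CIRCLE_DIAMETER_MM


@dataclass
class Schedule:
    """An ordered trial list plus the seed that produced it."""

    trials: list[TrialSpec]
    seed: int
    kind: Literal["training", "main"] = "main"

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


@dataclass(frozen=True)
class ProtocolConstants:
    """Presentation counts derived by counting over a schedule.

    ``bp`` is the number of bilateral trials; ``lp`` the number of lateralized
    circle presentations per side (identical left/right for the standard
    protocol). For the canonical 75-trial series bp = 33 and lp = 54.
    """

    bp: int
    lp: int
    viewing_distance_cm: float = VIEWING_DISTANCE_CM


def build_positions() -> list[TargetPosition]:
    """Return the 14 target positions of the standard display layout."""
    return [TargetPosition(i, x, y) for i, x, y in _POSITION_TABLE]


def positions_by_id() -> dict[int, TargetPosition]:
    return {p.id: p for p in build_positions()}


def build_configurations() -> list[Configuration]:
    """Return the 25 target configurations of the main series.

    14 unilateral (one per position), 7 bilateral pairs symmetric about the
    vertical axis, and 4 bilateral pairs symmetric about a diagonal axis.
    """
    configs: list[Configuration] = []
    cid = 1
    for pid, _, _ in _POSITION_TABLE:
        configs.append(Configuration(cid, frozenset({pid}), "unilateral"))
        cid += 1
    for a, b in _VERTICAL_SYMMETRIC_PAIRS:
        configs.append(Configuration(cid, frozenset({a, b}), "bilateral_vertical_symmetric"))
        cid += 1
    for a, b in _DIAGONAL_PAIRS:
        configs.append(Configuration(cid, frozenset({a, b}), "bilateral_diagonal"))
        cid += 1
    return configs


def configurations_by_id() -> dict[int, Configuration]:
    return {c.config_id: c for c in build_configurations()}


def generate_main_schedule(seed: int) -> Schedule:
    """Generate the 75-trial main series in seeded random order.

    Each configuration appears exactly three times; trial order is a uniform
    permutation and the central digit is drawn i.i.d. uniform from {1,2,3,4}.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    config_ids = [c.config_id for c in build_configurations() for _ in range(3)]
    order = rng.permutation(len(config_ids))
    trials = [
        TrialSpec(
            trial_index=i,
            config_id=config_ids[j],
            digit=int(rng.integers(1, 5)),
        )
        for i, j in enumerate(order)
    ]
    return Schedule(trials=trials, seed=seed, kind="main")


#: stimulus-duration ladder for the 7 training trials, ms (1 s down to 100 ms)
TRAINING_DURATIONS_MS = (1000, 850, 700, 550, 400, 250, 100)


def generate_training_schedule(seed: int) -> Schedule:
    """Generate the 7-trial training series.

    Stimulus duration decreases linearly from 1000 ms to 100 ms while the
    trials sample varied configurations: left and right unilateral targets at
    near and far eccentricity, upper and lower bands, and bilateral displays.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    by_kind: dict[str, list[Configuration]] = {}
    for c in build_configurations():
        by_kind.setdefault(c.kind, []).append(c)
    pos = positions_by_id()

    def pick(pool: Iterable[Configuration]) -> Configuration:
        pool = list(pool)
        return pool[int(rng.integers(len(pool)))]

    uni = by_kind["unilateral"]
    chosen = [
        pick(c for c in uni if pos[next(iter(c.position_ids))].side == "left"),
        pick(c for c in uni if pos[next(iter(c.position_ids))].side == "right"),
        pick(by_kind["bilateral_vertical_symmetric"]),
        pick(c for c in uni if pos[next(iter(c.position_ids))].band == "upper"),
        pick(c for c in uni if pos[next(iter(c.position_ids))].band == "lower"),
        pick(by_kind["bilateral_diagonal"]),
        pick(c for c in uni if abs(pos[next(iter(c.position_ids))].x_cm) <= 1.5),
    ]
    trials = [
        TrialSpec(
            trial_index=i,
            config_id=c.config_id,
            digit=int(rng.integers(1, 5)),
            stimulus_ms=dur,
        )
        for i, (c, dur) in enumerate(zip(chosen, TRAINING_DURATIONS_MS))
    ]
    return Schedule(trials=trials, seed=seed, kind="training")


def derive_constants(schedule: Schedule) -> ProtocolConstants:
    """Count bilateral trials and per-side presentations over a schedule.

    Counting (rather than hardcoding) keeps truncated or non-standard
    schedules scoreable; a standard main schedule yields bp=33, lp=54.
    """
    configs = configurations_by_id()
    pos = positions_by_id()
    bp = 0
    left = 0
    right = 0
    for t in schedule.trials:
        c = configs[t.config_id]
        if c.bilateral:
            bp += 1
        for pid in c.position_ids:
            if pos[pid].side == "left":
                left += 1
            else:
                right += 1
    if left != right:
        raise ValueError(
            f"schedule is not left/right balanced ({left} left vs {right} right "
            "presentations); per-side LP is undefined"
        )
    return ProtocolConstants(bp=bp, lp=left)


def position_presentation_counts(schedule: Schedule) -> dict[int, int]:
    """Number of times each position is shown across a schedule."""
    configs = configurations_by_id()
    counts = {pid: 0 for pid, _, _ in _POSITION_TABLE}
    for t in schedule.trials:
        for pid in configs[t.config_id].position_ids:
            counts[pid] += 1
    return counts


def cm_to_visual_angle(offset_cm: float, distance_cm: float = VIEWING_DISTANCE_CM) -> float:
    """Convert a center-referenced offset to degrees of visual angle.

    Uses the plain arctangent of offset/distance for an offset measured from
    the fixation point.
    """
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    return math.degrees(math.atan2(offset_cm, distance_cm))


# ---------------------------------------------------------------------------
# serialization

def schedule_to_json(schedule: Schedule, path: str | Path) -> None:
    """Write a schedule to JSON with full fidelity (incl. seed and kind)."""
    payload = {
        "kind": schedule.kind,
        "seed": schedule.seed,
        "trials": [asdict(t) for t in schedule.trials],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def schedule_from_json(path: str | Path) -> Schedule:
    payload = json.loads(Path(path).read_text())
    trials = [TrialSpec(**t) for t in payload["trials"]]
    return Schedule(trials=trials, seed=payload["seed"], kind=payload["kind"])


def schedule_to_csv(schedule: Schedule, path: str | Path) -> None:
    """Write one row per trial (positions joined with '+')."""
    configs = configurations_by_id()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["trial_index", "config_id", "position_ids", "digit",
             "fixation_ms", "stimulus_ms", "mask_ms"]
        )
        for t in schedule.trials:
            pids = "+".join(str(p) for p in sorted(configs[t.config_id].position_ids))
            w.writerow([t.trial_index, t.config_id, pids, t.digit,
                        t.fixation_ms, t.stimulus_ms, t.mask_ms])
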