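"""Response data model: what the participant reported on each trial, linked
to the schedule that produced the stimuli.

A verbal report consists of (a) which side(s) the circle(s) appeared on and
(b) the central digit. An indefinite report ("I didn't see", "something
flashed") carries no side and no digit: it is coded as an empty side set and
an INDEFINITE digit, which scoring treats as omissions on every presented
side and as a digit error.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .protocol import (
    Schedule,
    TrialSpec,
    configurations_by_id,
    generate_main_schedule,
)

#: sentinel for an indefinite digit report; serialized as "NA"
INDEFINITE = "INDEFINITE"

_SIDE_TOKENS = {
    "left": frozenset({"left"}),
    "right": frozenset({"right"}),
    "both": frozenset({"left", "right"}),
    "none": frozenset(),
    "": frozenset(),
}


class SessionFormatError(ValueError):
    """A session file violated the documented CSV/JSON dialect."""


@dataclass(frozen=True)
class TrialResponse:
    """Reported side set (0, 1 or 2 sides) and reported digit."""

    reported_sides: frozenset[str]
    reported_digit: int | str

    def __post_init__(self):
        if not self.reported_sides <= {"left", "right"}:
            raise ValueError(f"unknown side in {set(self.reported_sides)!r}")
        ok = self.reported_digit == INDEFINITE or self.reported_digit in (1, 2, 3, 4)
        if not ok:
            raise ValueError(f"reported digit must be 1-4 or INDEFINITE, got {self.reported_digit!r}")


@dataclass
class SessionRecord:
    """A subject's full run: schedule, aligned responses, optional metadata.

    ``metadata`` may carry a group label and external paper-and-pencil
    outcomes (Albert's, Bells, CBS, FAB) for the validation analyses.
    """

    subject_id: str
    schedule: Schedule
    responses: list[TrialResponse]
    metadata: dict[str, Any] = field(default_factory=dict)


def parse_side_token(token: str) -> frozenset[str]:
    """Normalize a side token case-insensitively from {left,right,both,none}."""
    key = token.strip().lower()
    if key not in _SIDE_TOKENS:
        raise SessionFormatError(f"unknown side token {token!r}")
    return _SIDE_TOKENS[key]


def _format_sides(sides: frozenset[str]) -> str:
    if sides == {"left", "right"}:
        return "both"
    if sides == {"left"}:
        return "left"
    if sides == {"right"}:
        return "right"
    return "none"


def _parse_digit(token: str, row: int) -> int | str:
    token = token.strip()
    if token.upper() in ("NA", "INDEFINITE", ""):
        return INDEFINITE
    try:
        digit = int(token)
    except ValueError:
        raise SessionFormatError(f"row {row}: unparseable digit {token!r}") from None
    if digit not in (1, 2, 3, 4):
        raise SessionFormatError(f"row {row}: digit {digit} outside 1-4")
    return digit


def validate_session(record: SessionRecord) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Checks response/trial alignment and, for a main schedule, that the
    protocol is legal: every configuration id resolves and appears exactly
    three times.
    """
    violations: list[str] = []
    n_trials = len(record.schedule.trials)
    if len(record.responses) != n_trials:
        violations.append(
            f"response count {len(record.responses)} != trial count {n_trials}"
        )
    configs = configurations_by_id()
    multiplicity: dict[int, int] = {}
    for t in record.schedule.trials:
        if t.config_id not in configs:
            violations.append(f"dangling trial index: unknown configuration {t.config_id}")
            continue
        multiplicity[t.config_id] = multiplicity.get(t.config_id, 0) + 1
    indices = [t.trial_index for t in record.schedule.trials]
    if sorted(indices) != list(range(n_trials)):
        violations.append("trial indices are not 0..n-1")
    if record.schedule.kind == "main":
        if n_trials != 75:
            violations.append(f"main schedule has {n_trials} trials, expected 75")
        bad = {cid: m for cid, m in multiplicity.items() if m != 3}
        if bad and n_trials == 75:
            violations.append(f"configuration multiplicity != 3 for {sorted(bad)}")
    return violations


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Serialize a session; '.json' bundles schedule + responses + metadata,
    anything else is written as the per-trial CSV dialect."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "subject_id": record.subject_id,
            "metadata": record.metadata,
            "schedule": {
                "kind": record.schedule.kind,
                "seed": record.schedule.seed,
                "trials": [vars(t) for t in record.schedule.trials],
            },
            "responses": [
                {
                    "reported_side": _format_sides(r.reported_sides),
                    "reported_digit": "NA" if r.reported_digit == INDEFINITE else r.reported_digit,
                }
                for r in record.responses
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    configs = configurations_by_id()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "trial_index", "config_id", "shown_digit",
                    "reported_side", "reported_digit"])
        for t, r in zip(record.schedule.trials, record.responses):
            w.writerow([
                record.subject_id,
                t.trial_index,
                t.config_id,
                t.digit,
                _format_sides(r.reported_sides),
                "NA" if r.reported_digit == INDEFINITE else r.reported_digit,
            ])


def read_session(path: str | Path, schedule: Schedule | None = None) -> SessionRecord:
    """Read a session written by :func:`write_session`.

    JSON files are self-contained. For CSV files the schedule is rebuilt from
    the rows themselves (config_id + shown digit per trial) unless an explicit
    ``schedule`` is given, in which case the rows are checked against it.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        sched = Schedule(
            trials=[TrialSpec(**t) for t in payload["schedule"]["trials"]],
            seed=payload["schedule"]["seed"],
            kind=payload["schedule"]["kind"],
        )
        responses = [
            TrialResponse(
                reported_sides=parse_side_token(r["reported_side"]),
                reported_digit=INDEFINITE if r["reported_digit"] in ("NA", None)
                else int(r["reported_digit"]),
            )
            for r in payload["responses"]
        ]
        record = SessionRecord(payload["subject_id"], sched, responses,
                               payload.get("metadata", {}))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise SessionFormatError("empty session file")
        subject_id = rows[0]["subject_id"]
        trials: list[TrialSpec] = []
        responses = []
        for i, row in enumerate(rows):
            try:
                trials.append(TrialSpec(
                    trial_index=int(row["trial_index"]),
                    config_id=int(row["config_id"]),
                    digit=int(row["shown_digit"]),
                ))
                responses.append(TrialResponse(
                    reported_sides=parse_side_token(row["reported_side"]),
                    reported_digit=_parse_digit(row["reported_digit"], i),
                ))
            except SessionFormatError:
                raise
            except (KeyError, ValueError) as exc:
                raise SessionFormatError(f"row {i}: {exc}") from exc
        if schedule is not None:
            if len(trials) != len(schedule.trials):
                raise SessionFormatError(
                    f"{len(trials)} responses against a {len(schedule.trials)}-trial schedule"
                )
            sched = schedule
        else:
            kind = "main" if len(trials) == 75 else "training"
            sched = Schedule(trials=trials, seed=-1, kind=kind)
        record = SessionRecord(subject_id, sched, responses)
    problems = validate_session(record)
    fatal = [p for p in problems if "count" in p or "dangling" in p]
    if fatal:
        raise SessionFormatError("; ".join(fatal))
    return record
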