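"""Notification dispatch planning.

Three notification kinds attach to a module:

* **opening** — announces availability; dispatched on a configured interval
  after the module opens (fixed offset or a seeded uniform draw on an
  integer-minute window) or at a fixed date.
* **reminder** — nudges a participant who has not finished an open module;
  dispatched only after the module has been available for at least
  15 minutes (the configurable offset can only be raised).
* **closing** — warns that the module is about to close; dispatched exactly
  15 minutes before the close time, which is only knowable for fixed-date
  and relative-after-start closing rules.

The planner emits a *dispatch plan* (a sorted list of planned
notifications), not pushes: transport is someone else's problem and plans
are trivially testable. Notifications whose module instance completed or
closed strictly before the dispatch minute are suppressed — nobody is
reminded of a module they already finished. When a module's lifetime is
shorter than the 15-minute closing lead the closing notification cannot be
honoured; it is dropped and recorded as a planning violation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .scheduler import ModuleState, ParticipantTimeline, Transition
from .study_model import (
    CLOSING_NOTIF_COMPATIBLE,
    CLOSING_LEAD_MINUTES,
    IntervalAfterOpen,
    FixedDispatch,
    MIN_REMINDER_OFFSET,
    NotificationKind,
    NotificationSpec,
    StudyDefinition,
)


@dataclass(frozen=True)
class PlannedNotification:
    participant_id: str
    module_id: str
    kind: NotificationKind
    dispatch_time: int
    text: str = ""


@dataclass(frozen=True)
class PlanningViolation:
    participant_id: str
    module_id: str
    code: str
    message: str


def _stream(seed: int, participant_id: str, module_id: str,
            kind: NotificationKind) -> np.random.Generator:
    # one independent stream per (seed, instance, kind): the plan is
    # invariant to iteration order and to unrelated modules being added
    entropy = (int(seed),
               zlib.crc32(participant_id.encode()),
               zlib.crc32(module_id.encode()),
               zlib.crc32(kind.value.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _interval_dispatch(spec_trigger, opened_at: int, rng: np.random.Generator) -> int:
    if isinstance(spec_trigger, FixedDispatch):
        return spec_trigger.at
    assert isinstance(spec_trigger, IntervalAfterOpen)
    if spec_trigger.offset_minutes is not None:
        return opened_at + spec_trigger.offset_minutes
    lo, hi = spec_trigger.window
    return opened_at + int(rng.integers(lo, hi + 1))


def _reminder_dispatch(spec: NotificationSpec, opened_at: int,
                       rng: np.random.Generator) -> int:
    if spec.reminder_offset_minutes is not None:
        return opened_at + max(spec.reminder_offset_minutes, MIN_REMINDER_OFFSET)
    if isinstance(spec.trigger, IntervalAfterOpen):
        if spec.trigger.offset_minutes is not None:
            return opened_at + max(spec.trigger.offset_minutes, MIN_REMINDER_OFFSET)
        lo, hi = spec.trigger.window
        lo = max(lo, MIN_REMINDER_OFFSET)
        hi = max(hi, lo)
        return opened_at + int(rng.integers(lo, hi + 1))
    if isinstance(spec.trigger, FixedDispatch):
        return max(spec.trigger.at, opened_at + MIN_REMINDER_OFFSET)
    return opened_at + MIN_REMINDER_OFFSET


def _deterministic_close_time(module, tl: ParticipantTimeline) -> Optional[int]:
    """Close time knowable at planning: fixed-date / relative-after-start."""
    from .scheduler import resolve_close_time

    inst = tl.instances[module.id]
    if inst.opened_at is None:
        return None
    times = [resolve_close_time(rule, inst, tl)
             for rule in module.closing_rules
             if rule.rule in CLOSING_NOTIF_COMPATIBLE]
    times = [t for t in times if t is not None]
    return min(times) if times else None


def plan_notifications(
    study: StudyDefinition,
    timelines: dict[str, ParticipantTimeline],
    transitions: Iterable[Transition],
    rng_seed: int = 0,
) -> tuple[list[PlannedNotification], list[PlanningViolation]]:
    """Plan every notification for a run's module instances.

    Deterministic given the seed; random-interval dispatches are uniform
    integer-minute draws on the configured window, from a stream derived
    per (seed, participant, module, kind). Already suppressed against the
    supplied transitions; returns (plan, planning violations).
    """
    transitions = list(transitions)
    raw: list[PlannedNotification] = []
    violations: list[PlanningViolation] = []
    for pid in sorted(timelines):
        tl = timelines[pid]
        if tl.intervention_id is None:
            continue
        for module in study.intervention(tl.intervention_id).modules:
            inst = tl.instances[module.id]
            if inst.opened_at is None:
                continue  # never opened: nothing to announce
            for spec in module.notifications:
                rng = _stream(rng_seed, pid, module.id, spec.kind)
                if spec.kind is NotificationKind.opening:
                    when = _interval_dispatch(spec.trigger, inst.opened_at, rng)
                    raw.append(PlannedNotification(pid, module.id, spec.kind,
                                                   max(when, inst.opened_at),
                                                   spec.text))
                elif spec.kind is NotificationKind.reminder:
                    raw.append(PlannedNotification(
                        pid, module.id, spec.kind,
                        _reminder_dispatch(spec, inst.opened_at, rng), spec.text))
                elif spec.kind is NotificationKind.closing:
                    close_time = _deterministic_close_time(module, tl)
                    if close_time is None:
                        violations.append(PlanningViolation(
                            pid, module.id, "CLOSE_TIME_UNRESOLVABLE",
                            "closing notification needs a fixed-date or "
                            "relative-after-start closing rule"))
                        continue
                    if close_time - inst.opened_at < CLOSING_LEAD_MINUTES:
                        violations.append(PlanningViolation(
                            pid, module.id, "CLOSING_LEAD_UNSATISFIABLE",
                            f"module lifetime {close_time - inst.opened_at} min "
                            f"is shorter than the {CLOSING_LEAD_MINUTES}-min lead"))
                        continue
                    raw.append(PlannedNotification(
                        pid, module.id, spec.kind,
                        close_time - CLOSING_LEAD_MINUTES, spec.text))
    plan = suppress_on_terminal(raw, transitions)
    plan.sort(key=lambda p: (p.dispatch_time, p.participant_id,
                             p.module_id, p.kind.value))
    return plan, violations


def suppress_on_terminal(
    plan: Iterable[PlannedNotification],
    transitions: Iterable[Transition],
) -> list[PlannedNotification]:
    """Drop notifications overtaken by completion or closure.

    A planned notification is removed iff its module instance reached
    COMPLETED or CLOSED strictly before the dispatch minute.
    """
    terminal: dict[tuple[str, str], int] = {}
    for tr in transitions:
        if tr.to_state in (ModuleState.COMPLETED, ModuleState.CLOSED):
            key = (tr.participant_id, tr.module_id)
            terminal[key] = min(terminal.get(key, tr.time), tr.time)
    return [p for p in plan
            if terminal.get((p.participant_id, p.module_id), None) is None
            or terminal[(p.participant_id, p.module_id)] >= p.dispatch_time]


PLAN_COLUMNS = ["dispatch_time", "participant_id", "module_id", "kind", "text"]


def plan_to_csv(plan: Iterable[PlannedNotification]) -> str:
    df = pd.DataFrame(
        [{"dispatch_time": p.dispatch_time, "participant_id": p.participant_id,
          "module_id": p.module_id, "kind": p.kind.value, "text": p.text}
         for p in plan], columns=PLAN_COLUMNS)
    return df.to_csv(index=False)
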