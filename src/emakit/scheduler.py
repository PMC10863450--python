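"""Per-participant module lifecycle engine.

Each module of an intervention is, for each participant, a tiny state
machine::

    LOCKED --open--> OPEN --complete--> COMPLETED
                       \\----close----> CLOSED

COMPLETED and CLOSED are terminal; there is no re-opening. Opening and
closing are driven by the declarative timing rules on the module; when a
module carries several rules of a kind they combine as OR — the earliest
rule to fire wins. A module with no opening rules opens at enrollment; a
module with no closing rules stays open until completed.

The engine consumes a time-ordered event stream (enrollments, item
answers, explicit completions, clock ticks) and interleaves the timed
transitions that fall between events. Within one minute the order is:
timed openings, then all of the minute's events, then closings — so an
answer submitted at the closing deadline still counts, and a module whose
fixed close date precedes its open time emits OPEN then CLOSED in the same
minute. Replaying the same event stream always yields the identical
transition list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import Iterable, Optional, Union

import pandas as pd

from .study_model import (
    AssignmentPolicy,
    ClosingRule,
    Comparator,
    InterventionModule,
    OpeningRule,
    StudyDefinition,
)


class ModuleState(str, Enum):
    LOCKED = "LOCKED"
    OPEN = "OPEN"
    COMPLETED = "COMPLETED"
    CLOSED = "CLOSED"


TERMINAL_STATES = frozenset({ModuleState.COMPLETED, ModuleState.CLOSED})

_LEGAL = {
    (ModuleState.LOCKED, ModuleState.OPEN),
    (ModuleState.OPEN, ModuleState.COMPLETED),
    (ModuleState.OPEN, ModuleState.CLOSED),
}


class SchedulingError(ValueError):
    pass


class MonotonicityError(SchedulingError):
    """An event arrived earlier than one already applied."""


@dataclass
class ModuleInstance:
    participant_id: str
    module_id: str
    state: ModuleState = ModuleState.LOCKED
    opened_at: Optional[int] = None
    finished_at: Optional[int] = None
    closed_at: Optional[int] = None
    answered_items: set[str] = field(default_factory=set)


_EVENT_PRIORITY = {"enroll": 0, "answer": 1, "module_completed": 2, "clock_tick": 3}


@dataclass(frozen=True)
class Event:
    time: int
    kind: str  # enroll | answer | module_completed | clock_tick
    participant_id: str
    module_id: Optional[str] = None
    item_id: Optional[str] = None
    value: Optional[object] = None

    def __post_init__(self):
        if self.kind not in _EVENT_PRIORITY:
            raise SchedulingError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Transition:
    time: int
    participant_id: str
    module_id: str
    from_state: ModuleState
    to_state: ModuleState


@dataclass
class ParticipantTimeline:
    participant_id: str
    enrollment_time: int
    intervention_id: Optional[str]  # None when waitlisted
    instances: dict[str, ModuleInstance] = field(default_factory=dict)
    answers: list[tuple[int, str, object]] = field(default_factory=list)
    rejected_answers: int = 0


def _as_number(value) -> Optional[float]:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value) if math.isfinite(value) else None
    if isinstance(value, str):
        try:
            x = float(value)
        except ValueError:
            return None
        return x if math.isfinite(x) else None
    return None


def _compare(comparator: Comparator, answer, target) -> bool:
    a, b = _as_number(answer), _as_number(target)
    if a is not None and b is not None:
        return {
            Comparator.eq: a == b, Comparator.ne: a != b,
            Comparator.lt: a < b, Comparator.le: a <= b,
            Comparator.gt: a > b, Comparator.ge: a >= b,
        }[comparator]
    if comparator is Comparator.eq:
        return str(answer) == str(target)
    if comparator is Comparator.ne:
        return str(answer) != str(target)
    return False  # ordering comparator on text: validator flags this


def resolve_open_time(rule: OpeningRule, timeline: ParticipantTimeline,
                      now: int) -> Optional[int]:
    """Earliest time >= enrollment at which an opening rule fires.

    Returns None while the firing time cannot yet be determined (e.g. the
    referenced module has not finished, or a not-finished check lies in the
    future). Deterministic given the timeline.
    """
    kind = rule.rule
    if kind == "relative_to_intervention_start":
        return timeline.enrollment_time + rule.offset_minutes
    if kind == "fixed_datetime":
        return max(rule.at, timeline.enrollment_time)
    if kind == "relative_to_module_completion":
        ref = timeline.instances.get(rule.ref_module_id)
        if ref is None:
            raise SchedulingError(f"dangling module reference {rule.ref_module_id!r}")
        if ref.finished_at is None:
            return None
        return ref.finished_at + rule.offset_minutes
    if kind == "on_module_not_finished":
        ref = timeline.instances.get(rule.ref_module_id)
        if ref is None:
            raise SchedulingError(f"dangling module reference {rule.ref_module_id!r}")
        if ref.opened_at is None:
            return None  # never opened -> the check never arms
        check_at = ref.opened_at + rule.check_offset_minutes
        # the check sees the state at the start of the minute: finishing
        # exactly at the check minute is too late (openings precede events)
        if ref.finished_at is not None and ref.finished_at < check_at:
            return None  # finished in time; rule never fires
        return check_at
    if kind == "answer_condition":
        for t, item_id, value in timeline.answers:
            if item_id == rule.ref_item_id and _compare(rule.comparator, value,
                                                        rule.value):
                return t
        return None
    raise SchedulingError(f"unknown opening rule {kind!r}")


def resolve_close_time(rule: ClosingRule, instance: ModuleInstance,
                       timeline: ParticipantTimeline) -> Optional[int]:
    """Earliest close time >= opened_at for one closing rule, or None.

    A fixed close date in the past, and a satisfying answer given before the
    module opened, both clamp to opened_at: the module closes the instant
    it opens.
    """
    if instance.opened_at is None:
        raise SchedulingError("closing rules only apply to opened modules")
    kind = rule.rule
    if kind == "fixed_date":
        return max(rule.at, instance.opened_at)
    if kind == "relative_to_module_start":
        return instance.opened_at + rule.offset_minutes
    if kind == "answer_condition":
        for t, item_id, value in timeline.answers:
            if item_id == rule.ref_item_id and _compare(rule.comparator, value,
                                                        rule.value):
                return max(t, instance.opened_at)
        return None
    raise SchedulingError(f"unknown closing rule {kind!r}")


class ScheduleEngine:
    """Stateful fold over an event stream for one study.

    ``step`` applies one event (monotone non-decreasing times required),
    first firing every timed transition due before it, and returns the
    transitions emitted. Transitions at one minute are ordered openings
    first, then closings, each by (participant enrollment order, module
    order in the intervention).
    """

    def __init__(self, study: StudyDefinition):
        self.study = study
        self.timelines: dict[str, ParticipantTimeline] = {}
        self.transitions: list[Transition] = []
        self.now = 0
        self._enroll_order: list[str] = []
        # item -> owning module, per intervention
        self._item_module: dict[str, dict[str, str]] = {
            iv.id: {it.id: m.id for m in iv.modules for it in m.items}
            for iv in study.interventions
        }

    # -- public API -----------------------------------------------------------

    def step(self, event: Event) -> list[Transition]:
        if event.time < self.now:
            raise MonotonicityError(
                f"event at t={event.time} after engine reached t={self.now}")
        mark = len(self.transitions)
        self._flush(event.time, include_closings_at_target=False)
        self.now = event.time
        self._apply_event(event)
        # closings due at this very minute stay deferred: a later event in
        # the same minute (e.g. the answer finishing the module) still counts
        self._flush(event.time, include_closings_at_target=False)
        return self.transitions[mark:]

    def flush_to(self, time: int) -> list[Transition]:
        """Fire every timed transition due up to ``time`` (inclusive)."""
        if time < self.now:
            raise MonotonicityError(f"cannot flush backwards to t={time}")
        mark = len(self.transitions)
        self._flush(time, include_closings_at_target=True)
        self.now = time
        return self.transitions[mark:]

    # -- internals ------------------------------------------------------------

    def _modules(self, intervention_id: str) -> list[InterventionModule]:
        return self.study.intervention(intervention_id).modules

    def _apply_event(self, event: Event) -> None:
        if event.kind == "enroll":
            self._enroll(event)
            return
        if event.kind == "clock_tick":
            return
        tl = self.timelines.get(event.participant_id)
        if tl is None:
            raise SchedulingError(
                f"participant {event.participant_id!r} not enrolled")
        if event.kind == "answer":
            self._apply_answer(tl, event)
        elif event.kind == "module_completed":
            inst = tl.instances.get(event.module_id)
            if inst is not None and inst.state is ModuleState.OPEN:
                self._transition(tl, inst, ModuleState.COMPLETED, event.time)

    def _enroll(self, event: Event) -> None:
        pid = event.participant_id
        if pid in self.timelines:
            raise SchedulingError(f"participant {pid!r} already enrolled")
        iv_id = event.value if isinstance(event.value, str) else None
        if iv_id is None:
            auto = [iv for iv in self.study.interventions
                    if iv.assignment_policy is AssignmentPolicy.auto_assign]
            iv_id = auto[0].id if auto else None
        tl = ParticipantTimeline(participant_id=pid,
                                 enrollment_time=event.time,
                                 intervention_id=iv_id)
        if iv_id is not None:
            policy = self.study.intervention(iv_id).assignment_policy
            if policy is AssignmentPolicy.waitlist:
                tl.intervention_id = None  # waitlisted: no modules scheduled
            else:
                for mod in self._modules(iv_id):
                    tl.instances[mod.id] = ModuleInstance(
                        participant_id=pid, module_id=mod.id)
        self.timelines[pid] = tl
        self._enroll_order.append(pid)

    def _apply_answer(self, tl: ParticipantTimeline, event: Event) -> None:
        if tl.intervention_id is None:
            tl.rejected_answers += 1
            return
        module_id = self._item_module[tl.intervention_id].get(event.item_id)
        if module_id is None:
            tl.rejected_answers += 1
            return
        inst = tl.instances[module_id]
        if inst.state is not ModuleState.OPEN:
            tl.rejected_answers += 1  # answers only count while OPEN
            return
        tl.answers.append((event.time, event.item_id, event.value))
        inst.answered_items.add(event.item_id)
        module = next(m for m in self._modules(tl.intervention_id)
                      if m.id == module_id)
        answerable = {it.id for it in module.answerable_items()}
        if answerable and answerable <= inst.answered_items:
            self._transition(tl, inst, ModuleState.COMPLETED, event.time)

    def _transition(self, tl: ParticipantTimeline, inst: ModuleInstance,
                    to_state: ModuleState, time: int) -> None:
        if (inst.state, to_state) not in _LEGAL:
            raise SchedulingError(
                f"illegal transition {inst.state.value} -> {to_state.value}")
        tr = Transition(time=time, participant_id=tl.participant_id,
                        module_id=inst.module_id, from_state=inst.state,
                        to_state=to_state)
        inst.state = to_state
        if to_state is ModuleState.OPEN:
            inst.opened_at = time
        elif to_state is ModuleState.COMPLETED:
            inst.finished_at = time
        elif to_state is ModuleState.CLOSED:
            inst.closed_at = time
        self.transitions.append(tr)

    def _pending_open(self, tl: ParticipantTimeline,
                      mod: InterventionModule) -> Optional[int]:
        inst = tl.instances[mod.id]
        if inst.state is not ModuleState.LOCKED:
            return None
        if not mod.opening_rules:
            return tl.enrollment_time
        times = [resolve_open_time(r, tl, self.now) for r in mod.opening_rules]
        times = [t for t in times if t is not None]
        return min(times) if times else None

    def _pending_close(self, tl: ParticipantTimeline,
                       mod: InterventionModule) -> Optional[int]:
        inst = tl.instances[mod.id]
        if inst.state is not ModuleState.OPEN:
            return None
        times = [resolve_close_time(r, inst, tl) for r in mod.closing_rules]
        times = [t for t in times if t is not None]
        return min(times) if times else None

    def _earliest_due(self, target: int,
                      include_closings_at_target: bool) -> Optional[int]:
        due: Optional[int] = None
        for pid in self._enroll_order:
            tl = self.timelines[pid]
            if tl.intervention_id is None:
                continue
            for mod in self._modules(tl.intervention_id):
                t_open = self._pending_open(tl, mod)
                if t_open is not None and t_open <= target:
                    due = t_open if due is None else min(due, t_open)
                t_close = self._pending_close(tl, mod)
                if t_close is not None:
                    bound = target if include_closings_at_target else target - 1
                    if t_close <= bound:
                        due = t_close if due is None else min(due, t_close)
        return due if due is None else max(due, self.now)

    def next_due(self, limit: int) -> Optional[int]:
        """Earliest minute <= limit at which a timed transition is pending."""
        return self._earliest_due(limit, include_closings_at_target=True)

    def _flush(self, target: int, include_closings_at_target: bool) -> None:
        """Fire timed transitions due up to ``target``.

        At each due minute openings are applied before closings, and the
        minute is revisited until a fixpoint (a zero-offset chain can open
        several modules in the same minute). Closings due exactly at
        ``target`` are deferred when an event at ``target`` is still to be
        applied, so a deadline-minute answer still counts.
        """
        while True:
            due = self._earliest_due(target, include_closings_at_target)
            if due is None:
                return
            progressed = False
            for pid in self._enroll_order:
                tl = self.timelines[pid]
                if tl.intervention_id is None:
                    continue
                for mod in self._modules(tl.intervention_id):
                    t_open = self._pending_open(tl, mod)
                    if t_open is not None and max(t_open, self.now) <= due:
                        self._transition(tl, tl.instances[mod.id],
                                         ModuleState.OPEN, due)
                        progressed = True
            close_bound = target if include_closings_at_target else target - 1
            for pid in self._enroll_order:
                tl = self.timelines[pid]
                if tl.intervention_id is None:
                    continue
                for mod in self._modules(tl.intervention_id):
                    t_close = self._pending_close(tl, mod)
                    if t_close is not None and t_close <= due <= close_bound:
                        self._transition(tl, tl.instances[mod.id],
                                         ModuleState.CLOSED, due)
                        progressed = True
            self.now = due
            if not progressed:
                return


def sort_events(events: Iterable[Event]) -> list[Event]:
    """Stable order by time, then enroll < answer < module_completed < tick."""
    return sorted(events, key=lambda e: (e.time, _EVENT_PRIORITY[e.kind]))


def step(study: StudyDefinition, engine: ScheduleEngine,
         event: Event) -> list[Transition]:
    """Functional wrapper around :meth:`ScheduleEngine.step`."""
    assert engine.study is study
    return engine.step(event)


def run_timeline(
    study: StudyDefinition,
    events: Iterable[Event],
    horizon: Optional[int] = None,
) -> tuple[dict[str, ParticipantTimeline], list[Transition]]:
    """Fold the whole event stream; replay-deterministic.

    ``horizon`` additionally fires every timed transition due up to that
    minute after the last event (a trailing clock tick).
    """
    engine = ScheduleEngine(study)
    for event in sort_events(events):
        engine.step(event)
    engine.flush_to(engine.now if horizon is None else max(horizon, engine.now))
    return engine.timelines, engine.transitions


# --- CSV interchange ---------------------------------------------------------

EVENT_COLUMNS = ["time", "participant_id", "kind", "module_id", "item_id", "value"]
TRANSITION_COLUMNS = ["time", "participant_id", "module_id", "from", "to"]


def events_to_csv(events: Iterable[Event]) -> str:
    df = pd.DataFrame(
        [{"time": e.time, "participant_id": e.participant_id, "kind": e.kind,
          "module_id": e.module_id, "item_id": e.item_id, "value": e.value}
         for e in events], columns=EVENT_COLUMNS)
    return df.to_csv(index=False)


def events_from_csv(text_or_path: Union[str, "pd.io.common.FilePath"]) -> list[Event]:
    src = StringIO(text_or_path) if isinstance(text_or_path, str) and "\n" in text_or_path else text_or_path
    df = pd.read_csv(src)
    events = []
    for row in df.itertuples(index=False):
        value = row.value
        if pd.isna(value):
            value = None
        events.append(Event(
            time=int(row.time), kind=str(row.kind),
            participant_id=str(row.participant_id),
            module_id=None if pd.isna(row.module_id) else str(row.module_id),
            item_id=None if pd.isna(row.item_id) else str(row.item_id),
            value=value))
    return events


def transitions_to_csv(transitions: Iterable[Transition]) -> str:
    df = pd.DataFrame(
        [{"time": t.time, "participant_id": t.participant_id,
          "module_id": t.module_id, "from": t.from_state.value,
          "to": t.to_state.value} for t in transitions],
        columns=TRANSITION_COLUMNS)
    return df.to_csv(index=False)
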