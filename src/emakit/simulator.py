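"""Virtual-participant cohort simulation.

Drives the whole stack end to end: a synthetic cohort enrolls in a study,
modules open and close per their timing rules, participants answer items
with configurable adherence and latency, and the notification planner runs
over the resulting transitions. The output is an event log (replayable
through :func:`emakit.scheduler.run_timeline` to bit-identical
transitions), the transition list, the dispatch plan, and an adherence
report.

Behavioral model: when a module opens for a participant, they complete it
with probability ``adherence_prob``; if so, all its answerable items are
answered after an exponential response latency. A participant "intending"
to respond after the module closes simply does not — the engine rejects the
late answers and the simulator never records them, which mirrors a missed
prompt. Each participant owns one pseudo-random stream derived from
(seed, participant id), so cohorts are order-independent and grow stably.
"""

from __future__ import annotations

import heapq
import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .notifications import (
    PlannedNotification,
    PlanningViolation,
    plan_notifications,
)
from .scheduler import (
    Event,
    ModuleState,
    ParticipantTimeline,
    ScheduleEngine,
    Transition,
    _EVENT_PRIORITY,
)
from .study_model import Item, StudyDefinition, validate_study


@dataclass
class AnswerModel:
    """How simulated participants answer one item.

    ``uniform_int`` draws integers on [lo, hi]; ``categorical`` draws one of
    ``codes`` with ``probs`` (uniform when omitted); ``constant`` always
    answers ``value``.
    """

    kind: str = "uniform_int"  # uniform_int | categorical | constant
    lo: int = 1
    hi: int = 10
    codes: Optional[list[float]] = None
    probs: Optional[list[float]] = None
    value: Optional[object] = None

    def draw(self, rng: np.random.Generator):
        if self.kind == "uniform_int":
            return int(rng.integers(self.lo, self.hi + 1))
        if self.kind == "categorical":
            codes = self.codes or []
            return float(rng.choice(codes, p=self.probs))
        if self.kind == "constant":
            return self.value
        raise ValueError(f"unknown answer model {self.kind!r}")


def default_answer_model(item: Item) -> AnswerModel:
    if item.options:
        return AnswerModel(kind="categorical",
                           codes=[o.code for o in item.options])
    if item.numeric:
        return AnswerModel(kind="uniform_int", lo=1, hi=10)
    return AnswerModel(kind="constant", value="free text")


@dataclass
class SimulationConfig:
    n_participants: int
    horizon: int  # minutes of simulated study time
    enrollment_window: int = 0  # enrollments uniform on [0, window]
    adherence_prob: float = 1.0
    response_latency_mean: float = 60.0  # exponential, minutes after open
    answer_models: dict[str, AnswerModel] = field(default_factory=dict)
    seed: int = 0

    def check(self) -> None:
        if not 0 <= self.adherence_prob <= 1:
            raise ValueError("adherence_prob must lie in [0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.n_participants < 0 or self.enrollment_window < 0:
            raise ValueError("counts and windows must be non-negative")
        if self.enrollment_window >= self.horizon:
            raise ValueError("enrollment window must end before the horizon")
        if self.response_latency_mean <= 0:
            raise ValueError("response latency mean must be positive")


@dataclass
class AdherenceReport:
    per_module_completion: dict[str, float] = field(default_factory=dict)
    per_participant_completion: dict[str, float] = field(default_factory=dict)
    overall_completion: float = 0.0
    mean_response_latency: float = 0.0
    notification_counts: dict[str, int] = field(default_factory=dict)
    n_opened: int = 0
    n_completed: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


@dataclass
class SimulationResult:
    events: list[Event]
    transitions: list[Transition]
    plan: list[PlannedNotification]
    plan_violations: list[PlanningViolation]
    report: AdherenceReport
    timelines: dict[str, ParticipantTimeline]


def _participant_rng(seed: int, pid: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(pid.encode()))))


def simulate_cohort(study: StudyDefinition,
                    config: SimulationConfig) -> SimulationResult:
    """Run one seeded cohort through the study.

    The study must validate cleanly. Fully deterministic given (study,
    config): the returned event log replays through ``run_timeline`` to the
    identical transition list.
    """
    config.check()
    violations = validate_study(study)
    if violations:
        raise ValueError(
            "study does not validate: " +
            "; ".join(f"{v.code} at {v.path}" for v in violations[:5]))

    item_by_id = {it.id: it for iv in study.interventions
                  for m in iv.modules for it in m.items}
    module_items = {(iv.id, m.id): m.answerable_items()
                    for iv in study.interventions for m in iv.modules}

    engine = ScheduleEngine(study)
    heap: list[tuple[int, int, int, Event]] = []
    seq = 0

    def push(event: Event) -> None:
        nonlocal seq
        heapq.heappush(heap, (event.time, _EVENT_PRIORITY[event.kind], seq, event))
        seq += 1

    rngs: dict[str, np.random.Generator] = {}
    for k in range(config.n_participants):
        pid = f"p{k:03d}"
        rngs[pid] = _participant_rng(config.seed, pid)
        t_enroll = (int(rngs[pid].integers(0, config.enrollment_window + 1))
                    if config.enrollment_window else 0)
        push(Event(time=t_enroll, kind="enroll", participant_id=pid))

    def schedule_answers(transitions: list[Transition]) -> None:
        for tr in transitions:
            if tr.to_state is not ModuleState.OPEN:
                continue
            pid = tr.participant_id
            rng = rngs[pid]
            iv_id = engine.timelines[pid].intervention_id
            items = module_items[(iv_id, tr.module_id)]
            if not items:
                continue
            if rng.random() >= config.adherence_prob:
                continue
            latency = 1 + int(rng.exponential(config.response_latency_mean))
            when = tr.time + latency
            if when > config.horizon:
                continue
            for item in items:
                model = config.answer_models.get(item.id,
                                                 default_answer_model(item))
                push(Event(time=when, kind="answer", participant_id=pid,
                           module_id=tr.module_id, item_id=item.id,
                           value=model.draw(rng)))

    # interleave heap events with the timed transitions that fall between
    # them, so answers to modules opening after the last event still happen
    log: list[Event] = []
    while True:
        t_event = heap[0][0] if heap else None
        t_timed = engine.next_due(config.horizon)
        if t_event is None and t_timed is None:
            break
        if t_timed is not None and (t_event is None or t_timed < t_event):
            schedule_answers(engine.flush_to(t_timed))
            continue
        _, _, _, event = heapq.heappop(heap)
        tl = engine.timelines.get(event.participant_id)
        rejected_before = tl.rejected_answers if tl is not None else 0
        new_transitions = engine.step(event)
        if event.kind == "answer":
            tl = engine.timelines[event.participant_id]
            if tl.rejected_answers > rejected_before:
                continue  # module no longer open: the prompt was missed
        log.append(event)
        schedule_answers(new_transitions)
    engine.flush_to(config.horizon)
    log.append(Event(time=config.horizon, kind="clock_tick",
                     participant_id="clock"))

    plan, plan_violations = plan_notifications(
        study, engine.timelines, engine.transitions, rng_seed=config.seed)
    report = adherence_report(log, engine.transitions, plan)
    return SimulationResult(events=log, transitions=engine.transitions,
                            plan=plan, plan_violations=plan_violations,
                            report=report, timelines=engine.timelines)


def adherence_report(
    events: Iterable[Event],
    transitions: Iterable[Transition],
    plan: Optional[Iterable[PlannedNotification]] = None,
) -> AdherenceReport:
    """Pure summary of a run's logs.

    Completion rates are completed/opened instances (per module, per
    participant, and overall); latency is the mean minutes from open to
    completion over completed instances.
    """
    transitions = list(transitions)
    opened: dict[tuple[str, str], int] = {}
    completed: dict[tuple[str, str], int] = {}
    for tr in transitions:
        key = (tr.participant_id, tr.module_id)
        if tr.to_state is ModuleState.OPEN:
            opened[key] = tr.time
        elif tr.to_state is ModuleState.COMPLETED:
            completed[key] = tr.time

    report = AdherenceReport()
    report.n_opened = len(opened)
    report.n_completed = len(completed)
    report.overall_completion = (len(completed) / len(opened)) if opened else 0.0

    mod_open: dict[str, int] = {}
    mod_done: dict[str, int] = {}
    pid_open: dict[str, int] = {}
    pid_done: dict[str, int] = {}
    for (pid, mod) in opened:
        mod_open[mod] = mod_open.get(mod, 0) + 1
        pid_open[pid] = pid_open.get(pid, 0) + 1
    for (pid, mod) in completed:
        mod_done[mod] = mod_done.get(mod, 0) + 1
        pid_done[pid] = pid_done.get(pid, 0) + 1
    report.per_module_completion = {
        mod: mod_done.get(mod, 0) / n for mod, n in sorted(mod_open.items())}
    report.per_participant_completion = {
        pid: pid_done.get(pid, 0) / n for pid, n in sorted(pid_open.items())}
    latencies = [completed[k] - opened[k] for k in completed if k in opened]
    report.mean_response_latency = (float(np.mean(latencies))
                                    if latencies else 0.0)
    report.notification_counts = {}
    if plan is not None:
        for p in plan:
            k = p.kind.value
            report.notification_counts[k] = report.notification_counts.get(k, 0) + 1
    return report


RESPONSE_COLUMNS = ["study_code", "intervention_id", "participant_id",
                    "module_id", "item_id", "variable", "value", "answered_at",
                    "module_state"]


def export_responses(study: StudyDefinition,
                     timelines: dict[str, ParticipantTimeline]) -> pd.DataFrame:
    """Long-format response export.

    One row per recorded answer; ``module_state`` is the final state of the
    owning module instance, so partial answers inside CLOSED modules remain
    in the export, flagged by their state.
    """
    item_meta = {}
    for iv in study.interventions:
        for m in iv.modules:
            for it in m.items:
                item_meta[(iv.id, it.id)] = (m.id, it.variable)
    rows = []
    for pid in sorted(timelines):
        tl = timelines[pid]
        if tl.intervention_id is None:
            continue
        for t, item_id, value in tl.answers:
            module_id, variable = item_meta[(tl.intervention_id, item_id)]
            rows.append({
                "study_code": study.study_code,
                "intervention_id": tl.intervention_id,
                "participant_id": pid,
                "module_id": module_id,
                "item_id": item_id,
                "variable": variable,
                "value": value,
                "answered_at": t,
                "module_state": tl.instances[module_id].state.value,
            })
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
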