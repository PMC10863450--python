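"""Module lifecycle engine: rule resolution, transitions, oracle equivalence."""

import numpy as np
import pytest

from emakit.scheduler import (
    Event,
    ModuleInstance,
    ModuleState,
    MonotonicityError,
    ParticipantTimeline,
    ScheduleEngine,
    resolve_close_time,
    resolve_open_time,
    run_timeline,
    events_from_csv,
    events_to_csv,
)
from emakit.study_model import loads_study
import json

import oracle
from conftest import make_study, slider_module


def timeline(enrolled=0, answers=(), instances=None):
    tl = ParticipantTimeline(participant_id="p", enrollment_time=enrolled,
                             intervention_id="iv")
    tl.answers = list(answers)
    for mid, inst in (instances or {}).items():
        tl.instances[mid] = inst
    return tl


def rule(doc):
    # reuse the study loader's discriminated-union parsing for a single rule
    study = make_study([slider_module("mX", "vX", opening=[doc])]) \
        if doc["rule"] in ("relative_to_intervention_start",
                           "relative_to_module_completion",
                           "on_module_not_finished", "answer_condition",
                           "fixed_datetime") else None
    return study.interventions[0].modules[0].opening_rules[0]


class TestOpeningRules:
    def test_relative_to_intervention_start_is_a_direct_offset(self):
        r = rule({"rule": "relative_to_intervention_start",
                  "offset_minutes": 1440})
        assert resolve_open_time(r, timeline(enrolled=0), now=0) == 1440
        assert resolve_open_time(r, timeline(enrolled=100), now=0) == 1540

    def test_relative_to_module_completion_offsets_from_finish(self):
        r = rule({"rule": "relative_to_module_completion",
                  "ref_module_id": "m1", "offset_minutes": 60})
        done = ModuleInstance("p", "m1", ModuleState.COMPLETED,
                              opened_at=100, finished_at=200)
        tl = timeline(instances={"m1": done})
        assert resolve_open_time(r, tl, now=250) == 260
        pending = ModuleInstance("p", "m1", ModuleState.OPEN, opened_at=100)
        assert resolve_open_time(r, timeline(instances={"m1": pending}),
                                 now=250) is None

    def test_answer_condition_fires_at_the_satisfying_answer(self):
        r = rule({"rule": "answer_condition", "ref_item_id": "q3",
                  "comparator": "ge", "value": 7})
        assert resolve_open_time(r, timeline(answers=[(100, "q3", 7)]),
                                 now=200) == 100
        assert resolve_open_time(r, timeline(answers=[(100, "q3", 5)]),
                                 now=200) is None

    def test_not_finished_check_never_arms_if_reference_never_opened(self):
        r = rule({"rule": "on_module_not_finished", "ref_module_id": "m1",
                  "check_offset_minutes": 2880})
        locked = ModuleInstance("p", "m1")
        assert resolve_open_time(r, timeline(instances={"m1": locked}),
                                 now=9999) is None
        opened = ModuleInstance("p", "m1", ModuleState.OPEN, opened_at=0)
        assert resolve_open_time(r, timeline(instances={"m1": opened}),
                                 now=0) == 2880

    def test_fixed_datetime_clamps_to_enrollment(self):
        r = rule({"rule": "fixed_datetime", "at": 50})
        assert resolve_open_time(r, timeline(enrolled=200), now=0) == 200


class TestClosingRules:
    def close_rule(self, doc):
        study = make_study([slider_module("mX", "vX", closing=[doc])])
        return study.interventions[0].modules[0].closing_rules[0]

    def test_relative_to_module_start(self):
        r = self.close_rule({"rule": "relative_to_module_start",
                             "offset_minutes": 60})
        inst = ModuleInstance("p", "m1", ModuleState.OPEN, opened_at=300)
        assert resolve_close_time(r, inst, timeline()) == 360

    def test_fixed_date(self):
        r = self.close_rule({"rule": "fixed_date", "at": 500})
        inst = ModuleInstance("p", "m1", ModuleState.OPEN, opened_at=300)
        assert resolve_close_time(r, inst, timeline()) == 500

    def test_fixed_date_in_the_past_closes_at_open(self):
        r = self.close_rule({"rule": "fixed_date", "at": 100})
        inst = ModuleInstance("p", "m1", ModuleState.OPEN, opened_at=300)
        assert resolve_close_time(r, inst, timeline()) == 300


class TestStep:
    def test_enroll_opens_zero_offset_module_at_the_same_minute(self, one_module_study):
        engine = ScheduleEngine(one_module_study)
        trs = engine.step(Event(time=5, kind="enroll", participant_id="p"))
        assert [(t.time, t.module_id, t.to_state) for t in trs] == \
            [(5, "m1", ModuleState.OPEN)]

    def test_answering_the_last_item_completes_the_module(self, one_module_study):
        engine = ScheduleEngine(one_module_study)
        engine.step(Event(time=0, kind="enroll", participant_id="p"))
        trs = engine.step(Event(time=30, kind="answer", participant_id="p",
                                item_id="m1_q", value=4))
        assert trs[-1].to_state is ModuleState.COMPLETED
        assert engine.timelines["p"].instances["m1"].finished_at == 30

    def test_unfinished_module_unlocks_the_follow_up_at_the_check(self):
        study = make_study([
            slider_module("m1", "v1"),
            slider_module("m2", "v2", opening=[
                {"rule": "on_module_not_finished", "ref_module_id": "m1",
                 "check_offset_minutes": 2880}]),
        ])
        engine = ScheduleEngine(study)
        engine.step(Event(time=0, kind="enroll", participant_id="p"))
        trs = engine.step(Event(time=2880, kind="clock_tick",
                                participant_id="p"))
        assert [(t.time, t.module_id, t.to_state) for t in trs] == \
            [(2880, "m2", ModuleState.OPEN)]

    def test_out_of_order_events_are_rejected(self, one_module_study):
        engine = ScheduleEngine(one_module_study)
        engine.step(Event(time=100, kind="enroll", participant_id="p"))
        with pytest.raises(MonotonicityError):
            engine.step(Event(time=50, kind="enroll", participant_id="q"))

    def test_answers_to_non_open_modules_are_rejected_without_state_change(self):
        study = make_study([slider_module(
            "m1", "v1",
            opening=[{"rule": "relative_to_intervention_start",
                      "offset_minutes": 500}])])
        engine = ScheduleEngine(study)
        engine.step(Event(time=0, kind="enroll", participant_id="p"))
        trs = engine.step(Event(time=10, kind="answer", participant_id="p",
                                item_id="m1_q", value=3))
        assert trs == []
        tl = engine.timelines["p"]
        assert tl.answers == [] and tl.rejected_answers == 1
        assert tl.instances["m1"].state is ModuleState.LOCKED


def chain_study():
    """Three modules, each opening right after the previous completes."""
    return make_study([
        slider_module("m1", "v1",
                      closing=[{"rule": "relative_to_module_start",
                                "offset_minutes": 1000}]),
        slider_module("m2", "v2",
                      opening=[{"rule": "relative_to_module_completion",
                                "ref_module_id": "m1", "offset_minutes": 0}]),
        slider_module("m3", "v3",
                      opening=[{"rule": "relative_to_module_completion",
                                "ref_module_id": "m2", "offset_minutes": 0}]),
    ])


class TestRunTimeline:
    def test_empty_event_list_produces_no_transitions(self, one_module_study):
        timelines, transitions = run_timeline(one_module_study, [])
        assert timelines == {} and transitions == []

    def test_chain_with_all_answers_completes_all_modules(self):
        # hand-traced: m1 opens 0, done 10; m2 opens 10, done 20; m3 ...
        events = [
            Event(0, "enroll", "p"),
            Event(10, "answer", "p", item_id="m1_q", value=5),
            Event(20, "answer", "p", item_id="m2_q", value=5),
            Event(35, "answer", "p", item_id="m3_q", value=5),
        ]
        _, trs = run_timeline(chain_study(), events)
        got = [(t.time, t.module_id, t.to_state.value) for t in trs]
        assert got == [
            (0, "m1", "OPEN"), (10, "m1", "COMPLETED"),
            (10, "m2", "OPEN"), (20, "m2", "COMPLETED"),
            (20, "m3", "OPEN"), (35, "m3", "COMPLETED"),
        ]

    def test_chain_with_no_answers_closes_first_and_keeps_rest_locked(self):
        timelines, trs = run_timeline(chain_study(),
                                      [Event(0, "enroll", "p")], horizon=5000)
        got = [(t.time, t.module_id, t.to_state.value) for t in trs]
        assert got == [(0, "m1", "OPEN"), (1000, "m1", "CLOSED")]
        tl = timelines["p"]
        assert tl.instances["m2"].state is ModuleState.LOCKED
        assert tl.instances["m3"].state is ModuleState.LOCKED

    def test_replay_is_deterministic(self):
        rng = np.random.default_rng(5)
        doc = oracle.random_study_doc(rng)
        events = oracle.random_events(rng, doc, n_participants=3, horizon=4000)
        study = oracle.load_doc(doc)
        out1 = run_timeline(study, events, horizon=4000)
        out2 = run_timeline(study, events, horizon=4000)
        assert out1[1] == out2[1]

    def test_event_csv_round_trip(self):
        events = [Event(0, "enroll", "p"),
                  Event(10, "answer", "p", item_id="m1_q", value=5)]
        again = events_from_csv(events_to_csv(events))
        assert [(e.time, e.kind, e.item_id) for e in again] == \
            [(0, "enroll", None), (10, "answer", "m1_q")]


def test_no_illegal_transition_on_random_studies_and_events():
    """State-machine safety over random studies and haphazard event streams."""
    legal = {("LOCKED", "OPEN"), ("OPEN", "COMPLETED"), ("OPEN", "CLOSED")}
    rng = np.random.default_rng(99)
    for _ in range(30):
        doc = oracle.random_study_doc(rng)
        horizon = int(rng.integers(500, 6000))
        events = oracle.random_events(rng, doc, int(rng.integers(1, 4)), horizon)
        study = oracle.load_doc(doc)
        timelines, trs = run_timeline(study, events, horizon=horizon)
        seen = {}
        for t in trs:
            assert (t.from_state.value, t.to_state.value) in legal
            key = (t.participant_id, t.module_id)
            assert seen.get(key) != "terminal"
            if t.to_state in (ModuleState.COMPLETED, ModuleState.CLOSED):
                seen[key] = "terminal"
        for tl in timelines.values():
            for inst in tl.instances.values():
                if inst.opened_at is not None and inst.finished_at is not None:
                    assert inst.opened_at <= inst.finished_at
                if inst.opened_at is not None and inst.closed_at is not None:
                    assert inst.opened_at <= inst.closed_at


def test_matches_minute_by_minute_oracle_on_random_studies():
    """Engine vs the brute-force minute loop, canonical transition order."""
    rng = np.random.default_rng(1234)
    for _ in range(25):
        doc = oracle.random_study_doc(rng)
        horizon = int(rng.integers(1000, 6000))
        events = oracle.random_events(rng, doc, int(rng.integers(1, 4)), horizon)
        study = oracle.load_doc(doc)
        _, trs = run_timeline(study, events, horizon=horizon)
        expected = oracle.minute_simulate(doc, events, horizon)
        assert oracle.canonical(trs) == oracle.canonical(expected)
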