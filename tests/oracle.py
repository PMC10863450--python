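"""Independent brute-force oracles and random generators for the suite.

Everything here deliberately re-derives semantics from first principles
rather than calling into emakit internals: a minute-by-minute scheduling
simulator, a naive recursive expression evaluator over explicit ASTs, and
seeded random generators for studies, event streams, expressions and
contexts. The only emakit imports are data constructors.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict

import numpy as np

from emakit.scheduler import Event
from emakit.study_model import loads_study

# --- minute-by-minute scheduling oracle --------------------------------------

_STATE_ORDER = {"OPEN": 0, "COMPLETED": 1, "CLOSED": 2}


def canonical(transitions):
    """Canonical order for comparing transition lists.

    Same-minute transitions of distinct instances have no semantically
    meaningful relative order, so comparison sorts by (time, participant,
    module, lifecycle phase).
    """
    rows = []
    for t in transitions:
        if hasattr(t, "to_state"):
            rows.append((t.time, t.participant_id, t.module_id,
                         t.from_state.value, t.to_state.value))
        else:
            rows.append(tuple(t))
    return sorted(rows, key=lambda r: (r[0], r[1], r[2], _STATE_ORDER[r[4]]))


def _num(v):
    try:
        x = float(v)
    except (TypeError, ValueError):
        return None
    return x if np.isfinite(x) else None


def _cmp(op, answer, target):
    a, b = _num(answer), _num(target)
    if a is None or b is None:
        if op == "eq":
            return str(answer) == str(target)
        if op == "ne":
            return str(answer) != str(target)
        return False
    return {"eq": a == b, "ne": a != b, "lt": a < b,
            "le": a <= b, "gt": a > b, "ge": a >= b}[op]


class _Inst:
    __slots__ = ("state", "opened", "finished", "answered")

    def __init__(self):
        self.state = "LOCKED"
        self.opened = None
        self.finished = None
        self.answered = set()


def minute_simulate(study_doc: dict, events: list[Event], horizon: int):
    """Replay events through a literal minute loop; emit transitions.

    Per minute: due openings (to fixpoint), then the minute's events in
    priority order, due openings again, then due closings. Opening rules
    OR-combine (earliest wins), as do closing rules.
    """
    iv = study_doc["interventions"][0]
    modules = iv["modules"]
    mod_ids = [m["id"] for m in modules]
    item_mod = {it["id"]: m["id"] for m in modules for it in m["items"]}
    answerable = {m["id"]: [it["id"] for it in m["items"]
                            if it["item_type"] != "info_content"]
                  for m in modules}
    mod_by_id = {m["id"]: m for m in modules}

    enrolled: dict[str, int] = {}
    order: list[str] = []
    inst: dict[tuple[str, str], _Inst] = {}
    answers: dict[str, list[tuple[int, str, object]]] = defaultdict(list)
    transitions: list[tuple] = []

    prio = {"enroll": 0, "answer": 1, "module_completed": 2, "clock_tick": 3}
    by_minute: dict[int, list[Event]] = defaultdict(list)
    for idx, e in enumerate(sorted(events, key=lambda e: (e.time, prio[e.kind]))):
        by_minute[e.time].append(e)

    def open_fire_time(pid, mod):
        rules = mod.get("opening_rules", [])
        if not rules:
            return enrolled[pid]
        times = []
        for r in rules:
            k = r["rule"]
            if k == "relative_to_intervention_start":
                times.append(enrolled[pid] + r["offset_minutes"])
            elif k == "fixed_datetime":
                times.append(max(r["at"], enrolled[pid]))
            elif k == "relative_to_module_completion":
                ref = inst[(pid, r["ref_module_id"])]
                if ref.finished is not None:
                    times.append(ref.finished + r["offset_minutes"])
            elif k == "on_module_not_finished":
                ref = inst[(pid, r["ref_module_id"])]
                if ref.opened is not None:
                    check = ref.opened + r["check_offset_minutes"]
                    if ref.finished is None or ref.finished >= check:
                        times.append(check)
            elif k == "answer_condition":
                for t, iid, v in answers[pid]:
                    if iid == r["ref_item_id"] and _cmp(r["comparator"], v,
                                                        r["value"]):
                        times.append(t)
                        break
        return min(times) if times else None

    def close_fire_time(pid, mod):
        ins = inst[(pid, mod["id"])]
        times = []
        for r in mod.get("closing_rules", []):
            k = r["rule"]
            if k == "fixed_date":
                times.append(max(r["at"], ins.opened))
            elif k == "relative_to_module_start":
                times.append(ins.opened + r["offset_minutes"])
            elif k == "answer_condition":
                for t, iid, v in answers[pid]:
                    if iid == r["ref_item_id"] and _cmp(r["comparator"], v,
                                                        r["value"]):
                        times.append(max(t, ins.opened))
                        break
        return min(times) if times else None

    def fire_opens(m):
        changed = True
        while changed:
            changed = False
            for pid in order:
                for mid in mod_ids:
                    ins = inst[(pid, mid)]
                    if ins.state != "LOCKED":
                        continue
                    t = open_fire_time(pid, mod_by_id[mid])
                    if t is not None and t <= m:
                        ins.state, ins.opened = "OPEN", m
                        transitions.append((m, pid, mid, "LOCKED", "OPEN"))
                        changed = True

    def fire_closes(m):
        for pid in order:
            for mid in mod_ids:
                ins = inst[(pid, mid)]
                if ins.state != "OPEN":
                    continue
                t = close_fire_time(pid, mod_by_id[mid])
                if t is not None and t <= m:
                    ins.state = "CLOSED"
                    transitions.append((m, pid, mid, "OPEN", "CLOSED"))

    for m in range(horizon + 1):
        if order:
            fire_opens(m)
        for e in by_minute.get(m, ()):
            if e.kind == "enroll":
                enrolled[e.participant_id] = m
                order.append(e.participant_id)
                for mid in mod_ids:
                    inst[(e.participant_id, mid)] = _Inst()
            elif e.kind == "answer":
                mid = item_mod.get(e.item_id)
                if mid is None or e.participant_id not in enrolled:
                    continue
                ins = inst[(e.participant_id, mid)]
                if ins.state != "OPEN":
                    continue
                answers[e.participant_id].append((m, e.item_id, e.value))
                ins.answered.add(e.item_id)
                need = answerable[mid]
                if need and set(need) <= ins.answered:
                    ins.state, ins.finished = "COMPLETED", m
                    transitions.append((m, e.participant_id, mid,
                                        "OPEN", "COMPLETED"))
            elif e.kind == "module_completed":
                ins = inst.get((e.participant_id, e.module_id))
                if ins is not None and ins.state == "OPEN":
                    ins.state, ins.finished = "COMPLETED", m
                    transitions.append((m, e.participant_id, e.module_id,
                                        "OPEN", "COMPLETED"))
        if order:
            fire_opens(m)
            fire_closes(m)
    return transitions


# --- random studies and event streams ----------------------------------------

def random_study_doc(rng: np.random.Generator, n_modules: int | None = None,
                     with_notifications: bool = False) -> dict:
    """A random valid single-intervention study document (as a dict)."""
    n_modules = n_modules or int(rng.integers(1, 6))
    modules = []
    item_ids = []
    for j in range(n_modules):
        mid = f"m{j}"
        items = [{"id": f"q{j}_{k}", "item_type": "slider",
                  "prompt": f"Q {j}.{k}", "variable": f"v{j}_{k}"}
                 for k in range(int(rng.integers(1, 3)))]
        opening = []
        if j == 0 or rng.random() < 0.4:
            opening.append({"rule": "relative_to_intervention_start",
                            "offset_minutes": int(rng.integers(0, 300))})
        else:
            choice = rng.integers(0, 4)
            ref = f"m{int(rng.integers(0, j))}"
            if choice == 0:
                opening.append({"rule": "relative_to_module_completion",
                                "ref_module_id": ref,
                                "offset_minutes": int(rng.integers(0, 500))})
            elif choice == 1:
                opening.append({"rule": "on_module_not_finished",
                                "ref_module_id": ref,
                                "check_offset_minutes": int(rng.integers(0, 1000))})
            elif choice == 2 and item_ids:
                opening.append({"rule": "answer_condition",
                                "ref_item_id": str(rng.choice(item_ids)),
                                "comparator": str(rng.choice(
                                    ["eq", "ne", "lt", "le", "gt", "ge"])),
                                "value": int(rng.integers(1, 11))})
            else:
                opening.append({"rule": "fixed_datetime",
                                "at": int(rng.integers(0, 3000))})
        if rng.random() < 0.3:  # a second OR'd rule
            opening.append({"rule": "relative_to_intervention_start",
                            "offset_minutes": int(rng.integers(0, 2000))})
        closing = []
        if rng.random() < 0.7:
            closing.append({"rule": "relative_to_module_start",
                            "offset_minutes": int(rng.integers(30, 2500))})
        if rng.random() < 0.2:
            closing.append({"rule": "fixed_date",
                            "at": int(rng.integers(0, 5000))})
        if rng.random() < 0.2 and item_ids:
            closing.append({"rule": "answer_condition",
                            "ref_item_id": str(rng.choice(item_ids)),
                            "comparator": "ge",
                            "value": int(rng.integers(5, 11))})
        notifications = []
        if with_notifications:
            notifications.append({"kind": "reminder",
                                  "reminder_offset_minutes":
                                      int(rng.integers(15, 240))})
            if rng.random() < 0.5:
                notifications.append({
                    "kind": "opening",
                    "trigger": {"trigger": "interval_after_open",
                                "window": [0, int(rng.integers(1, 60))]}})
            if any(c["rule"] in ("fixed_date", "relative_to_module_start")
                   for c in closing):
                notifications.append({"kind": "closing",
                                      "text": "closing soon"})
        modules.append({"id": mid, "title": f"Module {j}", "items": items,
                        "opening_rules": opening, "closing_rules": closing,
                        "notifications": notifications})
        item_ids.extend(it["id"] for it in items)
    return {"schema_version": 1, "study_code": "RND1",
            "interventions": [{"id": "iv", "modules": modules}]}


def random_events(rng: np.random.Generator, study_doc: dict,
                  n_participants: int, horizon: int) -> list[Event]:
    """Random enrollments plus haphazard answers (some inevitably late)."""
    items = [it["id"] for m in study_doc["interventions"][0]["modules"]
             for it in m["items"]]
    events = []
    for p in range(n_participants):
        pid = f"p{p}"
        t0 = int(rng.integers(0, max(1, horizon // 10)))
        events.append(Event(time=t0, kind="enroll", participant_id=pid))
        for _ in range(int(rng.integers(0, 4 * len(items)))):
            events.append(Event(
                time=int(rng.integers(t0, horizon + 1)), kind="answer",
                participant_id=pid, item_id=str(rng.choice(items)),
                value=int(rng.integers(1, 11))))
    return events


def load_doc(doc: dict):
    return loads_study(json.dumps(doc))


# --- naive expression oracle -------------------------------------------------
#
# Random expression ASTs are plain tuples:
#   ("num", x) ("var", name) ("neg", a) ("bin", op, a, b)
#   ("call", fname, argnames...)

class NaiveUndefined(Exception):
    pass


class NaiveError(Exception):
    pass


def naive_eval(ast, assigned, answers, scope=None):
    """Directly evaluate a tuple AST; raises NaiveUndefined/NaiveError."""
    kind = ast[0]
    if kind == "num":
        return float(ast[1])
    if kind == "var":
        mine = [(t, i, v) for i, (pid, t, v) in enumerate(
            answers.get(ast[1], [])) if pid == scope]
        if scope is None:
            raise NaiveError("bare variable in cohort scope")
        if not mine:
            raise NaiveUndefined()
        return float(max(mine)[2])
    if kind == "neg":
        return -naive_eval(ast[1], assigned, answers, scope)
    if kind == "bin":
        a = naive_eval(ast[2], assigned, answers, scope)
        b = naive_eval(ast[3], assigned, answers, scope)
        op = ast[1]
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            if b == 0:
                raise NaiveError("division by zero")
            return a / b
        if op == "^":
            r = a ** b
            if isinstance(r, complex):
                raise NaiveError("complex power")
            return r
    if kind == "call":
        name = ast[1]
        vals = [float(v) for (_, _, v) in answers.get(ast[2], [])]
        pids = {p for (p, _, _) in answers.get(ast[2], [])}
        if name == "NUM_PS":
            return float(assigned)
        if name == "NUM_P_ANS":
            return float(len(pids))
        if name == "SUM_ANS":
            return float(sum(vals))
        if name == "MODE_ANS":
            if not vals:
                raise NaiveUndefined()
            freq = Counter(vals)
            best = max(freq.values())
            modal = [v for v, c in freq.items() if c == best]
            return modal[0] if len(modal) == 1 else sum(vals) / len(vals)
        if name == "COUNT_ANS":
            target = naive_eval(ast[3], assigned, answers, scope)
            return float(sum(1 for v in vals if v == target))
    raise NaiveError(f"bad node {ast!r}")


def render(ast) -> str:
    """Fully parenthesized source text for a tuple AST."""
    kind = ast[0]
    if kind == "num":
        x = ast[1]
        return repr(int(x)) if float(x).is_integer() else repr(x)
    if kind == "var":
        return ast[1]
    if kind == "neg":
        return f"(-{render(ast[1])})"
    if kind == "bin":
        return f"({render(ast[2])} {ast[1]} {render(ast[3])})"
    if kind == "call":
        if ast[1] == "COUNT_ANS":
            return f"COUNT_ANS({ast[2]}, {render(ast[3])})"
        return f"{ast[1]}({ast[2]})"
    raise ValueError(ast)


VARS = ["n1", "n2", "mood"]


def random_ast(rng: np.random.Generator, depth: int = 0):
    roll = rng.random()
    if depth >= 4 or roll < 0.3:
        if rng.random() < 0.5:
            return ("num", int(rng.integers(0, 10)))
        return ("var", str(rng.choice(VARS)))
    if roll < 0.45:
        name = str(rng.choice(["SUM_ANS", "NUM_PS", "NUM_P_ANS", "MODE_ANS"]))
        return ("call", name, str(rng.choice(VARS)))
    if roll < 0.55:
        return ("call", "COUNT_ANS", str(rng.choice(VARS)),
                ("num", int(rng.integers(0, 10))))
    if roll < 0.65:
        return ("neg", random_ast(rng, depth + 1))
    op = str(rng.choice(["+", "-", "*", "/", "^"]))
    if op == "^":  # keep magnitudes sane
        return ("bin", "^", random_ast(rng, 4), ("num", int(rng.integers(0, 4))))
    return ("bin", op, random_ast(rng, depth + 1), random_ast(rng, depth + 1))


def random_answers(rng: np.random.Generator):
    answers = {}
    pids = [f"p{i}" for i in range(int(rng.integers(1, 5)))]
    for var in VARS:
        recs = []
        for t in range(int(rng.integers(0, 6))):
            recs.append((str(rng.choice(pids)), t * 10 + int(rng.integers(0, 10)),
                         int(rng.integers(0, 10))))
        if recs:
            answers[var] = recs
    return len(pids), answers
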