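# emakit

A headless Python engine for mobile **EMA/EMI intervention studies**
(ecological momentary assessment / intervention, including just-in-time
adaptive designs). It is aimed at researchers and engineers who design
smartphone-delivered behavioral studies — mood diaries, self-control
training, resilience coaching — and want to prototype, test and simulate
the *behavioral logic* of such a study at their desk, without an app, a
push-notification service, or a participant in sight.

A study is a declarative tree: a **study** (joined via a short study code)
holds one or more **interventions**; an intervention is an ordered list of
**modules** (chapters); a module holds **items** (questions or
informational content). The engine implements, per participant:

* **Module scheduling** — a module is a state machine
  `LOCKED → OPEN → {COMPLETED, CLOSED}`, driven by declarative timing
  rules. Opening rules: a relative time after the intervention started; a
  relative time after another module finished; when another module has
  *not* been finished by a check time; when an item answer satisfies a
  condition; a fixed date and time. Closing rules: an answer condition, a
  fixed date, or a relative time after the module started. Several rules
  OR-combine; the earliest one wins.
* **Notification planning** — opening notifications on an interval or
  fixed date, reminder notifications no earlier than **15 minutes** after
  the module becomes available, closing notifications **exactly 15
  minutes** before the close; at most one opening and one closing
  notification per module, and a closing notification only where the close
  time is knowable in advance.
* **Calculated variables** — an arithmetic expression language
  (`+ - * / ^`, standard precedence, right-associative `^`) over item
  variables plus cohort aggregation functions `SUM_ANS(N)`, `NUM_PS(N)`,
  `NUM_P_ANS(N)`, `MODE_ANS(N)` (mean fallback when there is no mode) and
  `COUNT_ANS(VAR, VAL)`, with undefined-propagation for missing answers.
* **Biomarkers** — daily aggregation of step counts, pulse rate and
  variability, and sleep episodes (interval union, wearable preferred over
  phone), bound as expression variables; plus a seeded synthetic stream
  generator.
* **Simulation** — seeded virtual cohorts with configurable adherence,
  response latency and answer models, producing replayable event logs,
  transition lists, notification plans and adherence reports.

## Worked example

```python
import emakit as ek

study = ek.load_study(ek.example_study_path())   # 3-module reflection study
assert ek.validate_study(study) == []

result = ek.simulate_cohort(study, ek.SimulationConfig(
    n_participants=20, horizon=10080, adherence_prob=0.7, seed=3))
print(result.report.per_module_completion)
print(result.report.notification_counts)

ctx = ek.EvaluationContext(assigned_participants=3)
ctx.record("p1", 10, "N", 6)
ctx.record("p2", 20, "N", 4)
print(ek.evaluate_source("NUM_PS(N)", ctx),
      ek.evaluate_source("NUM_P_ANS(N)", ctx),
      ek.evaluate_source("SUM_ANS(N)", ctx))
```

prints

```
{'m_day2': 0.4166666666666667, 'm_low_mood_support': 0.8571428571428571, 'm_welcome': 0.6}
{'opening': 20, 'reminder': 19, 'closing': 9}
3.0 2.0 10.0
```

Of the 20 enrolled participants, 60% completed the welcome module; the
day-2 module only opens for those who did, and the support module opens
either on a low mood answer or when day 2 goes unfinished — hence the
differing per-module rates. The aggregation calls read: 3 participants
assigned, 2 of them answered variable `N`, and their answers sum to 10.

The same stack is scriptable from a shell:

```bash
emakit validate path/to/my.study.json
emakit simulate --study my.study.json --config sim.yaml --out results/
emakit eval --expr "MODE_ANS(mood)" --responses responses.csv --assigned 30
```

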