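# Methods

This note documents the behavioral model the engine implements, the
choices made where the semantics were genuinely open, and what the
synthetic cohorts do and do not tell you about real studies.

## Time model

All clock quantities are integer minutes from a study-local epoch;
timestamps are timezone-naive. The finest timing constant in the domain is
the 15-minute notification lead, so minute resolution is exact and avoids
every sub-minute ambiguity. Days for biomarker aggregation are the windows
`[1440·d, 1440·(d+1))`.

## Study schema and validation

The canonical serialization is one JSON schema (`schema_version: 1`); YAML
is accepted as an alternate surface syntax of the same schema. Unknown
fields and unknown item types are hard errors, not warnings: the target
users are no-code study designers and silent schema drift is worse than a
loud failure. Validation is a pure function returning violations as data
(stable-ordered by path), so a front end can show all problems at once.
Structural soundness (every rule reference resolves, variable names unique
per intervention, notification cardinality respected) guarantees the
scheduler and evaluator never hit a dangling reference at runtime.

Modules cannot be shared between interventions; a design that wants the
same chapter in two intervention arms duplicates it. This keeps every rule
reference intra-intervention and unambiguous.

## Scheduling semantics

Each module instance is a state machine `LOCKED → OPEN → {COMPLETED,
CLOSED}`; COMPLETED and CLOSED are terminal and there is no re-opening.
The open rule variants and close rule variants are each OR-combined:
**the earliest rule to fire wins**. The rule catalog states when a module
*can* open or close but not how multiple rules interact; OR/earliest-wins
matches the natural "enable as soon as a condition is met" reading and is
the simplest semantics a designer can predict.

Decisions on the open corners of the rule table:

* A module with no opening rules opens at enrollment; with no closing
  rules it stays open until completed.
* A fixed opening date earlier than enrollment opens the module at
  enrollment; a fixed close date earlier than the open closes the module
  the minute it opens (OPEN then CLOSED at the same minute).
* The "module not finished" check is anchored at the referenced module's
  open time plus the configured offset. If the referenced module never
  opens, the check never arms — an unopened module is not treated as
  unfinished. The check sees the state at the *start* of its minute, so a
  module finished exactly at the check minute counts as unfinished.
* An answer-condition opening evaluates the participant's full answer
  history and fires at the satisfying answer's timestamp. An
  answer-condition close fires at the satisfying answer's time, clamped to
  the module's open time.
* Module completion means every answerable item has been answered at
  least once while the module was open; informational items require no
  interaction. Answers to modules that are not OPEN are rejected and cause
  no state change; partial answers inside a module that closed are kept in
  the export, flagged by the module state.

Within one minute the order is: timed openings, then all of that minute's
events, then closings. Consequently an answer submitted at the closing
deadline still counts. The engine is event-driven, but its observable
behavior is defined as if a minute-by-minute loop evaluated every rule;
the test suite enforces exact agreement with such a brute-force simulator
over randomized studies and event streams (same-minute transitions of
distinct instances are compared order-insensitively, since no semantics
attaches to their relative order).

## Notifications

Notifications are planned, not sent: the planner emits a dispatch table
(CSV) and transport is out of scope. Timing semantics:

* reminders dispatch no earlier than 15 minutes after the module opens
  (the default is exactly 15; configuration can only raise it);
* closing notifications dispatch exactly 15 minutes before the close,
  which is only computable for fixed-date and relative-after-start closing
  rules — hence the validator's compatibility constraint. If a module's
  lifetime is shorter than the lead, the notification is dropped and a
  planning violation recorded rather than dispatched late.
* "random interval" triggers are uniform integer-minute draws on the
  configured window, from a stream keyed by (seed, participant, module,
  kind) so plans are reproducible and order-independent.

A notification is suppressed when its module instance reached COMPLETED or
CLOSED strictly before the dispatch minute; a terminal event in the
dispatch minute itself does not suppress (the push and the action race in
reality; the plan keeps the push).

## Expression language

Grammar: `+ - * / ^` with standard precedence, `^` highest and
right-associative, unary minus below `^` (`-2^2 = -4`), parentheses.
The five aggregation functions always evaluate in cohort scope; a bare
variable reference resolves to the scoped participant's most recent
answer. Semantics pinned down beyond the operator list:

* `NUM_PS(N)` reports the intervention's *assignment* count — context, not
  answers — so 3 assigned / 2 answering yields 3.
* `SUM_ANS(N)` sums **all** recorded responses, not distinct values. The
  phrase "sum of the different participant responses" is ambiguous; the
  all-responses reading keeps `SUM_ANS / NUM_P_ANS`-style means coherent
  and matches `COUNT_ANS` partitioning the responses by value.
* `MODE_ANS(N)` returns the most frequent response; when the maximal
  frequency is shared by two or more values ("no mode") it returns the
  mean of **all** answers (not of per-participant latest answers). No
  answers at all is undefined.
* `COUNT_ANS` equality is exact on integers and within 1e-9 relative
  tolerance on non-integer answers.
* Missing data propagates as a distinguished *undefined* value,
  short-circuiting left to right; scheduling rules over an undefined
  expression simply do not fire. Division by zero is a hard evaluation
  error, never NaN. Non-numeric answers are excluded from aggregations and
  the exclusion count is tallied on the context.

`three_day_average` packages the canonical use case (one daily 1–10 item
asked across three modules): the per-participant mean over the answers
that exist, so missed days shrink the denominator; no answers is
undefined.

## Biomarkers

Daily summaries: steps summed, pulse averaged, sleep episodes unioned as
intervals before measuring duration (overlapping reports are never double
counted). A sleep episode spanning midnight belongs to the day it ends —
the waking day, which is the day whose questionnaire would reference the
night. When both a wearable and the phone report sleep for the same day
only the wearable is used: wearable sleep is informed by heart rate while
phone sleep is inferred from alarms and non-usage, and mixing the two
double-counts. The per-day union is capped at 1440 minutes (an episode
longer than a day, attributed wholly to its end day, could otherwise
exceed the day). Pulse-rate variability is ingested as a delivered value;
no RMSSD-style computation is attempted. Plausibility bounds (pulse in
(20, 260) bpm, non-negative steps, non-empty sleep intervals) reject
malformed samples with a logged count.

The synthetic generator emulates: lognormal daily step totals (defaults
`μ=8.91, σ=0.45` on the log scale, mean ≈ 8.2 k steps — a typical
phone-measured adult day) split across daytime point samples; normal pulse
samples around 72 ± 8 bpm; one nightly sleep episode, onset near 23:00 and
duration 480 ± 45 min, with an extra ±60 min of noise on both for
phone-only participants, echoing the lower fidelity of alarm/non-usage
inference. It does **not** emulate intra-day activity structure, missing
wear days, device clock drift, or correlations between sleep and next-day
activity — so passing tests show the aggregation arithmetic is right, not
that real wearable data will be this clean.

## Simulation

A virtual participant completes an opened module with probability
`adherence_prob`; if so, all its answerable items are answered after an
exponential response latency (default mean 60 min), at one minute.
Latencies that land after the module closes are simply lost — the prompt
was missed — which is why completion rates recover `adherence_prob` only
for modules that stay open long enough. Each participant owns one RNG
stream derived from (seed, participant id), so cohorts are
order-independent and stable under growth. Answer values default to
uniform integers 1–10 for numeric items and uniform option codes for coded
items; there is no treatment-response model, so simulated answers carry no
effect to detect.

The emitted event log is self-contained: replaying it through
`run_timeline` reproduces the transition list bit-for-bit, which the suite
asserts.

## Problem sizes and tolerances

The randomized suites use: 100 random studies (≤ 5 modules) with horizons
up to 10 000 minutes for scheduler/oracle equivalence; 100 simulated
cohorts for the notification property suite; 1 000 random expressions for
the evaluator oracle; adherence recovery at n = 200 participants judged
within three binomial standard errors; the step-mean check at 200
generated days within three standard errors of the configured lognormal
mean. Exact integer arithmetic (minutes, counts) is compared exactly;
float comparisons use relative tolerances of 1e-12 (evaluator oracle) or
the sampling-error bounds above.

## Known limitations

No re-opening or module repeats, no cross-study dependencies, no
multi-study workspaces, no real wall-clock daemon, no push transport, no
behavior-change modeling. Waitlisted participants are recorded but receive
no module instances. The expression language has no string or date
functions.
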