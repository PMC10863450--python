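"""Wearable and phone biomarker streams and their daily aggregation.

Samples arrive as timestamped records — step counts, pulse rate (beats per
minute), pulse-rate variability (milliseconds), and sleep episodes
(intervals) — from either the phone or a wearable. The engine reduces them
to one :class:`DailySummary` per participant-day, which can then be bound
as expression variables (``steps_today``, ``mean_pulse_today``,
``sleep_minutes_last_night``) so that timing rules and feedback can react
to objective data.

Aggregation rules:

* steps are summed per day (a day is minutes ``[1440*d, 1440*(d+1))``);
* pulse-rate samples are averaged per day;
* sleep episodes are unioned as intervals before measuring duration, so
  overlapping reports are not double-counted; an episode spanning midnight
  is attributed to the day it ends (the waking day);
* when both the wearable and the phone report sleep for a day, only the
  wearable's episodes are used — phone sleep is inferred from alarms and
  non-usage and is markedly noisier than heart-rate-informed wearable
  sleep.

The synthetic generator emulates a realistic cohort stream for exercising
the stack end to end: lognormal daily step totals split over the day,
normal pulse samples, one nightly sleep episode whose timing noise depends
on the source.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .calc_expr import EvaluationContext

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

SAMPLE_KINDS = ("steps", "pulse_rate", "pulse_rate_variability", "sleep_episode")
SOURCES = ("phone", "wearable")


@dataclass(frozen=True)
class BiomarkerSample:
    participant_id: str
    kind: str  # steps | pulse_rate | pulse_rate_variability | sleep_episode
    start: int  # minutes
    end: int    # minutes; == start for point samples
    value: Optional[float] = None  # None for sleep episodes (interval carries it)
    source: str = "phone"

    def valid(self) -> bool:
        if self.kind not in SAMPLE_KINDS or self.source not in SOURCES:
            return False
        if self.start > self.end or self.start < 0:
            return False
        if self.kind == "sleep_episode":
            return self.end > self.start
        if self.value is None or not math.isfinite(self.value):
            return False
        if self.kind == "steps":
            return self.value >= 0
        if self.kind == "pulse_rate":
            return 20 < self.value < 260
        return True  # variability: delivered value, ingested as given


@dataclass
class DailySummary:
    participant_id: str
    day: int  # day index: minutes // 1440
    total_steps: float = 0.0
    mean_pulse: Optional[float] = None
    mean_pulse_variability: Optional[float] = None
    sleep_minutes: Optional[int] = None
    sources_present: set[str] = field(default_factory=set)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open integer intervals."""
    total, cur_start, cur_end = 0, None, None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def aggregate_daily(samples: Iterable[BiomarkerSample]) -> list[DailySummary]:
    """Reduce a sample stream to per-participant daily summaries.

    Point samples belong to the day of their timestamp; sleep episodes to
    the day they end. Invalid samples (negative steps, out-of-range pulse,
    empty sleep intervals) are rejected and counted in the log. The unioned
    sleep duration is capped at one day.
    """
    rejected = 0
    by_day: dict[tuple[str, int], list[BiomarkerSample]] = {}
    for s in samples:
        if not s.valid():
            rejected += 1
            continue
        anchor = s.end if s.kind == "sleep_episode" else s.start
        by_day.setdefault((s.participant_id, anchor // MINUTES_PER_DAY), []).append(s)
    if rejected:
        logger.warning("aggregate_daily rejected %d invalid samples", rejected)

    out: list[DailySummary] = []
    for (pid, day) in sorted(by_day):
        # canonical in-group order makes float reductions independent of
        # the order samples arrived in
        group = sorted(by_day[(pid, day)],
                       key=lambda s: (s.start, s.end, s.kind, s.source,
                                      -1.0 if s.value is None else s.value))
        summary = DailySummary(participant_id=pid, day=day)
        summary.sources_present = {s.source for s in group}
        steps = [s.value for s in group if s.kind == "steps"]
        if steps:
            summary.total_steps = float(sum(steps))
        pulse = [s.value for s in group if s.kind == "pulse_rate"]
        if pulse:
            summary.mean_pulse = float(np.mean(pulse))
        hrv = [s.value for s in group if s.kind == "pulse_rate_variability"]
        if hrv:
            summary.mean_pulse_variability = float(np.mean(hrv))
        sleep = [s for s in group if s.kind == "sleep_episode"]
        if sleep:
            wearable = [s for s in sleep if s.source == "wearable"]
            chosen = wearable if wearable else sleep
            minutes = _union_length([(s.start, s.end) for s in chosen])
            summary.sleep_minutes = min(minutes, MINUTES_PER_DAY)
        out.append(summary)
    return out


# --- synthetic streams -------------------------------------------------------

@dataclass
class StreamConfig:
    """Distribution parameters for the synthetic biomarker generator.

    Daily step totals are lognormal (median ``exp(steps_mu)`` ≈ 7,400 steps
    by default, a typical adult phone-measured day) and are split over
    several daytime point samples. Pulse samples are normal around a
    resting-to-light-activity mean. One sleep episode per night: bedtime
    jitters around 23:00, duration around 8 h; phone-only sleep gets extra
    timing noise on both ends, mirroring its alarm/non-usage inference.
    """

    steps_mu: float = 8.91      # log-scale mean of the daily total
    steps_sigma: float = 0.45   # log-scale sd
    steps_samples_per_day: int = 6
    pulse_mean: float = 72.0    # beats/min
    pulse_sd: float = 8.0
    pulse_samples_per_day: int = 8
    hrv_mean: float = 42.0      # ms
    hrv_sd: float = 12.0
    sleep_onset_minute: int = 1380   # 23:00
    sleep_onset_sd: float = 30.0
    sleep_duration_mean: float = 480.0
    sleep_duration_sd: float = 45.0
    phone_sleep_extra_sd: float = 60.0  # phone-only inference is noisier
    wearable_fraction: float = 0.5      # share of participants with a wearable

    def mean_daily_steps(self) -> float:
        """Analytic mean of the configured lognormal daily total."""
        return math.exp(self.steps_mu + self.steps_sigma ** 2 / 2)

    def check(self) -> None:
        if self.steps_sigma <= 0 or self.pulse_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0 <= self.wearable_fraction <= 1:
            raise ValueError("wearable_fraction must lie in [0, 1]")
        if self.steps_samples_per_day < 1 or self.pulse_samples_per_day < 1:
            raise ValueError("need at least one sample per day per kind")
        if not 0 < self.sleep_duration_mean < MINUTES_PER_DAY:
            raise ValueError("mean sleep duration must be inside one day")


def generate_synthetic_stream(
    config: StreamConfig,
    n_participants: int,
    n_days: int,
    seed: int,
) -> list[BiomarkerSample]:
    """Generate a reproducible cohort biomarker stream.

    One independent RNG stream per participant (derived from the seed and
    the participant index), so the stream for participant *k* does not
    change when the cohort grows.
    """
    config.check()
    samples: list[BiomarkerSample] = []
    for k in range(n_participants):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), k)))
        pid = f"p{k:04d}"
        wearable = rng.random() < config.wearable_fraction
        source = "wearable" if wearable else "phone"
        for day in range(n_days):
            base = day * MINUTES_PER_DAY
            total = rng.lognormal(config.steps_mu, config.steps_sigma)
            shares = rng.dirichlet(np.ones(config.steps_samples_per_day))
            minutes = np.sort(rng.integers(8 * 60, 22 * 60,
                                           config.steps_samples_per_day))
            for m, share in zip(minutes, shares):
                samples.append(BiomarkerSample(
                    pid, "steps", base + int(m), base + int(m),
                    float(round(total * share)), source="phone"))
            for _ in range(config.pulse_samples_per_day):
                t = base + int(rng.integers(7 * 60, 23 * 60))
                bpm = float(np.clip(rng.normal(config.pulse_mean, config.pulse_sd),
                                    21, 259))
                samples.append(BiomarkerSample(pid, "pulse_rate", t, t, bpm,
                                               source=source))
                if wearable:
                    hrv = float(max(rng.normal(config.hrv_mean, config.hrv_sd), 1.0))
                    samples.append(BiomarkerSample(
                        pid, "pulse_rate_variability", t, t, hrv, source=source))
            onset_sd = config.sleep_onset_sd + (
                0 if wearable else config.phone_sleep_extra_sd)
            dur_sd = config.sleep_duration_sd + (
                0 if wearable else config.phone_sleep_extra_sd)
            onset = base + config.sleep_onset_minute + int(
                round(rng.normal(0, onset_sd)))
            duration = int(np.clip(round(rng.normal(config.sleep_duration_mean,
                                                    dur_sd)),
                                   60, MINUTES_PER_DAY - 1))
            samples.append(BiomarkerSample(
                pid, "sleep_episode", max(onset, 0), max(onset, 0) + duration,
                None, source=source))
    samples.sort(key=lambda s: (s.start, s.participant_id, s.kind))
    return samples


def bind_as_variables(summaries: Iterable[DailySummary]) -> EvaluationContext:
    """Expose daily summaries as answer histories for the expression DSL.

    Each summary contributes ``steps_today``, ``mean_pulse_today`` and
    ``sleep_minutes_last_night`` answers timestamped at the end of its day,
    so scheduling rules and calculated variables can aggregate over them
    exactly like questionnaire answers.
    """
    ctx = EvaluationContext()
    pids = set()
    for s in summaries:
        pids.add(s.participant_id)
        t = (s.day + 1) * MINUTES_PER_DAY - 1
        ctx.record(s.participant_id, t, "steps_today", s.total_steps)
        if s.mean_pulse is not None:
            ctx.record(s.participant_id, t, "mean_pulse_today", s.mean_pulse)
        if s.sleep_minutes is not None:
            ctx.record(s.participant_id, t, "sleep_minutes_last_night",
                       float(s.sleep_minutes))
    ctx.assigned_participants = len(pids)
    return ctx


# --- CSV interchange ---------------------------------------------------------

SAMPLE_COLUMNS = ["participant_id", "kind", "value", "start", "end", "source"]


def samples_to_csv(samples: Iterable[BiomarkerSample]) -> str:
    df = pd.DataFrame(
        [{"participant_id": s.participant_id, "kind": s.kind, "value": s.value,
          "start": s.start, "end": s.end, "source": s.source}
         for s in samples], columns=SAMPLE_COLUMNS)
    return df.to_csv(index=False)


def samples_from_csv(path_or_buf: Union[str, object]) -> list[BiomarkerSample]:
    df = pd.read_csv(path_or_buf)
    return [BiomarkerSample(
        participant_id=str(r.participant_id), kind=str(r.kind),
        value=None if pd.isna(r.value) else float(r.value),
        start=int(r.start), end=int(r.end), source=str(r.source))
        for r in df.itertuples(index=False)]
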