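"""Per-animal behavioral quantification within analysis windows.

For trial-structured tests all durations come from bouts clipped to the
per-trial windows (40 s before + 80 s after time 0); consumption is
additionally restricted to the reward phase, because the resource is
simply not accessible during the inter-trial interval. For continuous
tests (SC, WC) the whole session is quantified.

Percent time consuming is normalized by the *effective* consumption
observation time — 400 s for trial tests (80 s × 5 trials), 600 s for
continuous ones — so consumption levels are comparable across tests of
different structure.

Ratios with empty denominators (e.g. pushing success with zero pushing
bouts) are reported as missing, never zero-filled: a rat that never pushed
tells us nothing about its efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from dyadrank.ethogram_io import (
    Animal,
    Behavior,
    EventRecord,
    PELLET_TESTS,
    PushOutcome,
    TestCode,
)
from dyadrank.sessions import AnalysisWindow, SessionSpec, clip_events, overlap

__all__ = [
    "BehaviorSummary",
    "latency_all_pellets",
    "pushing_success_pct",
    "split_exploration_by_phase",
    "summaries_to_frame",
    "summarize_session",
]

#: Pellets delivered per trial in the food-competition tests.
PELLETS_PER_TRIAL = 10


@dataclass(frozen=True)
class BehaviorSummary:
    """Windowed per-animal quantities for one (pair, test, day) session."""

    pair_id: str
    animal_id: Animal
    test_code: TestCode
    day: int
    # per-behavior aggregates over the analysis windows
    total_duration: dict[Behavior, float] = field(default_factory=dict)
    bout_count: dict[Behavior, int] = field(default_factory=dict)
    latency_to_first: dict[Behavior, float | None] = field(default_factory=dict)
    #: pellets eaten (mFC/mFCD) or drinking duration in s (SC/SCI/WC)
    consumption_units: float = 0.0
    percent_time_consuming: float = 0.0
    pushing_success_pct: float | None = None
    explore_anticipatory_s: float | None = None
    explore_reward_s: float | None = None
    #: pair-level latency (s from time 0) to finish all 10 pellets, per trial
    latency_all_pellets: tuple[float | None, ...] | None = None


def pushing_success_pct(events: Iterable[EventRecord]) -> float | None:
    """Percent of pushing bouts that displaced the partner.

    The base is the bout *count*, not pushing duration: efficiency is about
    how often a thrust works, not how long it lasts. Returns ``None`` when
    there are no pushing bouts (an undefined, not a zero, efficiency).
    """
    total = 0
    successful = 0
    for ev in events:
        if ev.behavior is not Behavior.PUSHING:
            continue
        total += 1
        if ev.outcome is PushOutcome.SUCCESSFUL:
            successful += 1
    if total == 0:
        return None
    return 100.0 * successful / total


def latency_all_pellets(
    events: Sequence[EventRecord], window: AnalysisWindow
) -> float | None:
    """Seconds from time 0 until the pair finishes all 10 pellets of a trial.

    Walks consumption bouts (either animal) inside the window in stop-time
    order, accumulating pellet counts; the latency is the stop time of the
    bout at which the pair-wise cumulative count first reaches 10, relative
    to the trial's time 0. Returns ``None`` if fewer than 10 pellets were
    eaten in the window; raises if the cumulative count exceeds 10.
    """
    bouts = [
        ev
        for ev in clip_events(events, window)
        if ev.behavior is Behavior.CONSUMPTION and ev.pellets
    ]
    bouts.sort(key=lambda ev: ev.t_stop)
    cumulative = 0
    for ev in bouts:
        cumulative += ev.pellets or 0
        if cumulative > PELLETS_PER_TRIAL:
            raise ValueError(
                f"trial {window.trial_index}: cumulative pellet count "
                f"{cumulative} exceeds the {PELLETS_PER_TRIAL} delivered"
            )
        if cumulative == PELLETS_PER_TRIAL:
            return ev.t_stop - window.time0
    return None


def split_exploration_by_phase(
    events: Sequence[EventRecord], windows: Sequence[AnalysisWindow]
) -> tuple[float, float]:
    """Feeder exploration split at time 0: (anticipatory s, reward s).

    Anticipatory exploration — sniffing the feeder while the reward is
    present but inaccessible — is summed over ``[t_lo, time0)`` of every
    window; reward-phase exploration over ``[time0, t_hi)``. The two parts
    sum exactly to the total windowed exploration time.
    """
    anticipatory = 0.0
    reward = 0.0
    for ev in events:
        if ev.behavior is not Behavior.EXPLORE_FEEDER:
            continue
        for w in windows:
            anticipatory += overlap(ev.t_start, ev.t_stop, *w.anticipatory)
            reward += overlap(ev.t_start, ev.t_stop, *w.reward)
    return anticipatory, reward


def _windowed(events, windows) -> list[EventRecord]:
    out: list[EventRecord] = []
    for w in windows:
        out.extend(clip_events(events, w))
    return out


def _summarize_animal(
    animal: Animal,
    events: Sequence[EventRecord],
    spec: SessionSpec,
    windows: Sequence[AnalysisWindow],
    pair_id: str,
    day: int,
    pair_latencies: tuple[float | None, ...] | None,
) -> BehaviorSummary:
    own = [ev for ev in events if ev.animal_id is animal]
    windowed = _windowed(own, windows)

    total_duration: dict[Behavior, float] = {b: 0.0 for b in Behavior}
    bout_count: dict[Behavior, int] = {b: 0 for b in Behavior}
    latency_first: dict[Behavior, float | None] = {b: None for b in Behavior}
    for ev in windowed:
        total_duration[ev.behavior] += ev.duration
        bout_count[ev.behavior] += 1
        first = latency_first[ev.behavior]
        if first is None or ev.t_start < first:
            latency_first[ev.behavior] = ev.t_start

    consumption_bouts = [
        ev for ev in windowed if ev.behavior is Behavior.CONSUMPTION
    ]
    if spec.has_trials:
        # the resource only exists during the reward phase
        consumption_s = sum(
            overlap(ev.t_start, ev.t_stop, *w.reward)
            for ev in consumption_bouts
            for w in windows
        )
    else:
        consumption_s = sum(ev.duration for ev in consumption_bouts)

    if spec.test_code in PELLET_TESTS:
        units = float(sum(ev.pellets or 0 for ev in consumption_bouts))
    else:
        units = consumption_s

    percent = 100.0 * consumption_s / spec.consumption_denominator

    if spec.has_trials:
        anticipatory, reward = split_exploration_by_phase(own, windows)
    else:
        anticipatory = reward = None

    return BehaviorSummary(
        pair_id=pair_id,
        animal_id=animal,
        test_code=spec.test_code,
        day=day,
        total_duration=total_duration,
        bout_count=bout_count,
        latency_to_first=latency_first,
        consumption_units=units,
        percent_time_consuming=percent,
        pushing_success_pct=pushing_success_pct(windowed),
        explore_anticipatory_s=anticipatory,
        explore_reward_s=reward,
        latency_all_pellets=pair_latencies,
    )


def summarize_session(
    events: Sequence[EventRecord],
    spec: SessionSpec,
    windows: Sequence[AnalysisWindow] | None = None,
) -> tuple[BehaviorSummary, BehaviorSummary]:
    """Summaries for both animals of one (pair, test, day) session.

    ``windows`` defaults to the nominal schedule of ``spec``; pass windows
    built from observed time-0 values when the schedule jittered.
    """
    events = list(events)
    if not events:
        raise ValueError("no events to summarize")
    pair_ids = {ev.pair_id for ev in events}
    tests = {ev.test_code for ev in events}
    days = {ev.day for ev in events}
    if len(pair_ids) > 1 or len(tests) > 1 or len(days) > 1:
        raise ValueError(
            "summarize_session expects events from a single (pair, test, day); "
            f"got pairs={pair_ids}, tests={tests}, days={days}"
        )
    (test,) = tests
    if test is not spec.test_code:
        raise ValueError(
            f"events are {test.value} but spec is {spec.test_code.value}"
        )
    if windows is None:
        from dyadrank.sessions import build_windows

        windows = build_windows(spec)

    if spec.test_code in PELLET_TESTS:
        pair_latencies = tuple(latency_all_pellets(events, w) for w in windows)
    else:
        pair_latencies = None

    pair_id = next(iter(pair_ids))
    day = next(iter(days))
    return tuple(
        _summarize_animal(a, events, spec, windows, pair_id, day, pair_latencies)
        for a in (Animal.A, Animal.B)
    )


def summaries_to_frame(summaries: Iterable[BehaviorSummary]) -> pd.DataFrame:
    """Tidy table: one row per pair × animal × test × day."""
    rows = []
    for s in summaries:
        row = {
            "pair_id": s.pair_id,
            "animal_id": s.animal_id.value,
            "test_code": s.test_code.value,
            "day": s.day,
            "consumption_units": s.consumption_units,
            "percent_time_consuming": s.percent_time_consuming,
            "pushing_success_pct": s.pushing_success_pct,
            "explore_anticipatory_s": s.explore_anticipatory_s,
            "explore_reward_s": s.explore_reward_s,
            "mean_latency_all_pellets": (
                None
                if s.latency_all_pellets is None
                or all(v is None for v in s.latency_all_pellets)
                else float(
                    pd.Series(
                        [v for v in s.latency_all_pellets if v is not None]
                    ).mean()
                )
            ),
        }
        for b in Behavior:
            row[f"{b.value}_s"] = s.total_duration.get(b, 0.0)
            row[f"{b.value}_bouts"] = s.bout_count.get(b, 0)
            row[f"{b.value}_latency_first"] = s.latency_to_first.get(b)
        rows.append(row)
    return pd.DataFrame(rows)
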