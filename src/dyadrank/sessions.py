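"""Session schedules and trial-aligned analysis windows.

Trial-structured tests (mFC, mFCD, SCI) cycle a 1-min inter-trial interval
with 2 min of reward access, five times, for a 15-min session. Because the
door/bottle was operated manually, the realized "time 0" of each trial
(the moment access opens) can jitter around the nominal schedule; analysis
windows may therefore be anchored on observed time-0 values. Each window
spans the last 40 s of the inter-trial interval and the first 80 s of
access — the ``anticipatory`` and ``reward`` phases.

Continuous tests (SC, WC) have no trial structure: the "window" is the
whole 10-min session and phase labels are undefined.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from dyadrank.ethogram_io import EventRecord, TestCode, TRIAL_TESTS

__all__ = [
    "AnalysisWindow",
    "SessionSpec",
    "build_windows",
    "clip_events",
    "default_session_spec",
    "load_session_config",
]

#: Nominal door-opening times for the 5-trial tests: 1-min ITI then 2-min
#: access, repeating (60, 240, ..., 780 s).
NOMINAL_TRIAL_ZEROS = (60.0, 240.0, 420.0, 600.0, 780.0)


@dataclass(frozen=True)
class SessionSpec:
    """Schedule of one test session: trials, durations, window widths."""

    test_code: TestCode
    n_trials: int
    trial_zero_times: tuple[float, ...]
    access_duration: float  # seconds of reward access per trial
    session_duration: float
    pre_window: float = 40.0
    post_window: float = 80.0

    def __post_init__(self) -> None:
        zeros = self.trial_zero_times
        if len(zeros) != self.n_trials:
            raise ValueError(
                f"{self.n_trials} trials but {len(zeros)} trial_zero_times"
            )
        for a, b in zip(zeros, zeros[1:]):
            if not (b > a):
                raise ValueError("trial_zero_times must be strictly increasing")
            if a + self.access_duration > b:
                raise ValueError(
                    f"access period starting at {a} overruns next trial at {b}"
                )
        if self.pre_window < 0 or self.post_window < 0:
            raise ValueError("window widths must be non-negative")

    @property
    def has_trials(self) -> bool:
        return self.test_code in TRIAL_TESTS

    @property
    def consumption_denominator(self) -> float:
        """Effective observation time for percent-consumption.

        80 s of access × 5 trials = 400 s for trial tests; the whole
        600-s session otherwise.
        """
        if self.has_trials:
            return self.post_window * self.n_trials
        return self.session_duration


@dataclass(frozen=True)
class AnalysisWindow:
    """One trial's quantification window ``[t_lo, t_hi)`` around time 0."""

    trial_index: int
    t_lo: float
    time0: float
    t_hi: float

    def __post_init__(self) -> None:
        if not (self.t_lo <= self.time0 <= self.t_hi):
            raise ValueError("window must bracket time0")

    @property
    def measure(self) -> float:
        return self.t_hi - self.t_lo

    @property
    def anticipatory(self) -> tuple[float, float]:
        """Phase before access opens: ``[t_lo, time0)``."""
        return (self.t_lo, self.time0)

    @property
    def reward(self) -> tuple[float, float]:
        """Phase with access to the resource: ``[time0, t_hi)``."""
        return (self.time0, self.t_hi)


def default_session_spec(test_code: TestCode | str) -> SessionSpec:
    """The canonical schedule for each test.

    mFC / mFCD / SCI: 5 trials, time 0 at 60/240/420/600/780 s, 120 s of
    access per trial, 900-s session. SC / WC: one continuous 600-s block.
    """
    code = TestCode(test_code)
    if code in TRIAL_TESTS:
        return SessionSpec(
            test_code=code,
            n_trials=5,
            trial_zero_times=NOMINAL_TRIAL_ZEROS,
            access_duration=120.0,
            session_duration=900.0,
        )
    return SessionSpec(
        test_code=code,
        n_trials=1,
        trial_zero_times=(0.0,),
        access_duration=600.0,
        session_duration=600.0,
    )


def build_windows(
    spec: SessionSpec,
    observed_zero_times: Sequence[float] | None = None,
) -> list[AnalysisWindow]:
    """Analysis windows for every trial of a session.

    When ``observed_zero_times`` is given (manual door control jitters the
    schedule), windows anchor on those instead of the nominal times. For
    continuous tests the single window is the whole session, with time 0
    at its start.

    Raises ``ValueError`` if any two windows would overlap.
    """
    if not spec.has_trials:
        if observed_zero_times is not None:
            raise ValueError(f"{spec.test_code.value} has no trial structure")
        return [
            AnalysisWindow(
                trial_index=1, t_lo=0.0, time0=0.0, t_hi=spec.session_duration
            )
        ]

    zeros = spec.trial_zero_times
    if observed_zero_times is not None:
        if len(observed_zero_times) != spec.n_trials:
            raise ValueError(
                f"expected {spec.n_trials} observed time-0 values, "
                f"got {len(observed_zero_times)}"
            )
        zeros = tuple(float(z) for z in observed_zero_times)

    windows = [
        AnalysisWindow(
            trial_index=i,
            t_lo=t0 - spec.pre_window,
            time0=t0,
            t_hi=t0 + spec.post_window,
        )
        for i, t0 in enumerate(zeros, start=1)
    ]
    for a, b in zip(windows, windows[1:]):
        if b.t_lo < a.t_hi:
            raise ValueError(
                f"windows for trials {a.trial_index} and {b.trial_index} overlap"
            )
    return windows


def overlap(a_lo: float, a_hi: float, b_lo: float, b_hi: float) -> float:
    """Measure of the intersection of two half-open intervals."""
    return max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))


def clip_events(
    events: Sequence[EventRecord], window: AnalysisWindow
) -> list[EventRecord]:
    """Intersect each bout with ``[t_lo, t_hi)``; drop bouts fully outside.

    Clipping (rather than dropping) boundary-spanning bouts preserves
    duration mass: the clipped durations sum to the exact interval overlap
    with the window.
    """
    clipped: list[EventRecord] = []
    for ev in events:
        lo = max(ev.t_start, window.t_lo)
        hi = min(ev.t_stop, window.t_hi)
        if hi <= lo:
            continue
        if lo == ev.t_start and hi == ev.t_stop:
            clipped.append(ev)
        else:
            clipped.append(dataclasses.replace(ev, t_start=lo, t_stop=hi))
    return clipped


def load_session_config(path: str | Path) -> dict[TestCode, SessionSpec]:
    """Per-test schedule overrides from a TOML file.

    Top-level tables are test codes; keys override SessionSpec fields, e.g.::

        [mFC]
        n_trials = 3
        trial_zero_times = [60.0, 240.0, 420.0]
        pre_window = 30.0
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    specs: dict[TestCode, SessionSpec] = {}
    for code_str, overrides in raw.items():
        code = TestCode(code_str)
        base = default_session_spec(code)
        fields = {f.name for f in dataclasses.fields(SessionSpec)}
        unknown = set(overrides) - fields
        if unknown:
            raise ValueError(f"unknown SessionSpec keys for {code_str}: {unknown}")
        if "trial_zero_times" in overrides:
            overrides = dict(overrides)
            overrides["trial_zero_times"] = tuple(
                float(x) for x in overrides["trial_zero_times"]
            )
        specs[code] = dataclasses.replace(base, **overrides)
    return specs
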