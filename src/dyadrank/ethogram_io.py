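"""Reading, validation and writing of ethogram event logs and trial tables.

Three tables drive the pipeline:

* an **events CSV** — one row per annotated behavioral bout
  (``pair_id,test_code,day,trial,animal_id,behavior,outcome,t_start_s,
  t_stop_s,pellets``),
* a **tube-trial CSV** — one row per tube-test trial
  (``pair_id,day,trial,winner,latency_s,completed``), and
* a **weights CSV** — one row per animal (``pair_id,animal_id,body_weight_g``).

All time intervals are half-open ``[t_start, t_stop)`` in seconds from
session start, so abutting bouts do not overlap and durations are exactly
``t_stop - t_start``. Zero-length bouts are rejected rather than ignored:
they are annotation errors and should surface early.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Animal",
    "Behavior",
    "CompletenessIssue",
    "EventRecord",
    "PushOutcome",
    "SchemaError",
    "TestCode",
    "TubeTrialRecord",
    "ValidationError",
    "WeightRecord",
    "read_events",
    "read_tube_trials",
    "read_weights",
    "validate_session_completeness",
    "write_events",
    "write_tube_trials",
    "write_weights",
]


class TestCode(str, enum.Enum):
    """Competition test identifiers.

    mFC — modified food competition (trial structure, 10 pellets/trial);
    SC — sucrose competition, continuous bottle access;
    SCI — sucrose competition, intermittent access (trial structure);
    mFCD — modified food competition under food deprivation;
    WC — water competition under water deprivation.
    """

    MFC = "mFC"
    SC = "SC"
    SCI = "SCI"
    MFCD = "mFCD"
    WC = "WC"


#: Tests with a 5-trial schedule (door / bottle cycles); SC and WC are one
#: continuous access block.
TRIAL_TESTS = frozenset({TestCode.MFC, TestCode.MFCD, TestCode.SCI})

#: Tests whose consumption is counted in pellets (events carry a pellet count).
PELLET_TESTS = frozenset({TestCode.MFC, TestCode.MFCD})


class Animal(str, enum.Enum):
    A = "A"
    B = "B"

    @property
    def partner(self) -> "Animal":
        return Animal.B if self is Animal.A else Animal.A


class Behavior(str, enum.Enum):
    CONSUMPTION = "consumption"
    PUSHING = "pushing"
    EXPLORE_FEEDER = "explore_feeder"
    GROOMING = "grooming"


class PushOutcome(str, enum.Enum):
    """Whether a pushing bout displaced the partner from the resource."""

    SUCCESSFUL = "successful"
    UNSUCCESSFUL = "unsuccessful"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a record-level contract; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class EventRecord:
    """One annotated behavioral bout within a session.

    ``outcome`` is present iff ``behavior`` is pushing (the successful /
    unsuccessful split is a manual annotation, not inferred); ``pellets``
    may only accompany consumption bouts of the pellet-based tests.
    """

    pair_id: str
    test_code: TestCode
    day: int
    animal_id: Animal
    behavior: Behavior
    t_start: float
    t_stop: float
    outcome: PushOutcome | None = None
    pellets: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        if not (self.t_start >= 0):
            raise ValidationError(f"t_start must be >= 0, got {self.t_start}")
        if not (self.t_stop > self.t_start):
            raise ValidationError(
                f"zero- or negative-length bout: [{self.t_start}, {self.t_stop})"
            )
        if (self.behavior is Behavior.PUSHING) != (self.outcome is not None):
            if self.outcome is None:
                raise ValidationError(
                    "pushing bout lacks an outcome label "
                    "(successful/unsuccessful)"
                )
            raise ValidationError(
                f"outcome given for non-pushing behavior {self.behavior.value!r}"
            )
        if self.pellets is not None:
            if self.behavior is not Behavior.CONSUMPTION:
                raise ValidationError(
                    f"pellets given for non-consumption behavior "
                    f"{self.behavior.value!r}"
                )
            if self.pellets < 0:
                raise ValidationError(f"negative pellet count {self.pellets}")

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start


class Winner(str, enum.Enum):
    A = "A"
    B = "B"
    NONE = "none"


@dataclass(frozen=True)
class TubeTrialRecord:
    """One tube-test trial: who retreated first, and how fast.

    Incomplete ("resistant") trials — where the presumed loser refuses to
    enter the tube — carry ``completed=False``, no winner and no latency.
    """

    pair_id: str
    day: int
    trial: int
    winner: Winner
    latency: float | None
    completed: bool

    def __post_init__(self) -> None:
        if not (1 <= self.trial <= 10):
            raise ValidationError(f"trial must be in 1..10, got {self.trial}")
        if self.completed:
            if self.winner is Winner.NONE:
                raise ValidationError("completed trial must name a winner")
            if self.latency is None or not (self.latency > 0):
                raise ValidationError(
                    f"completed trial needs latency > 0, got {self.latency}"
                )
        else:
            if self.winner is not Winner.NONE:
                raise ValidationError(
                    "incomplete (resistant) trial cannot have a winner"
                )
            if self.latency is not None:
                raise ValidationError("incomplete trial cannot have a latency")


@dataclass(frozen=True)
class WeightRecord:
    pair_id: str
    animal_id: Animal
    body_weight: float  # grams

    def __post_init__(self) -> None:
        if not (self.body_weight > 0):
            raise ValidationError(
                f"body_weight must be > 0 g, got {self.body_weight}"
            )


# ---------------------------------------------------------------------------
# readers

EVENT_COLUMNS = (
    "pair_id",
    "test_code",
    "day",
    "trial",
    "animal_id",
    "behavior",
    "outcome",
    "t_start_s",
    "t_stop_s",
    "pellets",
)
_EVENT_REQUIRED = (
    "pair_id",
    "test_code",
    "day",
    "animal_id",
    "behavior",
    "t_start_s",
    "t_stop_s",
)

TUBE_COLUMNS = ("pair_id", "day", "trial", "winner", "latency_s", "completed")
WEIGHT_COLUMNS = ("pair_id", "animal_id", "body_weight_g")


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _apply_schema(
    frame: pd.DataFrame,
    schema: Mapping[str, str] | None,
    required: Sequence[str],
) -> pd.DataFrame:
    if schema:
        rename = {src: canonical for canonical, src in schema.items()}
        frame = frame.rename(columns=rename)
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")
    return frame


def _parse_enum(cls, raw, what: str, row: int):
    try:
        return cls(str(raw))
    except ValueError:
        accepted = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown {what} {raw!r}; accepted: {accepted}", row=row
        ) from None


def read_events(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[EventRecord]:
    """Read an events CSV into validated :class:`EventRecord` rows.

    Parameters
    ----------
    path:
        CSV file with a header row; comma-separated, UTF-8.
    schema:
        Optional mapping from canonical column names (``pair_id`` ...
        ``pellets``) to the names used in the file, for annotation-tool
        exports with different headers.

    Returns
    -------
    Records sorted by (pair, test, day, animal, t_start). Any invalid row
    raises :class:`ValidationError` with its 0-based row index; no row is
    ever silently dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = _apply_schema(frame, schema, _EVENT_REQUIRED)
    records: list[EventRecord] = []
    for idx, row in enumerate(frame.to_dict("records")):
        try:
            t_start = float(row["t_start_s"])
            t_stop = float(row["t_stop_s"])
        except ValueError as exc:
            raise ValidationError(f"unparseable time: {exc}", row=idx) from None
        outcome_raw = row.get("outcome")
        pellets_raw = row.get("pellets")
        trial_raw = row.get("trial")
        try:
            record = EventRecord(
                pair_id=str(row["pair_id"]),
                test_code=_parse_enum(TestCode, row["test_code"], "test code", idx),
                day=int(row["day"]),
                animal_id=_parse_enum(Animal, row["animal_id"], "animal id", idx),
                behavior=_parse_enum(Behavior, row["behavior"], "behavior", idx),
                outcome=None
                if _is_missing(outcome_raw)
                else _parse_enum(PushOutcome, outcome_raw, "outcome", idx),
                t_start=t_start,
                t_stop=t_stop,
                pellets=None if _is_missing(pellets_raw) else int(pellets_raw),
                trial=None if _is_missing(trial_raw) else int(trial_raw),
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc), row=idx) from None
            raise
        records.append(record)
    records.sort(
        key=lambda r: (r.pair_id, r.test_code.value, r.day, r.animal_id.value, r.t_start)
    )
    return records


def read_tube_trials(path: str | Path) -> list[TubeTrialRecord]:
    """Read a tube-trial CSV; incomplete trials must have ``winner=none``."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = _apply_schema(frame, None, TUBE_COLUMNS[:4] + ("completed",))
    records: list[TubeTrialRecord] = []
    for idx, row in enumerate(frame.to_dict("records")):
        completed_raw = str(row["completed"]).strip().lower()
        if completed_raw not in {"true", "false", "1", "0"}:
            raise ValidationError(
                f"completed must be boolean, got {row['completed']!r}", row=idx
            )
        completed = completed_raw in {"true", "1"}
        latency_raw = row.get("latency_s")
        try:
            record = TubeTrialRecord(
                pair_id=str(row["pair_id"]),
                day=int(row["day"]),
                trial=int(row["trial"]),
                winner=_parse_enum(Winner, row["winner"], "winner", idx),
                latency=None if _is_missing(latency_raw) else float(latency_raw),
                completed=completed,
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc), row=idx) from None
            raise
        records.append(record)
    records.sort(key=lambda r: (r.pair_id, r.day, r.trial))
    return records


def read_weights(path: str | Path) -> list[WeightRecord]:
    """Read a body-weight CSV; exactly one row per (pair, animal)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = _apply_schema(frame, None, WEIGHT_COLUMNS)
    records: list[WeightRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(frame.to_dict("records")):
        key = (str(row["pair_id"]), str(row["animal_id"]))
        if key in seen:
            raise ValidationError(f"duplicate weight for {key}", row=idx)
        seen.add(key)
        try:
            records.append(
                WeightRecord(
                    pair_id=str(row["pair_id"]),
                    animal_id=_parse_enum(Animal, row["animal_id"], "animal id", idx),
                    body_weight=float(row["body_weight_g"]),
                )
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc), row=idx) from None
            raise
    return records


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_events(records: Iterable[EventRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "pair_id": r.pair_id,
                "test_code": r.test_code.value,
                "day": r.day,
                "trial": "" if r.trial is None else r.trial,
                "animal_id": r.animal_id.value,
                "behavior": r.behavior.value,
                "outcome": "" if r.outcome is None else r.outcome.value,
                "t_start_s": repr(float(r.t_start)),
                "t_stop_s": repr(float(r.t_stop)),
                "pellets": "" if r.pellets is None else r.pellets,
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_tube_trials(records: Iterable[TubeTrialRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "pair_id": r.pair_id,
                "day": r.day,
                "trial": r.trial,
                "winner": r.winner.value,
                "latency_s": "" if r.latency is None else repr(float(r.latency)),
                "completed": str(r.completed).lower(),
            }
        )
    pd.DataFrame(rows, columns=TUBE_COLUMNS).to_csv(path, index=False)


def write_weights(records: Iterable[WeightRecord], path: str | Path) -> None:
    rows = [
        {
            "pair_id": r.pair_id,
            "animal_id": r.animal_id.value,
            "body_weight_g": repr(float(r.body_weight)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session-level consistency report


@dataclass(frozen=True)
class CompletenessIssue:
    kind: str  # beyond_session | overlap | pellet_excess
    message: str
    events: tuple[int, ...] = ()  # indices into the checked event list


def validate_session_completeness(events, spec) -> list[CompletenessIssue]:
    """Report-only consistency checks for one (pair, test, day) session.

    Flags bouts extending past the session duration, overlapping bouts of
    the same animal and behavior, and pellet-test trials whose summed
    pellet count exceeds the 10 pellets delivered per trial. Returns an
    empty list for a clean log.
    """
    issues: list[CompletenessIssue] = []
    events = list(events)

    for i, ev in enumerate(events):
        if ev.t_stop > spec.session_duration:
            issues.append(
                CompletenessIssue(
                    kind="beyond_session",
                    message=(
                        f"bout [{ev.t_start}, {ev.t_stop}) extends beyond "
                        f"session duration {spec.session_duration} s"
                    ),
                    events=(i,),
                )
            )

    by_track: dict[tuple[Animal, Behavior], list[int]] = {}
    for i, ev in enumerate(events):
        by_track.setdefault((ev.animal_id, ev.behavior), []).append(i)
    for (animal, behavior), idxs in by_track.items():
        idxs = sorted(idxs, key=lambda i: events[i].t_start)
        for a, b in zip(idxs, idxs[1:]):
            if events[b].t_start < events[a].t_stop:  # half-open: < not <=
                issues.append(
                    CompletenessIssue(
                        kind="overlap",
                        message=(
                            f"animal {animal.value} has overlapping "
                            f"{behavior.value} bouts"
                        ),
                        events=(a, b),
                    )
                )

    if spec.test_code in PELLET_TESTS:
        per_trial: dict[int, int] = {}
        members: dict[int, list[int]] = {}
        for i, ev in enumerate(events):
            if ev.behavior is not Behavior.CONSUMPTION or ev.pellets is None:
                continue
            trial = ev.trial if ev.trial is not None else _nominal_trial(ev, spec)
            per_trial[trial] = per_trial.get(trial, 0) + ev.pellets
            members.setdefault(trial, []).append(i)
        for trial, total in sorted(per_trial.items()):
            if total > 10:
                issues.append(
                    CompletenessIssue(
                        kind="pellet_excess",
                        message=(
                            f"trial {trial}: {total} pellets consumed, "
                            "but only 10 are delivered per trial"
                        ),
                        events=tuple(members[trial]),
                    )
                )
    return issues


def _nominal_trial(event, spec) -> int:
    """Assign a bout to the trial whose access window contains its start."""
    for i, t0 in enumerate(spec.trial_zero_times, start=1):
        if t0 <= event.t_start < t0 + spec.access_duration:
            return i
    # fall back on nearest preceding trial (bout in an ITI)
    preceding = [i for i, t0 in enumerate(spec.trial_zero_times, start=1)
                 if t0 <= event.t_start]
    return preceding[-1] if preceding else 1


def events_to_frame(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of an event list (one row per bout)."""
    return pd.DataFrame(
        [
            {
                **dataclasses.asdict(r),
                "test_code": r.test_code.value,
                "animal_id": r.animal_id.value,
                "behavior": r.behavior.value,
                "outcome": None if r.outcome is None else r.outcome.value,
                "duration": r.duration,
            }
            for r in records
        ]
    )
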