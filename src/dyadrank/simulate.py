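"""Synthetic dyad cohorts with known ground truth.

Each simulated pair carries a latent dominance strength ``delta`` in
[-1, 1] (positive: animal A dominant) that is shared across tests — the
"stable trait" the cross-test reliability analysis looks for. An ablation
with independent per-test deltas provides the matching null.

What the generator emulates, per test:

* **mFC / mFCD** — each trial's 10 pellets split Binomial(10, 0.5 + k·delta);
  the pair finishes the pellets with a lognormal latency (median ~20 s,
  faster on day 2 and under deprivation); Poisson pushing bouts whose
  per-bout success is a logistic function of the pusher's dominance;
  subordinates groom more; dominants show more anticipatory feeder
  exploration.
* **SC / SCI** — drinking-time share of the dominant grows with delta;
  bouts alternate between animals; SCI places drinking inside the 5 reward
  phases.
* **WC** — long alternating drinking bouts with near-equal totals (the
  dominance index stays near 0), while the subordinate pushes more and
  longer but the dominant's pushes almost always succeed.
* **Tube test** — day-1 win odds are a logistic function of delta *and* of
  the within-pair body-weight difference; winners streak (the winner of a
  trial wins the next with probability >= 0.9); latencies settle around
  3.5 s after trial 1, longer for contested pairs; strongly ranked pairs
  show ~9% resistant (incomplete) trials on day 2.

All effect sizes live in :class:`CohortConfig`. They are calibrated
defaults chosen to reproduce the qualitative patterns above — not
estimates of any real cohort's generative parameters. Bout-duration
distributions (lognormal / exponential) are stand-ins; real bout-duration
statistics are not published.

Randomness: every pair gets its own stream derived from
``SeedSequence(seed, spawn_key=(pair_index,))``, so enlarging a cohort
never perturbs existing pairs, and identical seeds give byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dyadrank.ethogram_io import (
    Animal,
    Behavior,
    EventRecord,
    PushOutcome,
    TestCode,
    TubeTrialRecord,
    WeightRecord,
    Winner,
    write_events,
    write_tube_trials,
    write_weights,
)
from dyadrank.sessions import default_session_spec

__all__ = [
    "Cohort",
    "CohortConfig",
    "DyadParams",
    "simulate_cohort",
    "simulate_mfc_session",
    "simulate_sc_session",
    "simulate_sci_session",
    "simulate_tube_sessions",
    "simulate_wc_session",
]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class CohortConfig:
    """One block of generator effect sizes (calibrated defaults).

    Rates are per trial for trial-structured tests and per session for
    continuous ones; durations and latencies in seconds; gains are
    log-odds per unit of their covariate.
    """

    n_pairs: int = 20

    # food competition
    pellet_split_gain: float = 0.2  # p(dominant pellet) = 0.5 + gain*delta
    mfc_latency_median: float = 20.0  # pair latency to finish 10 pellets
    mfc_latency_sigma: float = 0.25
    day2_latency_factor: float = 0.8
    deprived_latency_factor: float = 0.6
    mfc_push_rate: float = 3.0  # bouts / trial / animal

    # sucrose competition
    sc_total_drink_mean: float = 100.0
    sc_total_drink_sd: float = 15.0
    sci_total_drink_mean: float = 80.0
    sci_total_drink_sd: float = 12.0
    drink_share_gain: float = 0.2  # dominant share = 0.5 + gain*delta
    drink_share_noise: float = 0.05
    sc_push_rate: float = 3.0  # per session
    sci_push_rate: float = 1.5  # per trial

    # water competition: near-equal totals, asymmetric pushing efficiency
    wc_total_drink_mean: float = 400.0
    wc_total_drink_sd: float = 30.0
    wc_share_gain: float = 0.015
    wc_share_noise: float = 0.02
    wc_push_rate: float = 20.0  # per session; subordinate pushes more:
    wc_push_asymmetry: float = 1.2  # rate × (1 + asym·|delta|) for subordinate
    wc_push_success_gain: float = 5.0
    wc_sub_push_bout_mean: float = 2.5
    wc_drink_bout_mean: float = 20.0

    # pushing (shared)
    push_bout_mean: float = 1.5
    push_success_gain: float = 3.0

    # grooming / exploration
    groom_bout_mean: float = 3.0  # per trial (or ×5 per continuous session)
    groom_asymmetry: float = 1.0  # scale × (1 + asym·|delta|) for subordinate
    explore_anticipatory_mean: float = 8.0
    explore_reward_mean: float = 5.0
    explore_dominant_gain: float = 0.5

    # tube test
    tube_delta_gain: float = 5.0
    tube_weight_gain: float = 0.25  # per percent of within-pair weight diff
    tube_persistence: float = 0.9
    tube_latency_trial1_median: float = 8.0
    tube_latency_median: float = 3.5
    tube_latency_sigma: float = 0.4
    tube_contested_latency_gain: float = 2.5
    tube_resistant_rate: float = 0.09  # day-2 trials of strongly ranked pairs
    tube_resistant_min_delta: float = 0.5

    # cohort assembly
    weight_mean: float = 450.0
    weight_sd: float = 25.0
    weight_diff_pct_max: float = 8.0  # within-pair difference stays <10%


DEFAULT_CONFIG = CohortConfig()


@dataclass(frozen=True)
class DyadParams:
    """Latent generative parameters of one simulated pair."""

    pair_id: str
    delta: float  # dominance strength in [-1, 1]; positive: A dominant
    weight_a: float  # grams
    weight_b: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must be in [-1, 1], got {self.delta}")
        if self.weight_a <= 0 or self.weight_b <= 0:
            raise ValueError("weights must be positive")

    @property
    def dominant(self) -> Animal:
        return Animal.A if self.delta >= 0 else Animal.B

    @property
    def weight_diff_pct(self) -> float:
        """(A - B) weight difference as % of the pair mean."""
        mean = 0.5 * (self.weight_a + self.weight_b)
        return 100.0 * (self.weight_a - self.weight_b) / mean


def default_dyad(delta: float = 0.6, seed: int = 0) -> DyadParams:
    """A typical established pair: clear but not extreme hierarchy."""
    return DyadParams(
        pair_id="pair01", delta=delta, weight_a=455.0, weight_b=445.0, seed=seed
    )


def _rng_for(params: DyadParams, rng: np.random.Generator | None):
    return rng if rng is not None else np.random.default_rng(params.seed)


def _signed(delta: float, animal: Animal) -> float:
    return delta if animal is Animal.A else -delta


def _place_bouts(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    dur_mean: float,
    dur_min: float = 0.3,
    dur_max: float | None = None,
) -> list[tuple[float, float]]:
    """n non-overlapping [start, stop) bouts in [lo, hi); crowded draws
    are truncated against the next bout, over-crowded ones dropped."""
    if n <= 0 or hi - lo <= dur_min:
        return []
    starts = np.sort(rng.uniform(lo, hi - dur_min, size=n))
    durations = np.clip(
        rng.exponential(dur_mean, size=n), dur_min, dur_max or 6.0 * dur_mean
    )
    bouts: list[tuple[float, float]] = []
    for i, (start, dur) in enumerate(zip(starts, durations)):
        stop = min(start + dur, hi)
        if i + 1 < n:
            stop = min(stop, starts[i + 1] - 0.05)
        if stop - start >= 0.1:
            bouts.append((float(start), float(stop)))
    return bouts


def _push_events(
    rng, params, cfg, test, day, lo, hi, n_by_animal, bout_mean_by_animal,
    success_gain,
) -> list[EventRecord]:
    events = []
    for animal in Animal:
        p_success = _sigmoid(success_gain * _signed(params.delta, animal))
        for start, stop in _place_bouts(
            rng, n_by_animal[animal], lo, hi, bout_mean_by_animal[animal]
        ):
            outcome = (
                PushOutcome.SUCCESSFUL
                if rng.random() < p_success
                else PushOutcome.UNSUCCESSFUL
            )
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.PUSHING,
                    t_start=start, t_stop=stop, outcome=outcome,
                )
            )
    return events


def _groom_explore_trial(
    rng, params, cfg, test, day, t0, trial
) -> list[EventRecord]:
    """Grooming + phase-structured exploration around one trial's time 0."""
    events = []
    for animal in Animal:
        is_sub = animal is not params.dominant
        groom_scale = cfg.groom_bout_mean * (
            1.0 + cfg.groom_asymmetry * abs(params.delta) * is_sub
        )
        dur = min(rng.exponential(groom_scale), 30.0)
        if dur >= 0.3:
            start = rng.uniform(t0 - 40.0, t0 - dur) if dur < 40 else t0 - 40.0
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.GROOMING,
                    t_start=start, t_stop=start + dur, trial=trial,
                )
            )
        ant_scale = cfg.explore_anticipatory_mean * (
            1.0 + cfg.explore_dominant_gain * abs(params.delta) * (not is_sub)
        )
        ant = min(rng.exponential(ant_scale), 35.0)
        if ant >= 0.3:
            start = rng.uniform(t0 - 40.0, t0 - ant) if ant < 40 else t0 - 40.0
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.EXPLORE_FEEDER,
                    t_start=start, t_stop=start + ant, trial=trial,
                )
            )
        rew = min(rng.exponential(cfg.explore_reward_mean), 25.0)
        if rew >= 0.3:
            start = rng.uniform(t0 + 40.0, t0 + 80.0 - rew)
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.EXPLORE_FEEDER,
                    t_start=start, t_stop=start + rew, trial=trial,
                )
            )
    return events


def simulate_mfc_session(
    params: DyadParams,
    day: int = 1,
    deprived: bool = False,
    rng: np.random.Generator | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
) -> list[EventRecord]:
    """One modified-food-competition session (5 trials, 10 pellets each).

    ``deprived=True`` yields the mFCD variant: same structure, faster
    pellet consumption.
    """
    rng = _rng_for(params, rng)
    cfg = config
    test = TestCode.MFCD if deprived else TestCode.MFC
    spec = default_session_spec(test)
    p_a = float(np.clip(0.5 + cfg.pellet_split_gain * params.delta, 0.02, 0.98))

    latency_median = cfg.mfc_latency_median
    if day >= 2:
        latency_median *= cfg.day2_latency_factor
    if deprived:
        latency_median *= cfg.deprived_latency_factor

    events: list[EventRecord] = []
    for trial, t0 in enumerate(spec.trial_zero_times, start=1):
        pellets_a = int(rng.binomial(10, p_a))
        pellets_b = 10 - pellets_a
        latency = float(
            np.clip(
                rng.lognormal(math.log(latency_median), cfg.mfc_latency_sigma),
                4.0,
                75.0,
            )
        )
        # dominant-first consumption, split proportional to pellets
        eat_lo = t0 + 0.5
        eat_len = latency - 0.5
        first, second = (
            (Animal.A, Animal.B) if pellets_a >= pellets_b else (Animal.B, Animal.A)
        )
        counts = {Animal.A: pellets_a, Animal.B: pellets_b}
        boundary = eat_lo + eat_len * counts[first] / 10.0
        segments = [
            (first, eat_lo, boundary),
            (second, boundary, t0 + latency),
        ]
        for animal, lo, hi in segments:
            if counts[animal] == 0 or hi - lo < 1e-6:
                continue
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.CONSUMPTION,
                    t_start=lo, t_stop=hi, pellets=counts[animal], trial=trial,
                )
            )
        events.extend(
            _push_events(
                rng, params, cfg, test, day,
                lo=t0, hi=t0 + 75.0,
                n_by_animal={a: int(rng.poisson(cfg.mfc_push_rate)) for a in Animal},
                bout_mean_by_animal={a: cfg.push_bout_mean for a in Animal},
                success_gain=cfg.push_success_gain,
            )
        )
        events.extend(_groom_explore_trial(rng, params, cfg, test, day, t0, trial))
    events.sort(key=lambda e: (e.animal_id.value, e.t_start))
    return events


def _alternating_drinking(
    rng, params, cfg, test, day, totals, n_bouts, lo, hi
) -> list[EventRecord]:
    """Alternating drinking bouts filling [lo, hi), dominant first."""
    order: list[Animal] = []
    remaining = dict(n_bouts)
    current = params.dominant
    while sum(remaining.values()) > 0:
        if remaining[current] > 0:
            order.append(current)
            remaining[current] -= 1
        elif remaining[current.partner] > 0:
            current = current.partner
            continue
        current = current.partner
    durations = {
        a: rng.dirichlet(np.full(n_bouts[a], 5.0)) * totals[a]
        if n_bouts[a]
        else np.array([])
        for a in Animal
    }
    total_drink = sum(totals[a] for a in Animal if n_bouts[a])
    span = hi - lo
    scale = min(1.0, (span * 0.9) / total_drink) if total_drink > 0 else 1.0
    total_gap = span - total_drink * scale
    gaps = rng.dirichlet(np.full(len(order) + 1, 2.0)) * total_gap

    events = []
    cursor = lo
    used = {a: 0 for a in Animal}
    for i, animal in enumerate(order):
        cursor += gaps[i]
        dur = float(durations[animal][used[animal]]) * scale
        used[animal] += 1
        if dur < 0.2:
            cursor += dur
            continue
        events.append(
            EventRecord(
                pair_id=params.pair_id, test_code=test, day=day,
                animal_id=animal, behavior=Behavior.CONSUMPTION,
                t_start=cursor, t_stop=cursor + dur,
            )
        )
        cursor += dur
    return events


def _continuous_groom_explore(rng, params, cfg, test, day, hi) -> list[EventRecord]:
    events = []
    for animal in Animal:
        is_sub = animal is not params.dominant
        groom_scale = cfg.groom_bout_mean * (
            1.0 + cfg.groom_asymmetry * abs(params.delta) * is_sub
        )
        for start, stop in _place_bouts(
            rng, int(rng.poisson(4.0)), 2.0, hi - 2.0, groom_scale
        ):
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.GROOMING,
                    t_start=start, t_stop=stop,
                )
            )
        for start, stop in _place_bouts(
            rng, int(rng.poisson(5.0)), 2.0, hi - 2.0, cfg.explore_reward_mean
        ):
            events.append(
                EventRecord(
                    pair_id=params.pair_id, test_code=test, day=day,
                    animal_id=animal, behavior=Behavior.EXPLORE_FEEDER,
                    t_start=start, t_stop=stop,
                )
            )
    return events


def simulate_sc_session(
    params: DyadParams,
    day: int = 1,
    rng: np.random.Generator | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
) -> list[EventRecord]:
    """Sucrose competition with continuous bottle access (600 s)."""
    rng = _rng_for(params, rng)
    cfg = config
    test = TestCode.SC
    total = float(
        np.clip(rng.normal(cfg.sc_total_drink_mean, cfg.sc_total_drink_sd), 20, 400)
    )
    share_a = float(
        np.clip(
            0.5
            + cfg.drink_share_gain * params.delta
            + rng.normal(0, cfg.drink_share_noise),
            0.02,
            0.98,
        )
    )
    totals = {Animal.A: total * share_a, Animal.B: total * (1 - share_a)}
    n_bouts = {
        a: max(1, int(round(totals[a] / 12.0))) for a in Animal
    }
    events = _alternating_drinking(
        rng, params, cfg, test, day, totals, n_bouts, 5.0, 595.0
    )
    events.extend(
        _push_events(
            rng, params, cfg, test, day, lo=5.0, hi=595.0,
            n_by_animal={a: int(rng.poisson(cfg.sc_push_rate)) for a in Animal},
            bout_mean_by_animal={a: cfg.push_bout_mean for a in Animal},
            success_gain=cfg.push_success_gain,
        )
    )
    events.extend(_continuous_groom_explore(rng, params, cfg, test, day, 600.0))
    events.sort(key=lambda e: (e.animal_id.value, e.t_start))
    return events


def simulate_sci_session(
    params: DyadParams,
    day: int = 1,
    rng: np.random.Generator | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
) -> list[EventRecord]:
    """Sucrose competition with intermittent access (5 × 2-min trials)."""
    rng = _rng_for(params, rng)
    cfg = config
    test = TestCode.SCI
    spec = default_session_spec(test)
    total = float(
        np.clip(
            rng.normal(cfg.sci_total_drink_mean, cfg.sci_total_drink_sd), 15, 300
        )
    )
    share_a = float(
        np.clip(
            0.5
            + cfg.drink_share_gain * params.delta
            + rng.normal(0, cfg.drink_share_noise),
            0.02,
            0.98,
        )
    )
    trial_weights = rng.dirichlet(np.full(spec.n_trials, 8.0))
    events: list[EventRecord] = []
    for trial, (t0, w) in enumerate(
        zip(spec.trial_zero_times, trial_weights), start=1
    ):
        trial_total = min(total * w, 74.0)
        totals = {
            Animal.A: trial_total * share_a,
            Animal.B: trial_total * (1 - share_a),
        }
        events.extend(
            _alternating_drinking(
                rng, params, cfg, test, day, totals,
                {a: 1 for a in Animal}, t0 + 1.0, t0 + 78.0,
            )
        )
        events.extend(
            _push_events(
                rng, params, cfg, test, day, lo=t0, hi=t0 + 75.0,
                n_by_animal={a: int(rng.poisson(cfg.sci_push_rate)) for a in Animal},
                bout_mean_by_animal={a: cfg.push_bout_mean for a in Animal},
                success_gain=cfg.push_success_gain,
            )
        )
        events.extend(_groom_explore_trial(rng, params, cfg, test, day, t0, trial))
    events.sort(key=lambda e: (e.animal_id.value, e.t_start))
    return events


def simulate_wc_session(
    params: DyadParams,
    day: int = 1,
    rng: np.random.Generator | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
) -> list[EventRecord]:
    """Water competition under deprivation (600 s, no trial structure).

    Totals are near-equal (|DI| mostly inside the noise band); the
    subordinate emits more and longer pushing bouts but the dominant's
    pushes almost always displace the partner.
    """
    rng = _rng_for(params, rng)
    cfg = config
    test = TestCode.WC
    total = float(
        np.clip(rng.normal(cfg.wc_total_drink_mean, cfg.wc_total_drink_sd), 150, 560)
    )
    share_a = float(
        np.clip(
            0.5
            + cfg.wc_share_gain * params.delta
            + rng.normal(0, cfg.wc_share_noise),
            0.05,
            0.95,
        )
    )
    totals = {Animal.A: total * share_a, Animal.B: total * (1 - share_a)}
    n_bouts = {
        a: max(2, int(round(totals[a] / cfg.wc_drink_bout_mean))) for a in Animal
    }
    events = _alternating_drinking(
        rng, params, cfg, test, day, totals, n_bouts, 5.0, 595.0
    )
    push_n = {}
    push_mean = {}
    for animal in Animal:
        is_sub = animal is not params.dominant
        rate = cfg.wc_push_rate * (
            1.0 + cfg.wc_push_asymmetry * abs(params.delta) * is_sub
        )
        push_n[animal] = int(rng.poisson(rate))
        push_mean[animal] = (
            cfg.wc_sub_push_bout_mean if is_sub else cfg.push_bout_mean
        )
    events.extend(
        _push_events(
            rng, params, cfg, test, day, lo=5.0, hi=595.0,
            n_by_animal=push_n, bout_mean_by_animal=push_mean,
            success_gain=cfg.wc_push_success_gain,
        )
    )
    events.extend(_continuous_groom_explore(rng, params, cfg, test, day, 600.0))
    events.sort(key=lambda e: (e.animal_id.value, e.t_start))
    return events


def simulate_tube_sessions(
    params: DyadParams,
    rng: np.random.Generator | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
) -> list[TubeTrialRecord]:
    """Two 10-trial tube-test sessions.

    Day-1 win odds depend on dominance and on the within-pair weight
    difference; winners streak; resolution latencies drop to ~3.5 s after
    trial 1 and are longer when the pair is contested. Strongly ranked
    pairs refuse ~9% of day-2 trials (resistant trials).
    """
    rng = _rng_for(params, rng)
    cfg = config
    p_a = _sigmoid(
        cfg.tube_delta_gain * params.delta
        + cfg.tube_weight_gain * params.weight_diff_pct
    )
    decisiveness = abs(2.0 * p_a - 1.0)
    latency_scale = 1.0 + cfg.tube_contested_latency_gain * (1.0 - decisiveness)

    trials: list[TubeTrialRecord] = []
    for day in (1, 2):
        previous: Winner | None = None
        for trial in range(1, 11):
            resistant = (
                day == 2
                and abs(params.delta) >= cfg.tube_resistant_min_delta
                and rng.random() < cfg.tube_resistant_rate
            )
            if resistant:
                trials.append(
                    TubeTrialRecord(
                        pair_id=params.pair_id, day=day, trial=trial,
                        winner=Winner.NONE, latency=None, completed=False,
                    )
                )
                continue
            if previous is not None and rng.random() < cfg.tube_persistence:
                winner = previous
            else:
                winner = Winner.A if rng.random() < p_a else Winner.B
            median = (
                cfg.tube_latency_trial1_median
                if (trial == 1 and day == 1)
                else cfg.tube_latency_median
            ) * latency_scale
            latency = float(
                np.clip(
                    rng.lognormal(math.log(median), cfg.tube_latency_sigma),
                    0.5,
                    120.0,
                )
            )
            trials.append(
                TubeTrialRecord(
                    pair_id=params.pair_id, day=day, trial=trial,
                    winner=winner, latency=latency, completed=True,
                )
            )
            previous = winner
    return trials


# ---------------------------------------------------------------------------
# cohort assembly

#: session plan: (test, days, simulator kwargs)
_REWARD_TESTS = (TestCode.MFC, TestCode.SC, TestCode.SCI, TestCode.MFCD)


@dataclass(frozen=True)
class Cohort:
    """A full simulated dataset plus its generative ground truth."""

    events: tuple[EventRecord, ...]
    tube_trials: tuple[TubeTrialRecord, ...]
    weights: tuple[WeightRecord, ...]
    ground_truth: pd.DataFrame
    params: tuple[DyadParams, ...]
    config: CohortConfig
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": out / "events.csv",
            "tube_trials": out / "tube_trials.csv",
            "weights": out / "weights.csv",
            "ground_truth": out / "ground_truth.csv",
        }
        write_events(self.events, paths["events"])
        write_tube_trials(self.tube_trials, paths["tube_trials"])
        write_weights(self.weights, paths["weights"])
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def _pair_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


def simulate_cohort(
    n_pairs: int | None = None,
    config: CohortConfig = DEFAULT_CONFIG,
    seed: int = 0,
    shared_delta: bool = True,
    tests: Sequence[TestCode] | None = None,
) -> Cohort:
    """Simulate a cohort of dyads across all competition tests.

    ``shared_delta=True`` (default) draws one latent dominance strength
    per pair, shared by every test — hierarchy as a stable trait.
    ``shared_delta=False`` is the null ablation: an independent delta per
    test, so cross-test DI correlations should vanish.

    ``tests`` restricts the simulated event-log tests (the tube test is
    always included); by default all five are generated with the study's
    schedule: two days of mFC, SC and SCI, one day of mFCD and WC, two
    10-trial tube sessions.
    """
    cfg = config
    if n_pairs is None:
        n_pairs = cfg.n_pairs
    if tests is None:
        tests = (TestCode.MFC, TestCode.SC, TestCode.SCI, TestCode.MFCD, TestCode.WC)
    tests = tuple(TestCode(t) for t in tests)

    all_events: list[EventRecord] = []
    all_tube: list[TubeTrialRecord] = []
    all_weights: list[WeightRecord] = []
    all_params: list[DyadParams] = []
    truth_rows = []

    for index in range(n_pairs):
        rng = _pair_rng(seed, index)
        pair_id = f"pair{index + 1:02d}"
        delta = float(rng.uniform(-1.0, 1.0))
        base_weight = float(rng.normal(cfg.weight_mean, cfg.weight_sd))
        diff_pct = float(rng.uniform(-cfg.weight_diff_pct_max, cfg.weight_diff_pct_max))
        weight_a = base_weight * (1.0 + diff_pct / 200.0)
        weight_b = base_weight * (1.0 - diff_pct / 200.0)
        params = DyadParams(
            pair_id=pair_id, delta=delta,
            weight_a=weight_a, weight_b=weight_b, seed=seed,
        )
        all_params.append(params)
        all_weights.append(WeightRecord(pair_id, Animal.A, weight_a))
        all_weights.append(WeightRecord(pair_id, Animal.B, weight_b))

        per_test_delta: dict[TestCode, float] = {}
        plan: list[tuple[TestCode, int]] = []
        for test in tests:
            days = 1 if test in (TestCode.MFCD, TestCode.WC) else 2
            plan.extend((test, day) for day in range(1, days + 1))
        for test in tests + ("tube",):
            key = test if isinstance(test, TestCode) else test
            per_test_delta[key] = (
                delta if shared_delta else float(rng.uniform(-1.0, 1.0))
            )

        for test, day in plan:
            p = replace(params, delta=per_test_delta[test])
            if test is TestCode.MFC:
                all_events.extend(
                    simulate_mfc_session(p, day=day, rng=rng, config=cfg)
                )
            elif test is TestCode.MFCD:
                all_events.extend(
                    simulate_mfc_session(
                        p, day=day, deprived=True, rng=rng, config=cfg
                    )
                )
            elif test is TestCode.SC:
                all_events.extend(
                    simulate_sc_session(p, day=day, rng=rng, config=cfg)
                )
            elif test is TestCode.SCI:
                all_events.extend(
                    simulate_sci_session(p, day=day, rng=rng, config=cfg)
                )
            elif test is TestCode.WC:
                all_events.extend(
                    simulate_wc_session(p, day=day, rng=rng, config=cfg)
                )
        all_tube.extend(
            simulate_tube_sessions(
                replace(params, delta=per_test_delta["tube"]), rng=rng, config=cfg
            )
        )

        row = {
            "pair_id": pair_id,
            "delta": delta,
            "weight_a": weight_a,
            "weight_b": weight_b,
            "expected_pellet_share_a": 0.5 + cfg.pellet_split_gain * delta,
        }
        for test in tests:
            row[f"delta_{test.value}"] = per_test_delta[test]
        row["delta_tube"] = per_test_delta["tube"]
        truth_rows.append(row)

    return Cohort(
        events=tuple(all_events),
        tube_trials=tuple(all_tube),
        weights=tuple(all_weights),
        ground_truth=pd.DataFrame(truth_rows),
        params=tuple(all_params),
        config=cfg,
        seed=seed,
    )
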