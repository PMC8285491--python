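"""Dominance indices, hierarchy classification and cross-test reliability.

The central quantity is the **Dominance Index**

    DI = 100 * (consumption_A - consumption_B) / (consumption_A + consumption_B)

where "consumption" is pellets eaten (food tests), drinking time (bottle
tests) or trials won (tube test). DI is antisymmetric under relabeling the
animals and bounded in [-100, 100]. Differences of less than 5% from equal
consumption — |DI| <= 10 — are treated as noise: no reliable hierarchy.

Two derived indices refine the picture. The **Conflict Resolution Index**
(tube test) divides DI by the mean time it took to resolve a trial, so
fast decisive wins score higher than slow contested ones. The **Conflict
Index** divides the pair's total pushing time by the time spent consuming
(bottle tests) or the latency to finish all pellets (food tests),
measuring how much conflict a test format induces.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from dyadrank.ethogram_io import (
    Animal,
    Behavior,
    EventRecord,
    TubeTrialRecord,
    Winner,
)
from dyadrank.metrics import pushing_success_pct

__all__ = [
    "HierarchyLabel",
    "PeakEpoch",
    "RegressionReport",
    "TubeDominance",
    "classify_hierarchy",
    "conflict_index",
    "conflict_resolution_index",
    "cross_test_reliability",
    "dominance_index",
    "mean_dominance_index",
    "peak_conflict_epoch",
    "tube_dominance",
    "weight_residual_regression",
]

#: Half-width of the DI noise band (a <5% deviation from equal consumption).
NOISE_BAND = 10.0


class HierarchyLabel(str, enum.Enum):
    A_DOMINANT = "A_dominant"
    B_DOMINANT = "B_dominant"
    UNSTABLE = "unstable"


def dominance_index(consumption_a: float, consumption_b: float) -> float:
    """DI in [-100, 100]; positive means animal A consumed more.

    Returns NaN (missing) when neither animal consumed anything — a
    no-consumption session carries no rank information.
    """
    if consumption_a < 0 or consumption_b < 0:
        raise ValueError("consumption must be non-negative")
    total = consumption_a + consumption_b
    if total == 0:
        return math.nan
    di = 100.0 * (consumption_a - consumption_b) / total
    return min(100.0, max(-100.0, di))  # guard 1-ulp rounding past the bound


def classify_hierarchy(di: float, band: float = NOISE_BAND) -> HierarchyLabel:
    """Dominant/submissive call from a DI value.

    The noise band is inclusive: |DI| <= band means no reliable hierarchy.
    A missing (NaN) DI also classifies as unstable.
    """
    if di is None or math.isnan(di):
        return HierarchyLabel.UNSTABLE
    if di > band:
        return HierarchyLabel.A_DOMINANT
    if di < -band:
        return HierarchyLabel.B_DOMINANT
    return HierarchyLabel.UNSTABLE


def mean_dominance_index(per_day_di: Iterable[float]) -> float:
    """Average DI over testing days, ignoring missing days."""
    values = [d for d in per_day_di if not math.isnan(d)]
    return float(np.mean(values)) if values else math.nan


@dataclass(frozen=True)
class TubeDominance:
    """Tube-test DI over completed trials, plus resistant-trial bookkeeping."""

    wins_a: int
    wins_b: int
    resistant_count: int
    di: float  # NaN if no completed trials
    mean_latency: float  # over completed trials; NaN if none

    @property
    def label(self) -> HierarchyLabel:
        return classify_hierarchy(self.di)


def tube_dominance(trials: Sequence[TubeTrialRecord]) -> TubeDominance:
    """DI over tube-test wins; incomplete ("resistant") trials are excluded
    from both numerator and denominator but counted separately."""
    wins_a = sum(1 for t in trials if t.completed and t.winner is Winner.A)
    wins_b = sum(1 for t in trials if t.completed and t.winner is Winner.B)
    resistant = sum(1 for t in trials if not t.completed)
    latencies = [t.latency for t in trials if t.completed and t.latency is not None]
    return TubeDominance(
        wins_a=wins_a,
        wins_b=wins_b,
        resistant_count=resistant,
        di=dominance_index(wins_a, wins_b),
        mean_latency=float(np.mean(latencies)) if latencies else math.nan,
    )


def conflict_resolution_index(di: float, mean_trial_latency: float) -> float:
    """CRI = DI / mean time to resolve a trial (% per second).

    Preserves DI's sign; missing when DI is missing or no completed trial
    provides a latency.
    """
    if math.isnan(di) or math.isnan(mean_trial_latency):
        return math.nan
    if not (mean_trial_latency > 0):
        raise ValueError(
            f"mean trial latency must be > 0 s, got {mean_trial_latency}"
        )
    return di / mean_trial_latency


def conflict_index(
    pushing_pair_total_s: float, denominator_s: float
) -> float:
    """CI: pair pushing time per unit of consumption opportunity.

    The denominator is the pair's consumption time for the bottle tests
    (SC/SCI/WC) or the mean latency to eat all pellets for the food tests
    (mFC/mFCD). Missing (NaN) when the denominator is zero or missing.
    """
    if pushing_pair_total_s < 0:
        raise ValueError("pushing time must be non-negative")
    if math.isnan(denominator_s) or denominator_s <= 0:
        return math.nan
    return pushing_pair_total_s / denominator_s


# ---------------------------------------------------------------------------
# peak-conflict epoch (water competition)


@dataclass(frozen=True)
class PeakEpoch:
    """Highest-conflict window of a continuous session and its summaries."""

    t_lo: float
    t_hi: float
    score: float  # summed pair drinking + pushing duration within
    drinking_s: dict[Animal, float]
    pushing_s: dict[Animal, float]
    pushing_success_pct: dict[Animal, float | None]
    di: float  # DI over within-epoch drinking durations

    @property
    def label(self) -> HierarchyLabel:
        return classify_hierarchy(self.di)


def peak_conflict_epoch(
    events: Sequence[EventRecord],
    epoch_len: float = 120.0,
    step: float = 1.0,
    session_duration: float | None = None,
) -> PeakEpoch:
    """Locate the epoch with the most combined drinking and pushing.

    Slides a window of ``epoch_len`` seconds in ``step``-second increments
    across the session and picks the window maximizing the summed pair
    drinking + pushing duration; ties break to the earliest window. Used
    for the water competition, where whole-session consumption is
    uninformative (both animals drink similar totals) but rank shows up in
    who successfully displaces whom during bursts of conflict.
    """
    events = list(events)
    if session_duration is None:
        session_duration = max((ev.t_stop for ev in events), default=0.0)
    if session_duration < epoch_len:
        raise ValueError(
            f"session ({session_duration} s) shorter than epoch ({epoch_len} s)"
        )

    conflict = [
        ev
        for ev in events
        if ev.behavior in (Behavior.CONSUMPTION, Behavior.PUSHING)
    ]
    starts = np.arange(0.0, session_duration - epoch_len + step / 2, step)
    if conflict:
        lo = np.array([ev.t_start for ev in conflict])
        hi = np.array([ev.t_stop for ev in conflict])
        # overlap of every bout with every candidate window
        ov = np.maximum(
            0.0,
            np.minimum(hi[:, None], starts[None, :] + epoch_len)
            - np.maximum(lo[:, None], starts[None, :]),
        )
        scores = ov.sum(axis=0)
    else:
        scores = np.zeros_like(starts)
    best = int(np.argmax(scores))  # argmax returns the first maximum: earliest
    t_lo = float(starts[best])
    t_hi = t_lo + epoch_len

    drinking: dict[Animal, float] = {}
    pushing: dict[Animal, float] = {}
    success: dict[Animal, float | None] = {}
    for animal in Animal:
        own = [ev for ev in events if ev.animal_id is animal]
        drinking[animal] = sum(
            max(0.0, min(ev.t_stop, t_hi) - max(ev.t_start, t_lo))
            for ev in own
            if ev.behavior is Behavior.CONSUMPTION
        )
        pushing[animal] = sum(
            max(0.0, min(ev.t_stop, t_hi) - max(ev.t_start, t_lo))
            for ev in own
            if ev.behavior is Behavior.PUSHING
        )
        # a bout belongs to the epoch if it overlaps it
        in_epoch = [
            ev
            for ev in own
            if ev.behavior is Behavior.PUSHING
            and ev.t_start < t_hi
            and ev.t_stop > t_lo
        ]
        success[animal] = pushing_success_pct(in_epoch)

    return PeakEpoch(
        t_lo=t_lo,
        t_hi=t_hi,
        score=float(scores[best]),
        drinking_s=drinking,
        pushing_s=pushing,
        pushing_success_pct=success,
        di=dominance_index(drinking[Animal.A], drinking[Animal.B]),
    )


@dataclass(frozen=True)
class DominanceResult:
    """Per-pair, per-test dominance scoring (assembled by the pipeline)."""

    pair_id: str
    test_code: str
    days_used: tuple[int, ...]
    consumption_a: float
    consumption_b: float
    di_per_day: tuple[float, ...]
    di: float  # day-averaged
    label: HierarchyLabel
    label_reason: str | None = None  # e.g. "missing_di"
    ci: float = math.nan
    cri: float = math.nan  # tube test only
    resistant_count: int | None = None  # tube test only
    peak_epoch: tuple[float, float] | None = None  # WC only


# ---------------------------------------------------------------------------
# cross-test reliability


def cross_test_reliability(
    di_table: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of DI between tests, over pairs.

    ``di_table`` has one row per pair and one column per test (NaN where a
    pair lacks a DI for a test). Returns (r, p, n) DataFrames; cells with
    fewer than ``min_pairs`` overlapping pairs are NaN. If hierarchy is a
    stable trait, DIs from different tests should correlate.
    """
    tests = list(di_table.columns)
    r = pd.DataFrame(np.nan, index=tests, columns=tests, dtype=float)
    p = pd.DataFrame(np.nan, index=tests, columns=tests, dtype=float)
    n = pd.DataFrame(0, index=tests, columns=tests, dtype=int)
    for i, ti in enumerate(tests):
        for tj in tests[i:]:
            both = di_table[[ti, tj]].dropna()
            n.loc[ti, tj] = n.loc[tj, ti] = len(both)
            if ti == tj:
                if len(both) >= min_pairs:
                    r.loc[ti, tj] = 1.0
                    p.loc[ti, tj] = 0.0
                continue
            if len(both) < min_pairs:
                continue
            x = both[ti].to_numpy()
            y = both[tj].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # degenerate: correlation undefined
            res = scipy.stats.pearsonr(x, y)
            r.loc[ti, tj] = r.loc[tj, ti] = float(res.statistic)
            p.loc[ti, tj] = p.loc[tj, ti] = float(res.pvalue)
    return r, p, n


# ---------------------------------------------------------------------------
# weight-controlled regression (food-competition rank vs tube outcome)


@dataclass(frozen=True)
class RegressionReport:
    """Residual-on-residual regression of tube CRI on food-test consumption.

    ``slope``/``p_value`` describe the fit of weight-residualized day-1
    tube CRI on the within-pair difference of weight-residualized pellet
    counts. A positive, significant slope means food-competition rank
    predicts early tube-test outcome once body weight is controlled for.
    """

    slope: float
    intercept: float
    stderr: float
    p_value: float
    r_squared: float
    n_pairs: int
    pellet_residuals: pd.DataFrame  # animal-level: pair_id, animal_id, residual
    cri_residuals: pd.DataFrame  # pair-level: pair_id, residual


def _ols(y: np.ndarray, x: np.ndarray):
    if np.std(x) == 0:
        raise ValueError("degenerate (constant) regressor")
    return sm.OLS(y, sm.add_constant(x)).fit()


def weight_residual_regression(
    pellets: pd.DataFrame,
    weights: pd.DataFrame,
    tube_cri_day1: Mapping[str, float] | pd.Series,
) -> RegressionReport:
    """Does food-competition rank predict tube outcome, controlling weight?

    Body weight affects who wins the first tube-test encounters but not
    who eats more in the home-cage food competition, so both variables are
    residualized on weight before relating them:

    1. pellets eaten ~ own body weight, across all animals → residuals;
    2. day-1 tube CRI ~ within-pair weight difference (A − B, g), across
       pairs → residuals;
    3. CRI residuals ~ within-pair difference of pellet residuals (A − B).

    ``pellets`` needs columns pair_id, animal_id, pellets; ``weights``
    needs pair_id, animal_id, body_weight_g. Pairs with a missing CRI are
    dropped. Both within-pair differences flip sign under A↔B relabeling,
    so the final slope is relabeling-equivariant.
    """
    merged = pellets.merge(weights, on=["pair_id", "animal_id"], how="inner")
    if len(merged) < len(pellets):
        missing = set(zip(pellets.pair_id, pellets.animal_id)) - set(
            zip(merged.pair_id, merged.animal_id)
        )
        raise ValueError(f"missing body weights for {sorted(missing)}")

    fit_pellets = _ols(
        merged["pellets"].to_numpy(float), merged["body_weight_g"].to_numpy(float)
    )
    pellet_resid = merged[["pair_id", "animal_id"]].copy()
    pellet_resid["residual"] = fit_pellets.resid

    wide_resid = pellet_resid.pivot(
        index="pair_id", columns="animal_id", values="residual"
    )
    wide_weight = merged.pivot(
        index="pair_id", columns="animal_id", values="body_weight_g"
    )
    pair_frame = pd.DataFrame(
        {
            "pellet_resid_diff": wide_resid["A"] - wide_resid["B"],
            "weight_diff": wide_weight["A"] - wide_weight["B"],
        }
    )
    cri = pd.Series(dict(tube_cri_day1), dtype=float)
    pair_frame = pair_frame.join(cri.rename("cri"), how="inner").dropna()
    if len(pair_frame) < 3:
        raise ValueError(
            f"need >= 3 pairs with CRI and weights, got {len(pair_frame)}"
        )

    fit_cri = _ols(
        pair_frame["cri"].to_numpy(), pair_frame["weight_diff"].to_numpy()
    )
    cri_resid = pd.DataFrame(
        {"pair_id": pair_frame.index, "residual": fit_cri.resid}
    ).reset_index(drop=True)

    fit_final = _ols(fit_cri.resid, pair_frame["pellet_resid_diff"].to_numpy())
    return RegressionReport(
        slope=float(fit_final.params[1]),
        intercept=float(fit_final.params[0]),
        stderr=float(fit_final.bse[1]),
        p_value=float(fit_final.pvalues[1]),
        r_squared=float(fit_final.rsquared),
        n_pairs=int(len(pair_frame)),
        pellet_residuals=pellet_resid,
        cri_residuals=cri_resid,
    )
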