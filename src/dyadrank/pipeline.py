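"""End-to-end orchestration: events in, report bundle out.

``run_analysis`` validates the inputs, windows and summarizes every
session, scores each pair on every test (DI, label, conflict index, tube
CRI, WC peak-conflict epoch), computes cross-test reliability, the
weight-controlled regression and the dominant-vs-submissive comparisons,
and writes everything to an output directory together with a manifest
that is sufficient to reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import dyadrank
from dyadrank import stats
from dyadrank.dominance import (
    DominanceResult,
    HierarchyLabel,
    classify_hierarchy,
    conflict_index,
    conflict_resolution_index,
    cross_test_reliability,
    dominance_index,
    mean_dominance_index,
    peak_conflict_epoch,
    tube_dominance,
    weight_residual_regression,
)
from dyadrank.ethogram_io import (
    Animal,
    Behavior,
    EventRecord,
    PELLET_TESTS,
    TestCode,
    TubeTrialRecord,
    WeightRecord,
    validate_session_completeness,
)
from dyadrank.metrics import BehaviorSummary, summaries_to_frame, summarize_session
from dyadrank.sessions import build_windows, default_session_spec

__all__ = ["AnalysisBundle", "RunConfig", "run_analysis", "score_sessions"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one analysis run (all defaults follow the study design)."""

    noise_band: float = 10.0
    epoch_len: float = 120.0
    epoch_step: float = 1.0
    day_aggregation: str = "mean"  # DI averaged over testing days
    seed: int = 0
    #: Bonferroni family: the set of dominant-vs-submissive behavior
    #: comparisons within one test is corrected together.
    bonferroni_per_test: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisBundle:
    summaries: pd.DataFrame
    dominance: pd.DataFrame
    reliability_r: pd.DataFrame
    reliability_p: pd.DataFrame
    reliability_n: pd.DataFrame
    stats_table: pd.DataFrame
    regression: dict | None
    validation_issues: list[str]
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _csv(name: str, frame: pd.DataFrame, **kw) -> None:
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name], **kw)

        _csv("behavior_summaries", self.summaries, index=False)
        _csv("dominance_results", self.dominance, index=False)
        _csv("reliability_r", self.reliability_r)
        _csv("reliability_p", self.reliability_p)
        _csv("reliability_n", self.reliability_n)
        _csv("stats_table", self.stats_table, index=False)
        if self.regression is not None:
            paths["regression"] = out / "regression_report.json"
            paths["regression"].write_text(
                json.dumps(self.regression, indent=2, default=float)
            )
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2))
        if self.validation_issues:
            paths["validation"] = out / "validation_issues.txt"
            paths["validation"].write_text("\n".join(self.validation_issues) + "\n")
        return paths


def _group_sessions(events):
    groups: dict[tuple[str, TestCode, int], list[EventRecord]] = {}
    for ev in events:
        groups.setdefault((ev.pair_id, ev.test_code, ev.day), []).append(ev)
    return groups


def score_sessions(
    events: list[EventRecord],
    tube_trials: list[TubeTrialRecord],
    config: RunConfig = RunConfig(),
) -> tuple[list[BehaviorSummary], list[DominanceResult], list[str]]:
    """Summarize every session and score every (pair, test).

    Returns the per-animal summaries, the per-pair dominance results
    (including a ``tube`` entry per pair) and a list of validation
    messages from the report-only completeness checks.
    """
    groups = _group_sessions(events)
    issues: list[str] = []
    summaries: list[BehaviorSummary] = []
    by_pair_test: dict[tuple[str, TestCode], dict[int, tuple]] = {}

    for (pair, test, day), session_events in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2])
    ):
        spec = default_session_spec(test)
        for issue in validate_session_completeness(session_events, spec):
            issues.append(f"{pair}/{test.value}/day{day}: {issue.message}")
        windows = build_windows(spec)
        pair_summaries = summarize_session(session_events, spec, windows)
        summaries.extend(pair_summaries)
        by_pair_test.setdefault((pair, test), {})[day] = (
            pair_summaries,
            session_events,
        )

    results: list[DominanceResult] = []
    for (pair, test), by_day in sorted(
        by_pair_test.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        days = tuple(sorted(by_day))
        di_per_day = []
        ci_per_day = []
        cons_a = cons_b = 0.0
        peak = None
        for day in days:
            (sa, sb), session_events = by_day[day]
            di_per_day.append(dominance_index(sa.consumption_units, sb.consumption_units))
            cons_a += sa.consumption_units
            cons_b += sb.consumption_units
            pushing_pair = (
                sa.total_duration[Behavior.PUSHING]
                + sb.total_duration[Behavior.PUSHING]
            )
            if test in PELLET_TESTS:
                lats = [
                    v
                    for v in (sa.latency_all_pellets or ())
                    if v is not None
                ]
                denom = float(np.mean(lats)) if lats else math.nan
            else:
                denom = (
                    sa.total_duration[Behavior.CONSUMPTION]
                    + sb.total_duration[Behavior.CONSUMPTION]
                )
            ci_per_day.append(conflict_index(pushing_pair, denom))
            if test is TestCode.WC:
                epoch = peak_conflict_epoch(
                    session_events,
                    epoch_len=config.epoch_len,
                    step=config.epoch_step,
                    session_duration=default_session_spec(test).session_duration,
                )
                peak = (epoch.t_lo, epoch.t_hi)
        di = mean_dominance_index(di_per_day)
        ci_vals = [c for c in ci_per_day if not math.isnan(c)]
        label = classify_hierarchy(di, band=config.noise_band)
        results.append(
            DominanceResult(
                pair_id=pair,
                test_code=test.value,
                days_used=days,
                consumption_a=cons_a,
                consumption_b=cons_b,
                di_per_day=tuple(di_per_day),
                di=di,
                label=label,
                label_reason="missing_di" if math.isnan(di) else None,
                ci=float(np.mean(ci_vals)) if ci_vals else math.nan,
                peak_epoch=peak,
            )
        )

    # tube test: DI over wins, CRI per day
    tube_by_pair: dict[str, dict[int, list[TubeTrialRecord]]] = {}
    for t in tube_trials:
        tube_by_pair.setdefault(t.pair_id, {}).setdefault(t.day, []).append(t)
    for pair in sorted(tube_by_pair):
        by_day = tube_by_pair[pair]
        days = tuple(sorted(by_day))
        di_per_day = []
        cri_per_day = []
        wins_a = wins_b = resistant = 0
        for day in days:
            td = tube_dominance(by_day[day])
            di_per_day.append(td.di)
            cri_per_day.append(conflict_resolution_index(td.di, td.mean_latency))
            wins_a += td.wins_a
            wins_b += td.wins_b
            resistant += td.resistant_count
        di = mean_dominance_index(di_per_day)
        cri_vals = [c for c in cri_per_day if not math.isnan(c)]
        results.append(
            DominanceResult(
                pair_id=pair,
                test_code="tube",
                days_used=days,
                consumption_a=float(wins_a),
                consumption_b=float(wins_b),
                di_per_day=tuple(di_per_day),
                di=di,
                label=classify_hierarchy(di, band=config.noise_band),
                label_reason="missing_di" if math.isnan(di) else None,
                cri=float(np.mean(cri_vals)) if cri_vals else math.nan,
                resistant_count=resistant,
            )
        )
    return summaries, results, issues


def _dominance_frame(results: list[DominanceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "pair_id": r.pair_id,
                "test_code": r.test_code,
                "days_used": "+".join(str(d) for d in r.days_used),
                "consumption_a": r.consumption_a,
                "consumption_b": r.consumption_b,
                "di_day1": r.di_per_day[0] if len(r.di_per_day) > 0 else math.nan,
                "di_day2": r.di_per_day[1] if len(r.di_per_day) > 1 else math.nan,
                "di": r.di,
                "label": r.label.value,
                "label_reason": r.label_reason,
                "ci": r.ci,
                "cri": r.cri,
                "resistant_count": r.resistant_count,
                "peak_epoch_lo": r.peak_epoch[0] if r.peak_epoch else None,
                "peak_epoch_hi": r.peak_epoch[1] if r.peak_epoch else None,
            }
        )
    return pd.DataFrame(rows)


def _mfc_day2_classification(results: list[DominanceResult]) -> dict[str, HierarchyLabel]:
    """Dominant/submissive per pair from day-2 DI of the food competition.

    Day 2 induces more conflict than day 1, which is what makes the mFC
    a sharp criterion; pairs inside the noise band (<5% difference from
    equal consumption) are unstable and excluded downstream.
    """
    out: dict[str, HierarchyLabel] = {}
    for r in results:
        if r.test_code != TestCode.MFC.value:
            continue
        di_day2 = r.di_per_day[-1] if r.di_per_day else math.nan
        out[r.pair_id] = classify_hierarchy(di_day2)
    return out


_DS_METRICS = (
    ("consumption_units", "consumption"),
    ("pushing_s", "pushing duration"),
    ("pushing_success_pct", "successful pushing pct"),
    ("explore_anticipatory_s", "anticipatory exploration"),
    ("grooming_s", "grooming"),
)


def _dominant_vs_submissive_stats(
    summary_frame: pd.DataFrame,
    classification: dict[str, HierarchyLabel],
    bonferroni_per_test: bool,
) -> pd.DataFrame:
    """Wilcoxon D-vs-S comparisons per behavior and test.

    Animals are labeled by the mFC day-2 criterion; unstable pairs drop
    out. Each test's set of behavior comparisons forms one Bonferroni
    family.
    """
    frames = []
    for test in summary_frame["test_code"].unique():
        sub = summary_frame[summary_frame["test_code"] == test]
        # average metrics over testing days per animal
        per_animal = sub.groupby(["pair_id", "animal_id"], as_index=False).mean(
            numeric_only=True
        )
        results = []
        kept = []
        for column, label in _DS_METRICS:
            if column not in per_animal:
                continue
            diffs = []
            for pair, group in per_animal.groupby("pair_id"):
                call = classification.get(pair)
                if call is None or call is HierarchyLabel.UNSTABLE:
                    continue
                dom_animal = "A" if call is HierarchyLabel.A_DOMINANT else "B"
                try:
                    dom = group.loc[group.animal_id == dom_animal, column].item()
                    sub_v = group.loc[group.animal_id != dom_animal, column].item()
                except ValueError:
                    continue
                if pd.isna(dom) or pd.isna(sub_v):
                    continue
                diffs.append(dom - sub_v)
            if len(diffs) < 3:
                continue
            results.append(stats.wilcoxon_signed_rank(diffs))
            kept.append(label)
        if not results:
            continue
        if bonferroni_per_test:
            results = stats.apply_bonferroni(results)
        frame = stats.results_to_frame(results)
        frame.insert(0, "test_code", test)
        frame.insert(1, "metric", kept)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["test_code", "metric", "test", "statistic", "z_or_t",
                     "p", "p_adj", "n", "correction", "degenerate"]
        )
    return pd.concat(frames, ignore_index=True)


def run_analysis(
    events: list[EventRecord],
    tube_trials: list[TubeTrialRecord],
    weights: list[WeightRecord] | None = None,
    config: RunConfig = RunConfig(),
) -> AnalysisBundle:
    """Full pipeline: summaries, dominance, reliability, regression, stats."""
    if not events:
        raise ValueError("no events to analyze")
    summaries, results, issues = score_sessions(events, tube_trials, config)
    summary_frame = summaries_to_frame(summaries)
    dominance_frame = _dominance_frame(results)

    di_table = dominance_frame.pivot(index="pair_id", columns="test_code", values="di")
    tube_cri = dominance_frame.loc[
        dominance_frame.test_code == "tube", ["pair_id", "cri"]
    ].set_index("pair_id")["cri"]
    if not tube_cri.empty:
        di_table = di_table.join(tube_cri.rename("tube_cri"))
    rel_r, rel_p, rel_n = cross_test_reliability(di_table)

    regression = None
    if weights and TestCode.MFC.value in set(dominance_frame.test_code):
        pellet_rows = summary_frame[
            summary_frame.test_code == TestCode.MFC.value
        ].groupby(["pair_id", "animal_id"], as_index=False)["consumption_units"].mean()
        pellet_rows = pellet_rows.rename(columns={"consumption_units": "pellets"})
        weight_frame = pd.DataFrame(
            [
                {
                    "pair_id": w.pair_id,
                    "animal_id": w.animal_id.value,
                    "body_weight_g": w.body_weight,
                }
                for w in weights
            ]
        )
        tube_day1 = {}
        tube_by_pair: dict[str, list[TubeTrialRecord]] = {}
        for t in tube_trials:
            if t.day == 1:
                tube_by_pair.setdefault(t.pair_id, []).append(t)
        for pair, trials in tube_by_pair.items():
            td = tube_dominance(trials)
            tube_day1[pair] = conflict_resolution_index(td.di, td.mean_latency)
        if len(tube_day1) >= 3:
            report = weight_residual_regression(pellet_rows, weight_frame, tube_day1)
            regression = {
                "slope": report.slope,
                "intercept": report.intercept,
                "stderr": report.stderr,
                "p_value": report.p_value,
                "r_squared": report.r_squared,
                "n_pairs": report.n_pairs,
            }

    classification = _mfc_day2_classification(results)
    stats_table = _dominant_vs_submissive_stats(
        summary_frame, classification, config.bonferroni_per_test
    )

    manifest = {
        "package": "dyadrank",
        "version": dyadrank.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_events": len(events),
        "n_tube_trials": len(tube_trials),
        "n_pairs": int(dominance_frame.pair_id.nunique()),
        "n_validation_issues": len(issues),
    }
    return AnalysisBundle(
        summaries=summary_frame,
        dominance=dominance_frame,
        reliability_r=rel_r,
        reliability_p=rel_p,
        reliability_n=rel_n,
        stats_table=stats_table,
        regression=regression,
        validation_issues=issues,
        manifest=manifest,
    )
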