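"""Dominance indices, classification, peak epochs and the regressions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadrank.dominance import (
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
from dyadrank.ethogram_io import Animal, TubeTrialRecord, Winner


class TestDominanceIndex:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(30, 20, 20.0), (7, 7, 0.0), (50, 0, 100.0), (0, 50, -100.0)],
    )
    def test_known_values(self, a, b, expected):
        assert dominance_index(a, b) == pytest.approx(expected)

    def test_no_consumption_is_missing(self):
        assert math.isnan(dominance_index(0, 0))

    def test_negative_consumption_rejected(self):
        with pytest.raises(ValueError):
            dominance_index(-1, 5)

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        di = dominance_index(a, b)
        assert -100.0 <= di <= 100.0
        assert di == pytest.approx(-dominance_index(b, a))


class TestClassifyHierarchy:
    @pytest.mark.parametrize(
        "di, expected",
        [
            (8.0, HierarchyLabel.UNSTABLE),
            (10.0, HierarchyLabel.UNSTABLE),  # band inclusive at +10
            (-10.0, HierarchyLabel.UNSTABLE),  # ... and at -10
            (10.0001, HierarchyLabel.A_DOMINANT),
            (25.0, HierarchyLabel.A_DOMINANT),
            (-25.0, HierarchyLabel.B_DOMINANT),
            (math.nan, HierarchyLabel.UNSTABLE),
        ],
    )
    def test_noise_band(self, di, expected):
        assert classify_hierarchy(di) is expected

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-100, 100, allow_nan=False))
    def test_relabeling_swaps_dominant_fixes_unstable(self, di):
        direct = classify_hierarchy(di)
        swapped = classify_hierarchy(-di)
        if direct is HierarchyLabel.UNSTABLE:
            assert swapped is HierarchyLabel.UNSTABLE
        else:
            assert {direct, swapped} == {
                HierarchyLabel.A_DOMINANT, HierarchyLabel.B_DOMINANT
            }


def _trial(pair, day, trial, winner, latency=3.5, completed=True):
    return TubeTrialRecord(
        pair_id=pair, day=day, trial=trial,
        winner=Winner(winner) if completed else Winner.NONE,
        latency=latency if completed else None, completed=completed,
    )


class TestTubeDominance:
    def test_clean_sweep_is_plus_100(self):
        trials = [_trial("p1", 1, t, "A") for t in range(1, 11)]
        result = tube_dominance(trials)
        assert result.di == 100.0
        assert result.label is HierarchyLabel.A_DOMINANT

    def test_tie_is_zero_and_unstable(self):
        trials = [
            _trial("p1", 1, t, "A" if t <= 5 else "B") for t in range(1, 11)
        ]
        result = tube_dominance(trials)
        assert result.di == 0.0
        assert result.label is HierarchyLabel.UNSTABLE

    def test_resistant_trials_excluded_but_counted(self):
        trials = [_trial("p1", 2, t, "A") for t in range(1, 10)]
        trials.append(_trial("p1", 2, 10, None, completed=False))
        result = tube_dominance(trials)
        assert result.di == 100.0
        assert result.resistant_count == 1
        assert result.wins_a == 9

    def test_all_resistant_gives_missing_di(self):
        trials = [_trial("p1", 2, t, None, completed=False) for t in (1, 2)]
        assert math.isnan(tube_dominance(trials).di)

    def test_mean_latency_over_completed_only(self):
        trials = [
            _trial("p1", 1, 1, "A", latency=2.0),
            _trial("p1", 1, 2, "A", latency=4.0),
            _trial("p1", 1, 3, None, completed=False),
        ]
        assert tube_dominance(trials).mean_latency == pytest.approx(3.0)


class TestConflictIndices:
    def test_cri_formula(self):
        assert conflict_resolution_index(100.0, 5.0) == pytest.approx(20.0)
        assert conflict_resolution_index(0.0, 7.0) == 0.0
        assert conflict_resolution_index(-50.0, 2.0) == pytest.approx(-25.0)

    def test_cri_equals_direct_recomputation_from_trials(self):
        # aggregate wins and latencies by hand, then divide
        trials = [
            _trial("p1", 1, 1, "A", latency=2.0),
            _trial("p1", 1, 2, "A", latency=6.0),
            _trial("p1", 1, 3, "B", latency=4.0),
        ]
        result = tube_dominance(trials)
        wins_a, wins_b = 2, 1
        oracle_di = 100.0 * (wins_a - wins_b) / (wins_a + wins_b)
        oracle = oracle_di / np.mean([2.0, 6.0, 4.0])
        assert conflict_resolution_index(
            result.di, result.mean_latency
        ) == pytest.approx(oracle)

    def test_cri_missing_propagates(self):
        assert math.isnan(conflict_resolution_index(math.nan, 3.0))
        assert math.isnan(conflict_resolution_index(50.0, math.nan))

    @pytest.mark.parametrize(
        "pushing, denom, expected",
        [(30.0, 60.0, 0.5), (40.0, 20.0, 2.0), (0.0, 55.0, 0.0)],
    )
    def test_ci_formula(self, pushing, denom, expected):
        assert conflict_index(pushing, denom) == pytest.approx(expected)

    def test_ci_zero_denominator_missing(self):
        assert math.isnan(conflict_index(30.0, 0.0))

    def test_day_average_ignores_missing_days(self):
        assert mean_dominance_index([20.0, math.nan]) == pytest.approx(20.0)
        assert math.isnan(mean_dominance_index([math.nan]))


class TestPeakConflictEpoch:
    def test_activity_cluster_is_found(self, ev):
        events = [
            ev(100, 160, "A"), ev(160, 200, "B"),
            ev(120, 130, "B", "pushing", outcome="unsuccessful"),
        ]
        epoch = peak_conflict_epoch(events, session_duration=600.0)
        assert epoch.t_lo <= 100.0 and epoch.t_hi >= 200.0
        assert epoch.score == pytest.approx(110.0)

    def test_uniform_activity_ties_break_earliest(self, ev):
        events = [ev(0, 600, "A")]  # constant coverage: every window ties
        epoch = peak_conflict_epoch(events, session_duration=600.0)
        assert epoch.t_lo == 0.0

    def test_session_shorter_than_epoch_rejected(self, ev):
        with pytest.raises(ValueError, match="shorter"):
            peak_conflict_epoch([ev(0, 50)], session_duration=100.0)

    def test_within_epoch_summaries(self, ev):
        events = [
            ev(100, 150, "A"),
            ev(110, 112, "A", "pushing", outcome="successful"),
            ev(120, 125, "B", "pushing", outcome="unsuccessful"),
        ]
        epoch = peak_conflict_epoch(events, session_duration=600.0)
        assert epoch.pushing_success_pct[Animal.A] == 100.0
        assert epoch.pushing_success_pct[Animal.B] == 0.0
        assert epoch.di == 100.0  # only A drank within the epoch

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan_oracle(self, seed, ev):
        """The vectorized maximizer equals a plain exhaustive python scan."""
        rng = np.random.default_rng(seed)
        events = []
        for _ in range(20):
            start = float(rng.uniform(0, 580))
            stop = start + float(rng.uniform(0.5, 40))
            kind = rng.choice(["consumption", "pushing", "grooming"])
            events.append(
                ev(start, min(stop, 600.0), rng.choice(["A", "B"]), kind,
                   outcome="successful" if kind == "pushing" else None)
            )
        epoch = peak_conflict_epoch(events, session_duration=600.0)

        def score(lo):
            return sum(
                max(0.0, min(e.t_stop, lo + 120.0) - max(e.t_start, lo))
                for e in events
                if e.behavior.value in ("consumption", "pushing")
            )

        best_lo, best = 0.0, -1.0
        for lo in np.arange(0.0, 481.0, 1.0):
            s = score(lo)
            if s > best + 1e-9:
                best_lo, best = lo, s
        assert epoch.t_lo == pytest.approx(best_lo)
        assert epoch.score == pytest.approx(best)

    def test_invariant_to_event_ordering(self, ev):
        rng = np.random.default_rng(11)
        events = [
            ev(float(s), float(s) + 10.0, "A")
            for s in rng.uniform(0, 580, size=10)
        ]
        shuffled = list(events)
        rng.shuffle(shuffled)
        a = peak_conflict_epoch(events, session_duration=600.0)
        b = peak_conflict_epoch(shuffled, session_duration=600.0)
        assert (a.t_lo, a.t_hi, a.score) == (b.t_lo, b.t_hi, b.score)


class TestCrossTestReliability:
    def test_identical_columns_correlate_perfectly(self):
        di = pd.DataFrame(
            {"mFC": [10.0, -20.0, 35.0, 5.0, -40.0]},
            index=[f"p{i}" for i in range(5)],
        )
        di["SC"] = di["mFC"]
        di["SCI"] = -di["mFC"]
        r, p, n = cross_test_reliability(di)
        assert r.loc["mFC", "SC"] == pytest.approx(1.0)
        assert r.loc["mFC", "SCI"] == pytest.approx(-1.0)
        assert (n == 5).all().all()

    def test_insufficient_overlap_is_missing(self):
        di = pd.DataFrame(
            {
                "mFC": [10.0, -20.0, 35.0, np.nan, np.nan],
                "WC": [np.nan, np.nan, 1.0, 2.0, 3.0],
            },
            index=[f"p{i}" for i in range(5)],
        )
        r, p, n = cross_test_reliability(di)
        assert math.isnan(r.loc["mFC", "WC"])
        assert n.loc["mFC", "WC"] == 1

    def test_r_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        y = 0.5 * x + rng.normal(size=5)
        di = pd.DataFrame({"mFC": x, "SC": y}, index=[f"p{i}" for i in range(5)])
        r, _, _ = cross_test_reliability(di)
        oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r.loc["mFC", "SC"] == pytest.approx(oracle)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        di = pd.DataFrame(
            rng.normal(size=(8, 3)), columns=["mFC", "SC", "WC"],
            index=[f"p{i}" for i in range(8)],
        )
        r, _, _ = cross_test_reliability(di)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)


class TestWeightResidualRegression:
    def _tables(self, n_pairs, rng):
        pairs = [f"p{i:02d}" for i in range(n_pairs)]
        rows_p, rows_w = [], []
        for pair in pairs:
            base = float(rng.normal(450, 20))
            for animal, sign in (("A", 1.0), ("B", -1.0)):
                rows_w.append(
                    {"pair_id": pair, "animal_id": animal,
                     "body_weight_g": base + sign * float(rng.uniform(0, 15))}
                )
                rows_p.append(
                    {"pair_id": pair, "animal_id": animal,
                     "pellets": float(rng.uniform(10, 40))}
                )
        return pd.DataFrame(rows_p), pd.DataFrame(rows_w), pairs

    def test_zero_weight_slope_residuals_are_centered_pellets(self):
        rng = np.random.default_rng(0)
        pellets, weights, pairs = self._tables(8, rng)
        # make pellets exactly independent of weight
        pellets["pellets"] = np.tile([30.0, 20.0], 8)
        weights["body_weight_g"] = np.repeat(
            np.linspace(400, 500, 8), 2
        )  # same weight within pair -> weight_diff 0 would be degenerate
        weights.loc[weights.animal_id == "B", "body_weight_g"] += rng.uniform(
            1, 10, 8
        )
        cri = {p: float(rng.normal(0, 5)) for p in pairs}
        report = weight_residual_regression(pellets, weights, cri)
        fitted = np.polyfit(
            weights["body_weight_g"], pellets["pellets"], 1
        )
        manual = pellets["pellets"] - np.polyval(fitted, weights["body_weight_g"])
        assert np.allclose(report.pellet_residuals["residual"], manual)

    def test_matches_manual_three_step_ols_oracle(self):
        """The pipeline fit equals an explicit polyfit/residual recomputation."""
        rng = np.random.default_rng(1)
        pellets, weights, pairs = self._tables(10, rng)
        cri = {p: float(rng.normal(0, 10)) for p in pairs}
        report = weight_residual_regression(pellets, weights, cri)

        # step 1: pellets ~ own weight
        w = weights["body_weight_g"].to_numpy()
        pell = pellets["pellets"].to_numpy()
        presid = pell - np.polyval(np.polyfit(w, pell, 1), w)
        presid_diff = presid[0::2] - presid[1::2]  # rows alternate A, B
        # step 2: CRI ~ within-pair weight difference
        wdiff = w[0::2] - w[1::2]
        cri_arr = np.array([cri[p] for p in pairs])
        cresid = cri_arr - np.polyval(np.polyfit(wdiff, cri_arr, 1), wdiff)
        # step 3: CRI residuals ~ pellet-residual difference
        slope, intercept = np.polyfit(presid_diff, cresid, 1)
        assert report.slope == pytest.approx(slope, rel=1e-9)
        assert report.intercept == pytest.approx(intercept, abs=1e-9)

    def test_strong_linear_relation_detected(self):
        """CRI built from pellet residuals gives a large, significant slope."""
        rng = np.random.default_rng(1)
        pellets, weights, pairs = self._tables(10, rng)
        report0 = weight_residual_regression(
            pellets, weights, {p: float(rng.normal()) for p in pairs}
        )
        resid_diff = (
            report0.pellet_residuals.pivot(
                index="pair_id", columns="animal_id", values="residual"
            )
            .pipe(lambda frame: frame["A"] - frame["B"])
        )
        cri = (2.0 * resid_diff).to_dict()
        report = weight_residual_regression(pellets, weights, cri)
        assert report.slope == pytest.approx(2.0, rel=0.1)
        assert report.p_value < 1e-6

    def test_constant_regressor_rejected(self):
        rng = np.random.default_rng(2)
        pellets, weights, pairs = self._tables(6, rng)
        weights["body_weight_g"] = 450.0
        with pytest.raises(ValueError, match="degenerate"):
            weight_residual_regression(
                pellets, weights, {p: 1.0 for p in pairs}
            )

    def test_missing_weights_named(self):
        rng = np.random.default_rng(3)
        pellets, weights, pairs = self._tables(5, rng)
        with pytest.raises(ValueError, match="missing body weights"):
            weight_residual_regression(
                pellets, weights.iloc[:-1], {p: 1.0 for p in pairs}
            )

    def test_relabeling_equivariance(self):
        """Swapping every pair's A and B leaves the slope unchanged."""
        rng = np.random.default_rng(5)
        pellets, weights, pairs = self._tables(12, rng)
        cri = {p: float(rng.normal(0, 10)) for p in pairs}
        direct = weight_residual_regression(pellets, weights, cri)
        swap = {"A": "B", "B": "A"}
        pellets_s = pellets.assign(animal_id=pellets.animal_id.map(swap))
        weights_s = weights.assign(animal_id=weights.animal_id.map(swap))
        cri_s = {p: -v for p, v in cri.items()}
        swapped = weight_residual_regression(pellets_s, weights_s, cri_s)
        assert swapped.slope == pytest.approx(direct.slope)
        assert swapped.p_value == pytest.approx(direct.p_value)
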