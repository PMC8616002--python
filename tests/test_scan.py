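"""pH grids, transition detection/classification and dataset summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from disphscan import (
    ParameterError,
    ProteinRecord,
    build_ph_grid,
    classify_transition_ph,
    detect_transitions,
    scan_sequence,
    summarize_scan,
)
from disphscan.scan import (
    CONDITIONAL_FOLDING,
    CONDITIONAL_UNFOLDING,
    _debounced_signs,
)

from conftest import profile_from_scores


class TestPhGrid:
    def test_default_full_range_has_29_values(self):
        grid = build_ph_grid(0.0, 14.0, 0.5)
        assert len(grid) == 29
        assert grid.values[0] == 0.0
        assert grid.values[-1] == 14.0

    def test_degenerate_single_ph(self):
        grid = build_ph_grid(7.0, 7.0, 0.5)
        assert grid.values == (7.0,)
        assert grid.is_single_ph

    def test_unit_step(self):
        assert len(build_ph_grid(0.0, 14.0, 1.0)) == 15

    def test_last_value_never_exceeds_max(self):
        grid = build_ph_grid(2.0, 9.3, 0.5)
        assert grid.values[-1] <= 9.3

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ParameterError):
            build_ph_grid(8.0, 6.0, 0.5)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ParameterError):
            build_ph_grid(0.0, 14.0, 0.0)

    def test_bounds_outside_range_rejected(self):
        with pytest.raises(ParameterError):
            build_ph_grid(-1.0, 7.0, 0.5)

    def test_count_matches_bruteforce_enumeration(self):
        """The floor-formula count equals step-by-step enumeration for
        1,000 random (min, max, step) triples."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            lo = float(np.round(rng.uniform(0, 13), 2))
            hi = float(np.round(rng.uniform(lo, 14), 2))
            step = float(np.round(rng.uniform(0.05, 3.0), 2))
            if hi == lo:
                continue
            grid = build_ph_grid(lo, hi, step)
            count, k = 0, 0
            while lo + k * step <= hi + 1e-9:
                count += 1
                k += 1
            assert len(grid) == count


class TestScanSequence:
    def test_inert_sequence_is_ph_flat(self, full_grid, scale, pkas, boundary):
        rec = ProteinRecord("polyG", "G" * 50)
        profile = scan_sequence(rec, full_grid, 51, scale, pkas, boundary)
        scores = profile.scores()
        assert np.ptp(scores) == pytest.approx(0.0, abs=1e-12)

    def test_polylysine_ncpr_decays_from_one(self, full_grid, scale, pkas,
                                             boundary):
        rec = ProteinRecord("polyK", "K" * 50)
        profile = scan_sequence(rec, full_grid, 51, scale, pkas, boundary)
        ncpr = np.array([p.ncpr for p in profile.points])
        assert ncpr[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(ncpr) < 0)
        assert ncpr[-1] == pytest.approx(0.0, abs=1e-3)

    def test_single_ph_grid_yields_one_point(self, scale, pkas, boundary):
        rec = ProteinRecord("x", "MKV")
        grid = build_ph_grid(7.0, 7.0, 0.5)
        profile = scan_sequence(rec, grid, 51, scale, pkas, boundary)
        assert len(profile.points) == 1
        assert profile.points[0].ph == 7.0


class TestDetectTransitions:
    def test_single_folding_transition(self):
        profile = profile_from_scores([-0.5, -0.2, 0.1, 0.4],
                                      phs=[0.0, 1.0, 2.0, 3.0])
        report = detect_transitions(profile, ci=0.02)
        assert report.verdict == "transition"
        assert len(report.transitions) == 1
        t = report.transitions[0]
        assert t.direction == CONDITIONAL_FOLDING
        # zero interpolated between the points scoring -0.2 and +0.1
        assert t.ph == pytest.approx(1.0 + 0.2 / 0.3)

    def test_in_band_pair_is_no_transition(self):
        profile = profile_from_scores([-0.015, 0.015])
        report = detect_transitions(profile, ci=0.02)
        assert report.verdict in ("folded", "unfolded")
        assert report.transitions == ()

    def test_double_crossing_is_multitransition(self):
        profile = profile_from_scores([-0.5, 0.5, -0.5])
        report = detect_transitions(profile, ci=0.02)
        assert report.verdict == "multitransition"
        assert [t.direction for t in report.transitions] == [
            CONDITIONAL_FOLDING,
            CONDITIONAL_UNFOLDING,
        ]

    def test_single_point_profile_never_transitions(self):
        report = detect_transitions(profile_from_scores([0.4]))
        assert report.verdict == "folded"

    def test_gate_needs_both_extremes_outside_band(self):
        # max above +ci but min inside the band: no transition
        report = detect_transitions(profile_from_scores([-0.01, 0.5]), ci=0.02)
        assert report.verdict == "folded"
        assert report.transitions == ()

    def test_in_band_wiggle_is_debounced(self):
        """Scores dipping inside the band without reaching the other side
        do not create spurious transitions."""
        profile = profile_from_scores([0.5, 0.01, -0.01, 0.01, 0.5, -0.5])
        report = detect_transitions(profile, ci=0.02)
        assert len(report.transitions) == 1
        assert report.transitions[0].direction == CONDITIONAL_UNFOLDING

    def test_extrema_recorded_with_their_ph(self):
        profile = profile_from_scores([-0.5, 0.7, -0.9, 0.1],
                                      phs=[0.0, 1.0, 2.0, 3.0])
        report = detect_transitions(profile)
        assert report.max_score == pytest.approx(0.7)
        assert report.max_score_ph == 1.0
        assert report.min_score == pytest.approx(-0.9)
        assert report.min_score_ph == 2.0

    def test_crossings_lie_inside_grid_and_increase(self):
        profile = profile_from_scores([-0.5, 0.5, -0.5, 0.5, -0.5])
        report = detect_transitions(profile)
        phs = [t.ph for t in report.transitions]
        assert phs == sorted(phs)
        assert all(profile.grid.ph_min <= p <= profile.grid.ph_max for p in phs)

    def test_band_robustness_to_small_perturbations(self):
        """Perturbations smaller than ci never flip the gate outcome when
        the extrema are strictly outside the band."""
        rng = np.random.default_rng(5)
        base = [-0.5, -0.2, 0.1, 0.4]
        reference = detect_transitions(profile_from_scores(base), ci=0.02)
        for _ in range(50):
            noise = rng.uniform(-0.019, 0.019, size=len(base))
            # keep extrema strictly outside the band after perturbation
            perturbed = np.array(base) + noise
            if not (perturbed.max() > 0.02 and perturbed.min() < -0.02):
                continue
            report = detect_transitions(profile_from_scores(list(perturbed)),
                                        ci=0.02)
            assert (report.verdict in ("transition", "multitransition")) == (
                reference.verdict in ("transition", "multitransition")
            )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        scores=st.lists(
            st.floats(-1.0, 1.0, allow_nan=False), min_size=2, max_size=30
        )
    )
    def test_parity_of_crossing_count(self, scores):
        """Odd number of crossings iff the debounced endpoint signs differ."""
        profile = profile_from_scores(scores)
        report = detect_transitions(profile, ci=0.02)
        arr = np.asarray(scores)
        if not (arr.max() > 0.02 and arr.min() < -0.02):
            assert report.transitions == ()
            return
        signs = _debounced_signs(arr, 0.02)
        endpoints_differ = signs[0] != signs[-1]
        assert (len(report.transitions) % 2 == 1) == endpoints_differ

    def test_parity_under_seeded_fuzzer(self):
        """Dense random score series keep the parity invariant."""
        rng = np.random.default_rng(123)
        for _ in range(2000):
            n = rng.integers(2, 30)
            scores = rng.uniform(-1, 1, size=n)
            report = detect_transitions(profile_from_scores(list(scores)),
                                        ci=0.02)
            if not (scores.max() > 0.02 and scores.min() < -0.02):
                assert report.transitions == ()
                continue
            signs = _debounced_signs(scores, 0.02)
            assert (len(report.transitions) % 2 == 1) == (signs[0] != signs[-1])

    def test_directions_alternate(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            scores = rng.uniform(-1, 1, size=20)
            report = detect_transitions(profile_from_scores(list(scores)))
            dirs = [t.direction for t in report.transitions]
            for a, b in zip(dirs, dirs[1:]):
                assert a != b


class TestClassifyPh:
    @pytest.mark.parametrize(
        "ph,expected",
        [
            (5.9, "acid"),
            (6.0, "neutral"),
            (7.0, "neutral"),
            (8.0, "neutral"),
            (8.5, "basic"),
            (0.0, "acid"),
            (14.0, "basic"),
        ],
    )
    def test_class_bounds(self, ph, expected):
        assert classify_transition_ph(ph) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            classify_transition_ph(14.5)


class TestSummarize:
    def test_all_quiet_dataset(self):
        reports = [
            detect_transitions(profile_from_scores([0.3, 0.4, 0.5]))
            for _ in range(10)
        ]
        summary = summarize_scan(reports)
        assert summary.pct_no_transition == 100.0
        assert summary.pct_transition == 0.0

    def test_mixed_dataset_counts(self):
        reports = [
            detect_transitions(profile_from_scores([0.3, 0.4])),
            detect_transitions(profile_from_scores([-0.3, -0.4])),
            detect_transitions(
                profile_from_scores([-0.5, 0.5], phs=[3.5, 4.5])
            ),
            detect_transitions(
                profile_from_scores([-0.5, 0.5, -0.5], phs=[3.0, 7.0, 11.0])
            ),
        ]
        s = summarize_scan(reports)
        assert s.total == 4
        assert s.n_no_transition == 2
        assert s.n_single_transition == 1
        assert s.n_multitransition == 1
        assert s.pct_transition == 50.0
        assert s.pct_single_of_transitioning == 50.0
        assert s.pct_multi_of_transitioning == 50.0
        # both first transitions are conditional folding
        assert s.pct_conditional_folding == 100.0
        assert s.pct_conditional_unfolding == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(17)
        reports = [
            detect_transitions(
                profile_from_scores(list(rng.uniform(-1, 1, size=12)))
            )
            for _ in range(50)
        ]
        s = summarize_scan(reports)
        assert s.pct_no_transition + s.pct_transition == pytest.approx(100.0)
        if s.n_single_transition + s.n_multitransition:
            assert (
                s.pct_single_of_transitioning + s.pct_multi_of_transitioning
            ) == pytest.approx(100.0)
            assert (
                s.pct_conditional_folding + s.pct_conditional_unfolding
            ) == pytest.approx(100.0)
            assert s.pct_acid + s.pct_neutral + s.pct_basic == pytest.approx(
                100.0
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            summarize_scan([])
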