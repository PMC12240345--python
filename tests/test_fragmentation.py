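"""Binarization, run tables, transition curves and the kAR/kRA indices."""

import numpy as np
import pytest

from acticomplex import (
    ActivityTrace,
    SemiMarkovParams,
    ValidationError,
    binarize,
    find_constant_region,
    fragmentation_analysis,
    fragmentation_index,
    generate_semi_markov_activity,
    run_length_table,
    transition_probability_curve,
)
from acticomplex.fragmentation import BinarySequence, ConstantRegion, TransitionCurve

from _oracles import naive_run_durations


def trace_of(values):
    return ActivityTrace(values=np.asarray(values, dtype=float), epoch_seconds=60.0)


def binary_of(states):
    return BinarySequence(
        states=np.asarray(states, dtype=bool), threshold=0.0167, epoch_seconds=60.0
    )


def curve_of(t, p, n_runs, direction="AR"):
    t = np.asarray(t)
    gap = np.diff(np.append(t, t[-1] + 1))
    return TransitionCurve(
        t=t,
        p=np.asarray(p, dtype=float),
        n_runs=np.asarray(n_runs),
        gap=gap,
        direction=direction,
        epoch_seconds=60.0,
    )


class TestBinarize:
    def test_all_above_threshold_single_run(self):
        b = binarize(trace_of([0.1, 0.2, 0.3]))
        assert b.states.all()

    def test_direct_comparison(self):
        b = binarize(trace_of([0.01, 0.05, 0.05, 0.01]))
        np.testing.assert_array_equal(b.states, [False, True, True, False])

    def test_exact_threshold_is_rest(self):
        b = binarize(trace_of([0.0167]))
        assert not b.states[0]


class TestRunLengthTable:
    def test_direct_enumeration(self):
        table = run_length_table(binary_of([1, 1, 0, 0, 0, 1]))
        np.testing.assert_array_equal(np.sort(table.active_durations), [1, 2])
        np.testing.assert_array_equal(table.rest_durations, [3])
        np.testing.assert_array_equal(table.survival("active"), [2, 1])

    def test_survival_counts(self):
        # active durations {1,1,1,5}: N_1=4, N_2..N_5=1
        states = [1, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1, 0]
        table = run_length_table(binary_of(states))
        np.testing.assert_array_equal(np.sort(table.active_durations), [1, 1, 1, 5])
        np.testing.assert_array_equal(table.survival("active"), [4, 1, 1, 1, 1])

    def test_matches_rescan_oracle(self):
        rng = np.random.default_rng(31)
        states = rng.random(500) < 0.4
        table = run_length_table(binary_of(states))
        active, rest = naive_run_durations(states)
        np.testing.assert_array_equal(table.active_durations, active)
        np.testing.assert_array_equal(table.rest_durations, rest)

    def test_single_state_flagged_not_thrown(self):
        table = run_length_table(binary_of([1, 1, 1]))
        assert "no_rest_runs" in table.flags
        assert table.rest_durations.size == 0

    def test_run_count_balance(self):
        # runs alternate, so counts differ by at most one
        for seed in range(10):
            states = np.random.default_rng(seed).random(200) < 0.5
            table = run_length_table(binary_of(states))
            assert abs(table.active_durations.size - table.rest_durations.size) <= 1

    def test_survival_telescopes_to_run_count(self):
        states = np.random.default_rng(3).random(300) < 0.3
        table = run_length_table(binary_of(states))
        for state in ("active", "rest"):
            survival = table.survival(state)
            n_beyond = np.append(survival, 0)
            assert (n_beyond[:-1] - n_beyond[1:]).sum() == table.durations(state).size
            assert np.all(np.diff(survival) <= 0)


class TestTransitionCurve:
    def test_all_unit_runs_force_transition(self):
        table = run_length_table(binary_of([1, 0] * 10))
        curve = transition_probability_curve(table, "AR")
        np.testing.assert_array_equal(curve.t, [1])
        assert curve.p[0] == 1.0

    def test_gap_corrected_hand_case(self):
        # durations {1,1,1,5}: p(1) = (4-1)/(4*4) = 0.1875, p(5) = 1
        states = [1, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1, 0]
        curve = transition_probability_curve(run_length_table(binary_of(states)), "AR")
        np.testing.assert_array_equal(curve.t, [1, 5])
        np.testing.assert_array_equal(curve.gap, [4, 1])
        assert curve.p[0] == pytest.approx(0.1875)
        assert curve.p[1] == pytest.approx(1.0)

    def test_memoryless_chain_constant_hazard(self):
        params = SemiMarkovParams(
            p_ar=0.2, p_ra=0.2, diurnal_depth=0.0, n_epochs=100_000, seed=17
        )
        trace = generate_semi_markov_activity(params)
        table = run_length_table(binarize(trace, params.threshold_g))
        curve = transition_probability_curve(table, "AR")
        # at well-populated durations the hazard is ~0.2 within binomial error
        for t, p, n in zip(curve.t, curve.p, curve.n_runs):
            if n >= 500:
                se = np.sqrt(0.2 * 0.8 / n)
                assert abs(p - 0.2) < 4 * se, f"t={t}: p={p}, n={n}"

    def test_probabilities_in_unit_interval(self):
        for seed in range(5):
            states = np.random.default_rng(seed).random(1000) < 0.3
            table = run_length_table(binary_of(states))
            for direction in ("AR", "RA"):
                curve = transition_probability_curve(table, direction)
                assert np.all((curve.p >= 0) & (curve.p <= 1))
                assert np.all(np.diff(curve.n_runs) <= 0)

    def test_empty_table_rejected(self):
        table = run_length_table(binary_of([1, 1, 1]))
        with pytest.raises(ValidationError, match="no rest runs"):
            transition_probability_curve(table, "RA")


class TestConstantRegion:
    def test_exactly_constant_curve_spans_domain(self):
        t = np.arange(1, 21)
        curve = curve_of(t, np.full(20, 0.3), np.arange(200, 180, -1))
        region = find_constant_region(curve)
        assert (region.start_index, region.end_index) == (0, 19)

    def test_plateau_containment(self):
        # steep fall / flat plateau / steep rise with known plateau indices;
        # the smoothing window is chosen to resolve the 6-point edges
        rng = np.random.default_rng(1)
        fall = np.linspace(1.0, 0.2, 7)[:-1]
        plateau = 0.2 + rng.normal(0, 0.01, 40)
        rise = np.linspace(0.2, 1.0, 7)[1:]
        p = np.concatenate((fall, plateau, rise))
        t = np.arange(1, len(p) + 1)
        n_runs = np.arange(len(p), 0, -1) * 10
        region = find_constant_region(curve_of(t, p, n_runs), lowess_fraction=0.3)
        assert region.start_index >= 6
        assert region.end_index <= 45

    def test_tie_broken_toward_earlier_window(self):
        # two flat windows of equal length separated by a spike
        p = np.array([0.2, 0.2, 0.2, 5.0, 0.4, 0.4, 0.4], dtype=float)
        t = np.arange(1, 8)
        region = find_constant_region(curve_of(t, p, np.full(7, 100)), lowess_fraction=0.2)
        assert region.start_index == 0

    def test_short_curve_rejected(self):
        curve = curve_of([1, 2], [0.5, 0.5], [10, 5])
        with pytest.raises(ValidationError, match=">= 3"):
            find_constant_region(curve)


class TestFragmentationIndex:
    def test_weighted_mean_of_constant_is_constant(self):
        curve = curve_of([1, 2, 3], [0.25, 0.25, 0.25], [100, 40, 10])
        region = ConstantRegion(0, 2, 1, 3)
        assert fragmentation_index(curve, region) == pytest.approx(0.25)

    def test_sqrt_weighted_hand_case(self):
        # (p=0.2, N=100) and (p=0.4, N=25): (10*0.2 + 5*0.4) / 15 = 4/15
        curve = curve_of([1, 2], [0.2, 0.4], [100, 25])
        region = ConstantRegion(0, 1, 1, 2)
        assert fragmentation_index(curve, region) == pytest.approx(4.0 / 15.0)

    def test_empty_region_rejected(self):
        curve = curve_of([1, 2], [0.2, 0.4], [100, 25])
        with pytest.raises(ValidationError, match="region"):
            fragmentation_index(curve, ConstantRegion(1, 0, 0, 0))


class TestEndToEnd:
    def test_memoryless_hazard_recovery(self):
        # kAR/kRA estimate the generating per-epoch hazards
        params = SemiMarkovParams(
            p_ar=0.25, p_ra=0.1, diurnal_depth=0.0, n_epochs=200_000, seed=23
        )
        trace = generate_semi_markov_activity(params)
        result = fragmentation_analysis(trace)
        assert result.k_ar == pytest.approx(0.25, rel=0.05)
        assert result.k_ra == pytest.approx(0.1, rel=0.05)

    def test_monotone_in_generating_hazard(self):
        estimates = []
        for p_ar in (0.05, 0.15, 0.4):
            params = SemiMarkovParams(
                p_ar=p_ar, p_ra=0.1, diurnal_depth=0.0, n_epochs=100_000, seed=3
            )
            result = fragmentation_analysis(generate_semi_markov_activity(params))
            estimates.append(result.k_ar)
        assert estimates == sorted(estimates)

    def test_single_state_trace_flagged(self):
        result = fragmentation_analysis(trace_of([0.5] * 100))
        assert np.isnan(result.k_ar) and np.isnan(result.k_ra)
        assert "no_rest_runs" in result.flags

    def test_alternating_trace_clamps_index(self):
        result = fragmentation_analysis(trace_of([0.5, 0.001] * 50))
        # every run has duration 1 so the raw estimate is 1; clamped below 1
        assert 0 < result.k_ar < 1
        assert "k_ar_clamped" in result.flags
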