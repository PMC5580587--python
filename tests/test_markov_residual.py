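import numpy as np
import pytest

import tmcgm
from tmcgm.markov_residual import DegeneratePartitionError
from tmcgm.series_io import SyntheticSpec


class TestPartition:
    def test_equal_width_bounds_and_labels(self):
        p = tmcgm.partition_states([-1.0, 0.0, 2.0], 3)
        np.testing.assert_allclose(p.lower, [-1, 0, 1])
        np.testing.assert_allclose(p.upper, [0, 1, 2])
        np.testing.assert_array_equal(p.labels, [1, 2, 3])

    def test_single_state_spans_range(self):
        p = tmcgm.partition_states([-0.5, 0.2, 0.9], 1)
        assert p.interval(1) == pytest.approx((-0.5, 0.9))
        np.testing.assert_array_equal(p.labels, [1, 1, 1])

    def test_boundary_residual_goes_to_higher_state(self):
        # internal bound at 0 for range [-1, 1] with r=2
        p = tmcgm.partition_states([-1.0, 0.0, 1.0], 2)
        assert p.labels[1] == 2

    def test_maximum_residual_stays_in_last_state(self):
        p = tmcgm.partition_states([-1.0, 0.5, 1.0], 2)
        assert p.labels[2] == 2

    def test_identical_residuals_are_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            tmcgm.partition_states([0.3, 0.3, 0.3], 2)

    def test_labels_lie_in_their_intervals(self, hd_fit):
        for r in (2, 3, 4, 5):
            p = tmcgm.partition_states(hd_fit.residuals[1:], r)
            for e, lab in zip(hd_fit.residuals[1:], p.labels):
                L, U = p.interval(int(lab))
                assert L <= e <= U


class TestTransitions:
    def test_hand_counted_one_step_matrix(self):
        t = tmcgm.estimate_transitions([1, 1, 2, 1], 2, m=1)
        np.testing.assert_allclose(t.matrix, [[0.5, 0.5], [1.0, 0.0]])
        np.testing.assert_array_equal(t.counts, [[1, 1], [1, 0]])
        np.testing.assert_array_equal(t.totals, [2, 1])

    def test_two_step_pairs(self):
        t = tmcgm.estimate_transitions([1, 2, 1, 2], 2, m=2)
        np.testing.assert_allclose(t.matrix, [[1, 0], [0, 1]])

    def test_unoccupied_state_gets_uniform_row(self):
        t = tmcgm.estimate_transitions([1, 1, 1], 2, m=1)
        np.testing.assert_allclose(t.matrix[1], [0.5, 0.5])

    def test_step_exceeding_labels_is_error(self):
        with pytest.raises(ValueError):
            tmcgm.estimate_transitions([1, 2], 2, m=2)

    def test_rows_are_stochastic_on_real_data(self, hd_context):
        np.testing.assert_allclose(hd_context.transitions.matrix.sum(axis=1), 1.0, atol=1e-12)


class TestPropagate:
    def test_single_and_double_step_hand_values(self):
        P = [[0.5, 0.5], [1.0, 0.0]]
        np.testing.assert_allclose(tmcgm.propagate([1, 0], P, 1), [0.5, 0.5])
        np.testing.assert_allclose(tmcgm.propagate([1, 0], P, 2), [0.75, 0.25])

    def test_identity_matrix_is_fixed_point(self):
        a = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(tmcgm.propagate(a, np.eye(3), 5), a)

    def test_probability_mass_conserved(self, hd_context):
        a = np.array([1.0, 0.0, 0.0])
        for k in range(1, 8):
            out = tmcgm.propagate(a, hd_context.transitions.matrix, k)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(out >= 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            tmcgm.propagate([1, 0, 0], np.eye(2))


class TestWhiten:
    def test_endpoint_and_midpoint_coefficients(self):
        p = tmcgm.partition_states([-1.0, 0.0, 1.0], 2)
        np.testing.assert_allclose(tmcgm.whiten(p, [0.5, 0.5]), [-0.5, 0.5])
        np.testing.assert_allclose(tmcgm.whiten(p, [1.0, 1.0]), p.lower)
        np.testing.assert_allclose(tmcgm.whiten(p, [0.0, 0.0]), p.upper)

    def test_whitened_value_stays_in_interval(self, hd_context):
        rng = np.random.default_rng(7)
        p = hd_context.partition
        for _ in range(20):
            v = tmcgm.whiten(p, rng.uniform(size=p.r))
            assert np.all(p.lower <= v) and np.all(v <= p.upper)


class TestCorrection:
    def test_first_two_points_pass_through(self, hd_fit, hd_context):
        out = tmcgm.corrected_series(hd_fit, hd_context)
        assert out[0] == hd_fit.fitted[0]
        assert out[1] == hd_fit.fitted[1]

    def test_indicator_distribution_collapses_to_single_correction(self, hd_fit, hd_context):
        # identity transitions make a(t) the indicator of the previous state
        ident = tmcgm.TransitionModel(
            step=1,
            counts=np.eye(3, dtype=int),
            totals=np.ones(3, dtype=int),
            matrix=np.eye(3),
        )
        ctx = tmcgm.CorrectionContext(hd_context.partition, ident, np.array([1.0, 0.5, 0.0]))
        v = tmcgm.whiten(ctx.partition, ctx.alpha)
        out = tmcgm.corrected_series(hd_fit, ctx)
        labels = ctx.partition.labels
        for idx in range(2, hd_fit.n):
            assert out[idx] == pytest.approx(hd_fit.fitted[idx] + v[labels[idx - 2] - 1])

    def test_uniform_distribution_with_symmetric_corrections_cancels(self, hd_fit):
        part = tmcgm.StatePartition(
            r=3,
            lower=np.array([-1.0, 0.0, 1.0]) - 1.0,
            upper=np.array([-1.0, 0.0, 1.0]) + 1.0,
            labels=tmcgm.partition_states(hd_fit.residuals[1:], 3).labels,
        )
        uniform = tmcgm.TransitionModel(
            step=1,
            counts=np.zeros((3, 3), dtype=int),
            totals=np.zeros(3, dtype=int),
            matrix=np.full((3, 3), 1 / 3),
        )
        ctx = tmcgm.CorrectionContext(part, uniform, np.full(3, 0.5))
        out = tmcgm.corrected_series(hd_fit, ctx)
        np.testing.assert_allclose(out, hd_fit.fitted, atol=1e-12)

    def test_correction_magnitude_is_bounded_by_state_extremes(self, hd_fit, hd_context):
        out = tmcgm.corrected_series(hd_fit, hd_context)
        bound = max(np.max(np.abs(hd_context.partition.lower)),
                    np.max(np.abs(hd_context.partition.upper)))
        assert np.all(np.abs(out - hd_fit.fitted) <= bound + 1e-12)

    def test_stored_state_probabilities_are_distributions(self, hd_fit, hd_context):
        tmcgm.corrected_series(hd_fit, hd_context)
        probs = hd_context.probs
        assert probs.shape == (hd_fit.n - 2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0)


class TestForecastCorrected:
    def test_identity_chain_shifts_every_forecast_by_last_state(self, hd_fit, hd_context):
        ident = tmcgm.TransitionModel(
            step=1, counts=np.eye(3, dtype=int), totals=np.ones(3, dtype=int), matrix=np.eye(3)
        )
        ctx = tmcgm.CorrectionContext(hd_context.partition, ident, np.full(3, 0.3))
        v = tmcgm.whiten(ctx.partition, ctx.alpha)
        last = ctx.partition.labels[-1]
        out = tmcgm.forecast_corrected(hd_fit, ctx, 4)
        np.testing.assert_allclose(out, tmcgm.forecast_gm11(hd_fit, 4) + v[last - 1])

    def test_zero_width_corrections_reduce_to_plain_forecast(self, hd_fit, hd_context):
        part = hd_context.partition
        zero = tmcgm.StatePartition(
            r=3, lower=np.zeros(3), upper=np.zeros(3), labels=part.labels
        )
        ctx = tmcgm.CorrectionContext(zero, hd_context.transitions, np.full(3, 0.5))
        np.testing.assert_allclose(
            tmcgm.forecast_corrected(hd_fit, ctx, 5), tmcgm.forecast_gm11(hd_fit, 5)
        )


class TestStateRecovery:
    def test_alternating_offsets_recover_exact_alternation_matrix(self):
        """A grey trend plus strictly alternating +/-c offsets must label
        residuals in two alternating states whose one-step chain is the
        exact permutation matrix, and correcting with it must improve fit."""
        spec = SyntheticSpec(
            a_true=-0.1, b_true=1.0, x1=1.0, n=12,
            noise_states=((1.0, 0.2), (1.0, -0.2)),
            transition=((0.0, 1.0), (1.0, 0.0)), seed=11,
        )
        series = tmcgm.generate_grey_series(spec)
        fit = tmcgm.fit_gm11(series)
        part = tmcgm.partition_states(fit.residuals[1:], 2)
        trans = tmcgm.estimate_transitions(part.labels, 2)
        np.testing.assert_array_equal(trans.matrix, [[0.0, 1.0], [1.0, 0.0]])
        ctx = tmcgm.CorrectionContext(part, trans, np.full(2, 0.5))
        opt = tmcgm.optimize_alpha(fit, ctx)
        ctx.alpha = opt.alpha
        corrected = tmcgm.corrected_series(fit, ctx)
        assert tmcgm.mape(series.values, corrected) < tmcgm.mape(series.values, fit.fitted)
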