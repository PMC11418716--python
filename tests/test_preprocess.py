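import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stairreach as sr
from oracles import (
    fill_gaps_oracle,
    jump_flags_oracle,
    smooth_oracle,
)
from stairreach.preprocess import fill_gaps, flag_jumps, smooth, usable_spans


def _sinusoid(n=100, amp=20.0):
    t = np.arange(n)
    x = amp * np.sin(2 * np.pi * t / 50)
    y = amp * np.cos(2 * np.pi * t / 50)
    return x, y


def _sinusoid_long(n=500):
    return _sinusoid(n)


class TestFlagJumps:
    def test_constant_trajectory_unflagged(self):
        x = np.full(50, 7.0)
        y = np.full(50, 3.0)
        out = flag_jumps(x, y, np.ones(50, bool), k=6)
        assert out.all()

    def test_single_spike_flagged_exactly(self):
        x, y = _sinusoid()
        x[40] += 50.0
        out = flag_jumps(x, y, np.ones(100, bool), k=6)
        assert set(np.flatnonzero(~out)) == {40}

    def test_two_consecutive_spikes_both_flagged(self):
        # tracker stuck on the same wrong object for two frames; the
        # long trace keeps the spikes from dominating the SD estimate
        x, y = _sinusoid_long()
        x[140] += 60.0
        x[141] += 60.0
        out = flag_jumps(x, y, np.ones(500, bool), k=6)
        assert set(np.flatnonzero(~out)) == {140, 141}
        np.testing.assert_array_equal(
            out, jump_flags_oracle(x, y, np.ones(500, bool), 6)
        )

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        x, y = _sinusoid()
        x[33] += 45.0
        base = flag_jumps(x, y, np.ones(100, bool), k=6)
        scaled = flag_jumps(c * x, c * y, np.ones(100, bool), k=6)
        np.testing.assert_array_equal(base, scaled)

    def test_agrees_with_oracle_on_random_traces(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            x = np.cumsum(rng.normal(0, 2, n))
            y = np.cumsum(rng.normal(0, 2, n))
            for f in rng.choice(n, size=min(3, n // 4), replace=False):
                x[f] += rng.uniform(30, 80)
            valid = rng.random(n) > 0.05
            if valid.sum() < 3:
                continue
            try:
                ours = flag_jumps(x, y, valid, k=6)
            except ValueError:
                continue
            np.testing.assert_array_equal(
                ours, jump_flags_oracle(x, y, valid, 6)
            )

    def test_all_rejected_is_an_error(self):
        x = np.array([0.0, 100.0, 0.0])
        with pytest.raises(ValueError, match="unusable"):
            flag_jumps(x, x, np.array([True, False, False]), k=6)


class TestFillGaps:
    def test_single_gap_filled_with_flank_mean(self):
        x = np.array([0.0, 99.0, 2.0])
        y = np.array([0.0, 99.0, 2.0])
        valid = np.array([True, False, True])
        xf, yf, usable, filled = fill_gaps(x, y, valid, max_gap=1)
        assert xf[1] == 1.0 and yf[1] == 1.0
        assert usable.all() and filled[1]

    def test_long_gap_splits_spans(self):
        valid = np.ones(20, bool)
        valid[8:13] = False
        x = np.arange(20.0)
        _, _, usable, filled = fill_gaps(x, x, valid, max_gap=1)
        assert not filled.any()
        assert usable_spans(usable) == [(0, 8), (13, 20)]

    def test_identity_without_gaps(self):
        x = np.arange(10.0)
        xf, yf, usable, filled = fill_gaps(x, x, np.ones(10, bool), 1)
        np.testing.assert_array_equal(xf, x)
        assert usable.all() and not filled.any()

    def test_leading_and_trailing_gaps_never_filled(self):
        valid = np.array([False, True, True, False])
        x = np.arange(4.0)
        _, _, usable, filled = fill_gaps(x, x, valid, max_gap=1)
        assert not filled.any()
        np.testing.assert_array_equal(usable, valid)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_never_modifies_valid_frames_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        valid = rng.random(n) > 0.3
        max_gap = int(rng.integers(1, 4))
        xf, yf, usable, filled = fill_gaps(x, y, valid, max_gap)
        np.testing.assert_array_equal(xf[valid], x[valid])
        ox, oy, ou, of = fill_gaps_oracle(x, y, valid, max_gap)
        np.testing.assert_allclose(xf, ox)
        np.testing.assert_allclose(yf, oy)
        np.testing.assert_array_equal(usable, ou)
        np.testing.assert_array_equal(filled, of)


class TestSmooth:
    def test_window_one_is_identity(self, rng):
        v = rng.normal(size=30)
        np.testing.assert_array_equal(smooth(v, np.ones(30, bool), 1), v)

    def test_constant_unchanged(self):
        v = np.full(40, 5.0)
        np.testing.assert_allclose(smooth(v, np.ones(40, bool), 10), v)

    def test_linear_ramp_interior_unchanged(self):
        v = np.arange(50.0)
        out = smooth(v, np.ones(50, bool), 10)
        np.testing.assert_allclose(out[5:-5], v[5:-5], atol=1e-9)

    @pytest.mark.parametrize("window", [2, 3, 7, 10])
    def test_convex_combination_bounds_and_oracle(self, rng, window):
        v = rng.normal(size=80)
        usable = rng.random(80) > 0.2
        out = smooth(v, usable, window)
        for s0, s1 in usable_spans(usable):
            seg_in, seg_out = v[s0:s1], out[s0:s1]
            assert seg_out.min() >= seg_in.min() - 1e-12
            assert seg_out.max() <= seg_in.max() + 1e-12
        np.testing.assert_allclose(out, smooth_oracle(v, usable, window))


class TestPreprocessPipeline:
    def test_clean_input_equals_smooth_of_raw(self):
        spec = sr.default_session_spec(
            3, noise_sd=0.0, spike_rate=0.0, dropout_rate=0.0
        )
        table, _ = sr.generate_session(spec)
        clean = sr.preprocess(table)
        j = table.index("paw_right")
        assert not clean.jump_rejected[:, j].any()
        assert not clean.gap_filled[:, j].any()
        expected = smooth(table.x[:, j], np.ones(table.n_frames, bool), 10)
        np.testing.assert_allclose(clean.table.x[:, j], expected)

    def test_spike_and_dropout_are_filled_then_smoothed(self):
        spec = sr.default_session_spec(
            3, noise_sd=0.0, spike_rate=0.0, dropout_rate=0.0
        )
        table, _ = sr.generate_session(spec)
        j = table.index("paw_right")
        table.x[500, j] += 60.0  # spike
        table.likelihood[900, j] = 0.0  # dropout
        clean = sr.preprocess(table)
        assert clean.jump_rejected[500, j]
        assert clean.gap_filled[500, j] and clean.gap_filled[900, j]
        assert clean.usable[:, j].all()
        # independent step-by-step oracle
        from oracles import fill_gaps_oracle, jump_flags_oracle, smooth_oracle

        valid0 = table.likelihood[:, j] >= 0.6
        v1 = jump_flags_oracle(table.x[:, j], table.y[:, j], valid0, 6)
        xo, yo, uo, _ = fill_gaps_oracle(table.x[:, j], table.y[:, j], v1, 1)
        np.testing.assert_allclose(
            clean.table.x[:, j], smooth_oracle(xo, uo, 10)
        )

    def test_all_invalid_landmark_is_unusable(self):
        spec = sr.default_session_spec(
            3, noise_sd=0.0, spike_rate=0.0, dropout_rate=0.0
        )
        table, _ = sr.generate_session(spec)
        table.likelihood[:, table.index("paw_left")] = 0.0
        with pytest.raises(ValueError, match="unusable"):
            sr.preprocess(table)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_full_pipeline_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        x = np.cumsum(rng.normal(0, 1.5, n))
        y = np.cumsum(rng.normal(0, 1.5, n))
        lik = np.where(rng.random(n) > 0.03, 0.99, 0.1)
        table = sr.TrajectoryTable(
            landmarks=["paw_right"],
            x=x[:, None],
            y=y[:, None],
            likelihood=lik[:, None],
            fps=100.0,
        )
        try:
            clean = sr.preprocess(table)
        except ValueError:
            return
        valid0 = lik >= 0.6
        v1 = jump_flags_oracle(x, y, valid0, 6)
        xo, yo, uo, _ = fill_gaps_oracle(x, y, v1, 1)
        np.testing.assert_allclose(
            clean.table.x[:, 0], smooth_oracle(xo, uo, 10)
        )
        np.testing.assert_array_equal(clean.usable[:, 0], uo)
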