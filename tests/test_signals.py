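"""Windowing, trimming, decimation and sampling-scheme equivalence."""

import numpy as np
import pytest

from hsvmcc.errors import EmptyStreamError, ParameterError
from hsvmcc.signals import (
    SamplingScheme,
    SensorStream,
    decimate,
    equivalent_window,
    read_stream_csv,
    scheme_equivalence_stats,
    segment_windows,
    trim_session,
    window_stream,
    write_stream_csv,
)
from hsvmcc.synth import default_config, generate_session


def make_stream(n, rate_hz=1.0, labels=None, accel_fn=None):
    t = np.arange(n) / rate_hz
    accel = accel_fn(t) if accel_fn else np.tile([0.0, 9.81, 0.0], (n, 1))
    return SensorStream(
        accel_t=t,
        accel=accel,
        pressure_t=t.copy(),
        pressure=np.full(n, 1013.25),
        rate_hz=rate_hz,
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )


class TestWindowing:
    def test_ten_seconds_at_one_hz_gives_two_five_second_windows(self):
        windows = window_stream(make_stream(10), 5.0)
        assert len(windows) == 2
        assert [w.n_accel for w in windows] == [5, 5]
        assert [w.n_pressure for w in windows] == [5, 5]

    def test_sixty_second_session_tiles_into_twelve_windows(self):
        windows = window_stream(make_stream(60), 5.0)
        assert len(windows) == 12

    @pytest.mark.parametrize("n,rate,window,overlap", [
        (60, 1.0, 5.0, 0.0),
        (100, 2.0, 4.0, 0.0),
        (100, 2.0, 4.0, 2.0),
        (37, 1.0, 7.0, 3.0),
    ])
    def test_tiling_count_and_coverage(self, n, rate, window, overlap):
        stream = make_stream(n, rate_hz=rate)
        windows = window_stream(stream, window, overlap)
        span = n / rate
        expected = int(np.floor((span - overlap) / (window - overlap)))
        assert len(windows) == expected
        counts = np.zeros(n, dtype=int)
        for w in windows:
            for t in w.accel_t:
                counts[int(round(t * rate))] += 1
        if overlap == 0:
            # every retained sample appears in exactly one window
            retained = counts[: int(expected * window * rate)]
            assert np.all(retained == 1)
        else:
            assert counts.max() >= 1

    def test_majority_label_with_earliest_tie_break(self):
        labels = ["walk"] * 2 + ["run"] * 2 + ["sit"]
        windows = window_stream(make_stream(5, labels=labels), 5.0)
        assert windows[0].label == "walk"  # 2-2 tie: earliest wins

    def test_empty_stream_and_bad_overlap_raise(self):
        with pytest.raises(ParameterError):
            window_stream(make_stream(10), 5.0, overlap_s=5.0)
        empty = make_stream(1)
        empty = SensorStream(
            accel_t=np.empty(0), accel=np.empty((0, 3)),
            pressure_t=np.empty(0), pressure=np.empty(0), rate_hz=1.0,
        )
        with pytest.raises(EmptyStreamError):
            window_stream(empty, 5.0)


class TestTrim:
    def test_drops_first_and_last_window(self):
        windows = window_stream(make_stream(60), 5.0)
        trimmed = trim_session(windows)
        assert len(trimmed) == 10
        assert trimmed[0] is windows[1] and trimmed[-1] is windows[-2]

    def test_two_windows_leave_nothing_interior(self):
        windows = window_stream(make_stream(10), 5.0)
        with pytest.warns(UserWarning):
            assert trim_session(windows) == []

    def test_three_windows_leave_middle(self):
        windows = window_stream(make_stream(15), 5.0)
        assert trim_session(windows) == [windows[1]]

    def test_fewer_than_two_raises(self):
        windows = window_stream(make_stream(5), 5.0)
        with pytest.raises(ParameterError):
            trim_session(windows)


class TestDecimate:
    def test_stride_point_sampling(self):
        rng = np.random.default_rng(0)
        stream = make_stream(100, rate_hz=50.0, accel_fn=lambda t: rng.normal(size=(t.size, 3)))
        low = decimate(stream, 1.0)
        assert low.n_samples == 2
        np.testing.assert_array_equal(low.accel, stream.accel[::50])
        np.testing.assert_array_equal(low.pressure, stream.pressure[::50])

    def test_identity_and_composition(self):
        rng = np.random.default_rng(1)
        stream = make_stream(200, rate_hz=20.0, accel_fn=lambda t: rng.normal(size=(t.size, 3)))
        same = decimate(stream, 20.0)
        np.testing.assert_array_equal(same.accel, stream.accel)
        two_step = decimate(decimate(stream, 10.0), 2.0)
        one_step = decimate(stream, 2.0)
        np.testing.assert_array_equal(two_step.accel, one_step.accel)
        np.testing.assert_array_equal(two_step.accel_t, one_step.accel_t)

    def test_constant_stream_stats_invariant(self):
        stream = make_stream(100, rate_hz=10.0)
        low = decimate(stream, 2.0)
        np.testing.assert_allclose(
            low.accel.mean(axis=0), stream.accel.mean(axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            low.accel.var(axis=0), stream.accel.var(axis=0), atol=1e-12
        )

    def test_non_integer_stride_raises_with_both_rates(self):
        stream = make_stream(100, rate_hz=10.0)
        with pytest.raises(ParameterError, match="10.0"):
            decimate(stream, 3.0)


class TestEquivalentWindow:
    def test_formula_values(self):
        assert equivalent_window(2.0, 1.0, 1.0) == pytest.approx(4.0)
        assert equivalent_window(2.0, 1.0, 4.0) == pytest.approx(1.0)

    def test_homogeneity_in_low_rate(self):
        assert equivalent_window(2.0, 1.0, 2.0) == pytest.approx(
            equivalent_window(2.0, 1.0, 1.0) / 2.0
        )

    def test_positivity_precondition(self):
        with pytest.raises(ParameterError):
            equivalent_window(0.0, 1.0, 1.0)


def periodic_table_stream(n=1200, rate=10.0):
    """Deterministic base stream whose value repeats every 5 base samples."""
    table = np.array([0.0, 1.0, -1.0, 2.0, 0.5])
    vals = table[np.arange(n) % 5]
    accel = np.column_stack([vals, vals + 9.81, -vals])
    t = np.arange(n) / rate
    return SensorStream(
        accel_t=t, accel=accel, pressure_t=np.empty(0),
        pressure=np.empty(0), rate_hz=rate,
    )


class TestSchemeEquivalence:
    def test_constant_signal_zero_relative_difference(self):
        stream = make_stream(100, rate_hz=5.0)
        cmp_ = scheme_equivalence_stats(
            stream, SamplingScheme(5.0, 1.0), SamplingScheme(1.0, 5.0)
        )
        assert cmp_.rel_mean_diff.max() < 1e-12

    def test_aligned_stride_equal_products_identical_multisets(self):
        # rate x window = 5 samples/window for both schemes; the base signal
        # repeats every 5 base samples with window starts on period boundaries,
        # so every window of either scheme holds the same value multiset.
        stream = periodic_table_stream()
        a, b = SamplingScheme(2.5, 2.0), SamplingScheme(10.0, 0.5)
        for scheme in (a, b):
            sub = decimate(stream, scheme.rate_hz)
            for w in window_stream(sub, scheme.window_s):
                np.testing.assert_array_equal(
                    np.sort(w.accel[:, 0]), np.array([-1.0, 0.0, 0.5, 1.0, 2.0])
                )
        cmp_ = scheme_equivalence_stats(stream, a, b)
        assert cmp_.rel_mean_diff.max() < 1e-12
        assert cmp_.rel_var_diff.max() < 1e-12

    def test_quasi_periodic_gait_stats_agree_within_five_percent(self):
        cfg = default_config(schedule=(("walking", 600),), rate_hz=5.0, seed=3)
        stream = generate_session(cfg)
        cmp_ = scheme_equivalence_stats(
            stream, SamplingScheme(5.0, 1.0), SamplingScheme(1.0, 5.0)
        )
        assert cmp_.rel_var_diff.max() < 0.05
        assert cmp_.rel_mean_diff[1] < 0.05  # gravity-dominated axis
        # horizontal-axis means are ~0, so compare absolutely (m/s^2)
        assert abs(cmp_.mean_a[0] - cmp_.mean_b[0]) < 0.05
        assert abs(cmp_.mean_a[2] - cmp_.mean_b[2]) < 0.05

    def test_mismatched_products_raise(self):
        stream = make_stream(100, rate_hz=5.0)
        with pytest.raises(ParameterError, match="rate_hz \\* window_s"):
            scheme_equivalence_stats(
                stream, SamplingScheme(5.0, 1.0), SamplingScheme(1.0, 4.0)
            )


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        cfg = default_config(schedule=(("walking", 20), ("running", 20)), seed=5)
        stream = generate_session(cfg)
        path = tmp_path / "stream.csv"
        write_stream_csv(stream, path)
        back = read_stream_csv(path, rate_hz=1.0)
        np.testing.assert_allclose(back.accel, stream.accel)
        np.testing.assert_allclose(back.pressure, stream.pressure)
        assert list(back.labels) == list(stream.labels)

    def test_segment_windows_trims_each_activity_run(self):
        cfg = default_config(schedule=(("walking", 30), ("running", 30)), seed=5)
        stream = generate_session(cfg)
        windows = segment_windows(stream, 5.0)
        assert len(windows) == 8  # (6 - 2) per 30 s segment
        assert {w.label for w in windows} == {"walking", "running"}
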