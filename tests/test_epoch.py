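"""Epoch container: construction, metadata-consistent subsetting, crop, resample."""

import numpy as np
import pandas as pd
import pytest

from fragmap import Epoch, make_epoch

from conftest import random_epoch


class TestConstruction:
    def test_timestamp_arithmetic(self):
        ep = make_epoch(np.zeros((3, 100)), ["a", "b", "c"], -1.0, 100.0)
        assert ep.n_times == 100
        assert ep.times[0] == -1.0
        assert ep.end_time == pytest.approx(-1.0 + 99 / 100)

    def test_zero_matrix_identity(self):
        ep = make_epoch(np.zeros((2, 10)), ["x", "y"], 0.0, 10.0)
        assert np.all(ep.data == 0)

    @pytest.mark.parametrize("bad", [
        dict(electrodes=["a", "b"]),                       # count mismatch
        dict(electrodes=["a", "a", "b"]),                  # duplicates
        dict(electrodes=["a", "", "b"]),                   # empty name
        dict(sampling_rate=0.0),
        dict(sampling_rate=-5.0),
    ])
    def test_validation_errors(self, bad):
        kwargs = dict(data=np.zeros((3, 10)), electrodes=["a", "b", "c"],
                      start_time=0.0, sampling_rate=100.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_epoch(**kwargs)

    def test_row_data_length_mismatch(self):
        with pytest.raises(ValueError, match="row_data"):
            make_epoch(np.zeros((3, 10)), ["a", "b", "c"], 0.0, 100.0,
                       row_data=pd.DataFrame({"soz": [True, False]}))

    def test_row_data_defaults_to_empty_table(self):
        ep = make_epoch(np.zeros((3, 10)), ["a", "b", "c"], 0.0, 100.0)
        assert len(ep.row_data) == 3
        assert list(ep.row_data.columns) == []


class TestSubset:
    def test_rows_keep_metadata_order(self, small_epoch):
        sub = small_epoch.subset([0, 2], None)
        assert sub.electrodes == ["LA1", "LB1"]
        assert list(sub.row_data["soz"]) == [True, False]
        assert np.array_equal(sub.data, small_epoch.data[[0, 2]])

    def test_identity(self, small_epoch):
        sub = small_epoch.subset(None, None)
        assert sub.electrodes == small_epoch.electrodes
        assert np.array_equal(sub.data, small_epoch.data)
        assert sub.start_time == small_epoch.start_time

    def test_time_window_updates_start(self):
        ep = make_epoch(np.arange(300).reshape(3, 100), ["a", "b", "c"], 0.0, 100.0)
        sub = ep.subset(None, list(range(10, 20)))
        assert sub.start_time == pytest.approx(0.1)
        assert sub.n_times == 10

    def test_by_name_and_getitem(self, small_epoch):
        sub = small_epoch[["LB1", 0], :]
        assert sub.electrodes == ["LB1", "LA1"]
        sub2 = small_epoch[:, 10:20]
        assert sub2.n_times == 10

    def test_noncontiguous_time_rejected(self, small_epoch):
        with pytest.raises(ValueError, match="contiguous"):
            small_epoch.subset(None, [0, 2, 4])

    def test_bounds_and_name_errors(self, small_epoch):
        with pytest.raises(IndexError):
            small_epoch.subset([5], None)
        with pytest.raises(KeyError, match="NOPE"):
            small_epoch.subset(["NOPE"], None)
        with pytest.raises(IndexError):
            small_epoch.subset(None, [99, 100])

    def test_random_consistency_property(self, rng):
        """Electrodes, row_data and data of a subset agree row-for-row."""
        for _ in range(200):
            ep = random_epoch(rng)
            rows = list(rng.choice(ep.n_electrodes,
                                   size=rng.integers(1, ep.n_electrodes + 1),
                                   replace=False))
            t0 = int(rng.integers(0, ep.n_times))
            t1 = int(rng.integers(t0, ep.n_times)) + 1
            sub = ep.subset(rows, list(range(t0, t1)))
            assert sub.electrodes == [ep.electrodes[i] for i in rows]
            assert list(sub.row_data["soz"]) == [ep.row_data["soz"].iloc[i]
                                                 for i in rows]
            assert np.array_equal(sub.data, ep.data[np.ix_(rows, range(t0, t1))])
            assert sub.meta_data == ep.meta_data


class TestCrop:
    def test_half_open_arithmetic(self):
        ep = make_epoch(np.zeros((2, 10000)), ["a", "b"], 0.0, 1000.0)
        sub = ep.crop(2.0, 4.0)
        assert sub.n_times == 2000
        assert sub.start_time == pytest.approx(2.0)

    def test_full_span_identity(self, small_epoch):
        sub = small_epoch.crop(small_epoch.start_time,
                               small_epoch.end_time + 1.0)
        assert np.array_equal(sub.data, small_epoch.data)

    def test_empty_intersection_reports_span(self, small_epoch):
        with pytest.raises(ValueError, match="spans"):
            small_epoch.crop(100.0, 200.0)

    def test_composition(self, rng):
        """crop(a,b) then crop(c,d) with [c,d) inside [a,b) == crop(c,d)."""
        for _ in range(100):
            ep = random_epoch(rng, n=int(rng.integers(50, 400)))
            dur = ep.n_times / ep.sampling_rate
            a = ep.start_time + rng.uniform(0, dur / 4)
            b = a + rng.uniform(dur / 2, dur * 3 / 4)
            c = a + rng.uniform(0, (b - a) / 4)
            d = c + rng.uniform((b - a) / 4, (b - a) / 2)
            once = ep.crop(c, d)
            twice = ep.crop(a, b).crop(c, d)
            assert np.array_equal(once.data, twice.data)
            assert once.start_time == pytest.approx(twice.start_time)


class TestResample:
    def test_length_arithmetic(self):
        ep = make_epoch(np.random.default_rng(0).standard_normal((2, 5000)),
                        ["a", "b"], 0.0, 1000.0)
        out = ep.resample(500.0)
        assert out.n_times == 2500
        assert out.sampling_rate == 500.0

    def test_same_rate_passthrough(self, small_epoch):
        out = small_epoch.resample(small_epoch.sampling_rate)
        assert np.array_equal(out.data, small_epoch.data)

    def test_sinusoid_peak_preserved(self):
        t = np.arange(4000) / 1000.0
        sine = np.sin(2 * np.pi * 10 * t)
        ep = make_epoch(np.vstack([sine, sine]), ["a", "b"], 0.0, 1000.0)
        out = ep.resample(250.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_times, 1 / 250.0)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.3)

    def test_duration_preserved_property(self, rng):
        for _ in range(100):
            ep = random_epoch(rng, n=int(rng.integers(50, 500)))
            new_rate = float(rng.choice([100.0, 200.0, 250.0, 400.0]))
            out = ep.resample(new_rate)
            dur_in = ep.n_times / ep.sampling_rate
            dur_out = out.n_times / out.sampling_rate
            assert abs(dur_in - dur_out) <= 1.0 / new_rate + 1e-12

    def test_nonpositive_rate_rejected(self, small_epoch):
        with pytest.raises(ValueError):
            small_epoch.resample(0.0)


class TestPlotRaw:
    def test_trace_count_and_onset_marker(self, small_epoch):
        fig = small_epoch.plot_raw()
        ax = fig.axes[0]
        solid = [ln for ln in ax.lines if ln.get_linestyle() == "-"]
        assert len(solid) == 3
        vlines = [ln for ln in ax.lines if ln.get_linestyle() == "--"]
        assert any(np.allclose(ln.get_xdata(), 0.0) for ln in vlines)

    def test_highlight_styling(self, small_epoch):
        fig = small_epoch.plot_raw(highlight=["LA2"])
        ax = fig.axes[0]
        red = [ln for ln in ax.lines if ln.get_color() == "red"]
        assert len(red) == 1

    def test_unknown_highlight_errors(self, small_epoch):
        with pytest.raises(KeyError):
            small_epoch.plot_raw(highlight=["ZZ9"])
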