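import dataclasses

import numpy as np
import pytest
from scipy.signal import get_window

import nfpredict as nf
from nfpredict.design import _window_band_power

from oracles import band_power_oracle


class TestFrequencyBands:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((8, 30, 3, 1), [(8, 11)] + [None] * 8 + [(26, 29)]),
            ((8, 11, 3, 1), [(8, 11)]),
            ((8, 13, 3, 1), [(8, 11), (10, 13)]),
        ],
    )
    def test_band_enumeration(self, args, expected):
        bs = nf.build_frequency_bands(*args)
        assert len(bs) == len(expected)
        assert bs.bands[0] == expected[0]
        assert bs.bands[-1] == expected[-1]

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            nf.build_frequency_bands(8, 30, 1, 2)  # width <= overlap
        with pytest.raises(ValueError):
            nf.build_frequency_bands(8, 9, 3, 1)  # nothing fits


class TestSlidingBandPower:
    def test_sinusoid_concentrates_in_its_bands(self, short_recording, band_set):
        x = nf.sliding_band_power(short_recording, band_set)
        mean_power = x.values[x.n_prefix:, 0, :].mean(axis=0)
        # 10 Hz lives in [8,11] and [10,13]; everything from [14,17] up is noise floor
        assert mean_power[0] > 100 * mean_power[3:].max()
        assert mean_power[1] > 100 * mean_power[3:].max()

    def test_matches_independent_fft_oracle(self, short_recording, band_set):
        x = nf.sliding_band_power(short_recording, band_set)
        fs = short_recording.srate
        # check a handful of full windows against the hand-rolled periodogram
        for i in (20, 77, 150):
            end = int(round((i + 1) * 0.25 * fs))
            seg = short_recording.data[0, end - int(2 * fs):end]
            for j, band in enumerate(band_set.bands):
                expected = band_power_oracle(seg, fs, band)
                assert x.values[i, 0, j] == pytest.approx(expected, rel=1e-9)

    def test_zero_signal_gives_zero_tensor(self, band_set):
        rec = nf.EEGRecording(
            data=np.zeros((1, 1280)), srate=128.0, channel_names=["C3"]
        )
        x = nf.sliding_band_power(rec, band_set)
        assert np.all(x.values == 0)

    def test_320s_session_has_1280_rows(self, band_set):
        rec = nf.EEGRecording(
            data=np.random.default_rng(0).normal(size=(1, 320 * 128)),
            srate=128.0,
            channel_names=["C3"],
        )
        x = nf.sliding_band_power(rec, band_set)
        assert x.n_times == 1280
        assert np.all(x.values >= 0)

    def test_energy_conservation_full_partition(self, rng):
        # a partition whose band edges fall between the 0.5 Hz FFT bins
        # covers every bin exactly once; total band power must then equal
        # the tapered window's power (Parseval)
        fs = 150.0
        seg = rng.standard_normal(int(2 * fs))
        lows = -0.25 + 2.0 * np.arange(38)
        bands = nf.FrequencyBandSet(
            bands=tuple((lo, lo + 2.0) for lo in lows), width_hz=2.0, overlap_hz=0.0
        )
        bp = _window_band_power(seg[None, :], fs, bands)[0]
        nbins = [
            np.sum((np.fft.rfftfreq(len(seg), 1 / fs) >= lo)
                   & (np.fft.rfftfreq(len(seg), 1 / fs) <= lo + 2.0))
            for lo in lows
        ]
        total = np.sum(bp * np.array(nbins)) * (1.0 / 2.0)  # df = 0.5 Hz
        w = get_window("hamming", len(seg))
        windowed_power = np.sum((w * seg) ** 2) / np.sum(w**2)
        assert total == pytest.approx(windowed_power, rel=1e-2)

    def test_errors(self, band_set):
        low_rate = nf.EEGRecording(
            data=np.zeros((1, 100)), srate=50.0, channel_names=["C3"]
        )
        with pytest.raises(ValueError, match="too low"):
            nf.sliding_band_power(low_rate, band_set)
        short = nf.EEGRecording(
            data=np.zeros((1, 64)), srate=128.0, channel_names=["C3"]
        )
        with pytest.raises(ValueError, match="shorter"):
            nf.sliding_band_power(short, band_set)


class TestHRFKernel:
    def test_peak_location_and_normalization(self):
        k = nf.hrf_kernel(4.0, srate=4.0)
        assert np.argmax(k) == 16  # 4.0 s at 4 Hz
        assert k.max() == pytest.approx(1.0)

    def test_earlier_peak_parameter_peaks_earlier(self):
        assert np.argmax(nf.hrf_kernel(3.0)) < np.argmax(nf.hrf_kernel(5.0))

    def test_tail_decays(self):
        k = nf.hrf_kernel(4.0, srate=4.0, duration_s=40.0)
        lags = np.arange(len(k)) / 4.0
        assert np.all(np.abs(k[lags > 32.0]) < 0.01)

    def test_has_undershoot(self):
        k = nf.hrf_kernel(4.0)
        assert k.min() < 0

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            nf.hrf_kernel(0.0)


class TestConvolveDesign:
    def _impulse_design(self, band_set, T=100):
        values = np.zeros((T, 2, len(band_set)))
        values[10, 0, 2] = 1.0
        return nf.DesignTensor(
            values=values,
            times=np.arange(1, T + 1) * 0.25,
            feature_labels=[("C3", 0), ("Cz", 0)],
            band_set=band_set,
        )

    def test_impulse_reproduces_kernel(self, band_set):
        x0 = self._impulse_design(band_set)
        k = nf.hrf_kernel(4.0)
        out = nf.convolve_design(x0, k, delay_s=4)
        np.testing.assert_allclose(out.values[10:10 + 50, 0, 2], k[:50],
                                   atol=1e-12)
        np.testing.assert_allclose(out.values[:10], 0, atol=1e-12)  # causal
        np.testing.assert_allclose(out.values[:, 1, :], 0, atol=1e-12)

    def test_linearity(self, band_set, rng):
        T = 80
        mk = lambda v: nf.DesignTensor(
            values=v, times=np.arange(1, T + 1) * 0.25,
            feature_labels=[("C3", 0)], band_set=band_set,
        )
        a, b = rng.standard_normal((T, 1, 10)), rng.standard_normal((T, 1, 10))
        k = nf.hrf_kernel(3.0)
        lhs = nf.convolve_design(mk(2.0 * a + 3.0 * b), k).values
        rhs = (2.0 * nf.convolve_design(mk(a), k).values
               + 3.0 * nf.convolve_design(mk(b), k).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_constant_input_reaches_kernel_sum(self, band_set):
        T = 400
        x0 = nf.DesignTensor(
            values=np.full((T, 1, 10), 2.0),
            times=np.arange(1, T + 1) * 0.25,
            feature_labels=[("C3", 0)],
            band_set=band_set,
        )
        k = nf.hrf_kernel(4.0)
        out = nf.convolve_design(x0, k)
        assert out.values[-1, 0, 0] == pytest.approx(2.0 * k.sum(), rel=1e-9)

    def test_empty_kernel_rejected(self, band_set):
        with pytest.raises(ValueError):
            nf.convolve_design(self._impulse_design(band_set), np.array([]))


class TestAssembleRestrict:
    def test_block_sizes_by_mode(self, small_design, band_set):
        E = 8
        assert small_design.shape[1] == 4 * E
        x0 = nf.DesignTensor(
            values=small_design.block(0),
            times=small_design.times,
            feature_labels=[(e, 0) for e in small_design.electrodes],
            band_set=band_set,
        )
        assert nf.assemble_design(x0, mode="delayed_only").shape[1] == 3 * E
        x0_again = nf.assemble_design(x0, mode="x0_only")
        np.testing.assert_array_equal(x0_again.values, x0.values)

    def test_full_design_prepends_x0_block(self, small_design):
        np.testing.assert_array_equal(
            small_design.block(0), small_design.values[:, :8, :]
        )

    def test_restrict_commutes_with_assemble(self, small_design, band_set):
        keep = ["C3", "FC3", "CP3"]
        x0 = nf.DesignTensor(
            values=small_design.block(0),
            times=small_design.times,
            feature_labels=[(e, 0) for e in small_design.electrodes],
            band_set=band_set,
        )
        a = nf.restrict_active_set(nf.assemble_design(x0, mode="full"), keep)
        b = nf.assemble_design(nf.restrict_active_set(x0, keep), mode="full")
        np.testing.assert_allclose(a.values, b.values)
        assert a.feature_labels == b.feature_labels

    def test_restrict_unknown_label(self, small_design):
        with pytest.raises(KeyError, match="XX"):
            nf.restrict_active_set(small_design, ["C3", "XX"])

    def test_restrict_identity(self, small_design):
        out = nf.restrict_active_set(small_design, small_design.electrodes)
        np.testing.assert_array_equal(out.values, small_design.values)


class TestClipOutliers:
    def _design_with_outlier(self, band_set):
        values = np.zeros((100, 1, 10))
        values[50, 0, 0] = 100.0
        return nf.DesignTensor(
            values=values, times=np.arange(1, 101) * 0.25,
            feature_labels=[("C3", 0)], band_set=band_set,
        )

    def test_outlier_clipped_to_mean_plus_3std(self, band_set):
        x = self._design_with_outlier(band_set)
        col = x.values[:, 0, 0]
        expected = col.mean() + 3 * col.std()
        out, stats = nf.clip_outliers(x, k=3)
        assert out.values[50, 0, 0] == pytest.approx(expected)
        assert np.all(out.values[:50] == 0)

    def test_constant_column_unchanged(self, band_set):
        x = nf.DesignTensor(
            values=np.full((20, 1, 10), 7.0), times=np.arange(1, 21) * 0.25,
            feature_labels=[("C3", 0)], band_set=band_set,
        )
        out, _ = nf.clip_outliers(x)
        np.testing.assert_array_equal(out.values, x.values)

    def test_huge_k_is_identity(self, band_set):
        x = self._design_with_outlier(band_set)
        out, _ = nf.clip_outliers(x, k=1e12)
        np.testing.assert_array_equal(out.values, x.values)

    def test_idempotent_with_stored_stats(self, small_design):
        once, stats = nf.clip_outliers(small_design, k=2)
        twice, _ = nf.clip_outliers(once, stats=stats)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_stats_transfer_to_test_session(self, small_design):
        _, stats = nf.clip_outliers(small_design, k=3)
        shifted = dataclasses.replace(
            small_design, values=small_design.values + 1.0
        )
        out, _ = nf.clip_outliers(shifted, stats=stats)
        hi = stats.mean + 3 * stats.std
        assert np.all(out.values <= hi + 1e-12)


class TestDropBadSamples:
    def test_mask_removes_paired_rows(self, small_design):
        T = small_design.n_times
        y = nf.NFScoreSeries(values=np.arange(T, dtype=float), kind="c",
                             times=small_design.times)
        mask = np.zeros(T, dtype=bool)
        mask[5:15] = True
        x_out, y_out = nf.drop_bad_samples(small_design, y, mask)
        assert x_out.n_times == T - 10
        assert len(y_out) == T - 10
        np.testing.assert_array_equal(y_out.values[:5], np.arange(5))
        assert y_out.values[5] == 15.0  # pairing preserved across the gap

    def test_empty_mask_is_identity(self, small_design):
        T = small_design.n_times
        y = nf.NFScoreSeries(values=np.zeros(T), kind="c", times=small_design.times)
        x_out, y_out = nf.drop_bad_samples(small_design, y, np.zeros(T, bool))
        np.testing.assert_array_equal(x_out.values, small_design.values)

    def test_all_masked_is_error(self, small_design):
        T = small_design.n_times
        y = nf.NFScoreSeries(values=np.zeros(T), kind="c", times=small_design.times)
        with pytest.raises(ValueError, match="all samples"):
            nf.drop_bad_samples(small_design, y, np.ones(T, bool))
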