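"""Preprocessing chain: loading, resampling, filtering, epoching."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram, welch

from somnastage.preprocess import (ChannelSignal, EpochSet, PsgRecord,
                                   bandpass_filter, epoch_and_align,
                                   load_psg, notch_filter, pipeline,
                                   preprocess_record, rereference, resample,
                                   write_edf, write_hypnogram_csv)
from somnastage.synthetic import default_spec, generate_record, write_psg


def _tone(freq, fs, seconds=20.0, amp=1.0, name="T"):
    t = np.arange(int(fs * seconds)) / fs
    return ChannelSignal(name, amp * np.sin(2 * np.pi * freq * t), fs)


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def _db(before, after):
    return 20 * np.log10(_rms(before.samples) / max(_rms(after.samples),
                                                    1e-300))


class TestResample:
    def test_identity_when_rates_match(self):
        sig = _tone(5, 100)
        out = resample(sig, 100)
        assert np.array_equal(out.samples, sig.samples)

    def test_tone_survives_512_to_100(self):
        sig = _tone(5, 512, seconds=30)
        out = resample(sig, 100)
        f, p = periodogram(out.samples, fs=100)
        assert f[np.argmax(p)] == pytest.approx(5.0, abs=f[1] - f[0])

    def test_length_arithmetic_125_to_100(self):
        sig = ChannelSignal("x", np.zeros(12_000), 125)
        assert len(resample(sig, 100).samples) == 9_600


class TestNotch:
    def test_line_tone_attenuated_20db(self):
        sig = _tone(60, 200)
        out = notch_filter(sig, 60)
        assert _db(sig, out) >= 20

    def test_passband_within_1db(self):
        sig = _tone(10, 200)
        out = notch_filter(sig, 60)
        assert abs(_db(sig, out)) <= 1

    def test_zero_in_zero_out(self):
        sig = ChannelSignal("z", np.zeros(2000), 200)
        assert np.allclose(notch_filter(sig, 60).samples, 0)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch_filter(_tone(10, 100), 50)


class TestBandpass:
    def test_drift_attenuated_20db(self):
        sig = _tone(0.2, 100, seconds=60)
        out = bandpass_filter(sig, 1, 40)
        assert _db(sig, out) >= 20

    def test_passband_within_1db(self):
        sig = _tone(10, 100)
        out = bandpass_filter(sig, 1, 40)
        assert abs(_db(sig, out)) <= 1

    def test_zero_in_zero_out(self):
        sig = ChannelSignal("z", np.zeros(2000), 100)
        assert np.allclose(bandpass_filter(sig).samples, 0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_tone(10, 100), 40, 1)


class TestRereference:
    def test_identical_inputs_cancel(self):
        a = _tone(5, 100, name="C3")
        out = rereference(a, a)
        assert np.allclose(out.samples, 0)
        assert out.name == "C3-C3"

    def test_pointwise_subtraction(self):
        a = ChannelSignal("A", [3.0, 1.0], 1)
        r = ChannelSignal("R", [1.0, 1.0], 1)
        assert np.array_equal(rereference(a, r).samples, [2.0, 0.0])

    def test_linearity(self, rng):
        a = ChannelSignal("A", rng.normal(size=100), 10)
        r = ChannelSignal("R", rng.normal(size=100), 10)
        double = rereference(ChannelSignal("A", 2 * a.samples, 10),
                             ChannelSignal("R", 2 * r.samples, 10))
        assert np.allclose(double.samples,
                           2 * rereference(a, r).samples)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rereference(_tone(5, 100), _tone(5, 200))


class TestLoadPsg:
    def test_round_trip_unchanged(self, tmp_path, small_record):
        write_psg(small_record, tmp_path / "r.edf", tmp_path / "r.csv")
        rec = load_psg(tmp_path / "r.edf", tmp_path / "r.csv")
        assert [c.name for c in rec.channels] == \
            [c.name for c in small_record.channels]
        assert len(rec.annotations) == len(small_record.annotations)

    def test_unlabeled_signal_tail_truncated(self, tmp_path, small_record):
        write_edf(small_record.channels, tmp_path / "r.edf")
        # labels for only 6 of the 10 epochs
        stages = [s for _, _, s in small_record.annotations][:6]
        write_hypnogram_csv(stages, tmp_path / "r.csv")
        rec = load_psg(tmp_path / "r.edf", tmp_path / "r.csv")
        assert all(len(c.samples) == 6 * 3000 for c in rec.channels)

    def test_signal_shorter_than_labels_is_an_error(self, tmp_path,
                                                    small_record):
        write_edf(small_record.channels, tmp_path / "r.edf")
        stages = [s for _, _, s in small_record.annotations] + ["W", "W"]
        write_hypnogram_csv(stages, tmp_path / "r.csv")
        with pytest.raises(ValueError, match="signal loss"):
            load_psg(tmp_path / "r.edf", tmp_path / "r.csv")

    def test_missing_channel_named_in_error(self, tmp_path, small_record):
        write_psg(small_record, tmp_path / "r.edf", tmp_path / "r.csv")
        with pytest.raises(KeyError, match="C9"):
            load_psg(tmp_path / "r.edf", tmp_path / "r.csv",
                     channel_select=["C9"])

    def test_derivation_computed_by_rereference(self, tmp_path, rng):
        fs, n = 100.0, 9000
        c3 = ChannelSignal("C3", rng.normal(size=n), fs)
        m2 = ChannelSignal("M2", rng.normal(size=n), fs)
        write_edf([c3, m2], tmp_path / "d.edf")
        write_hypnogram_csv(["W", "N2", "REM"], tmp_path / "d.csv")
        rec = load_psg(tmp_path / "d.edf", tmp_path / "d.csv",
                       channel_select=["C3-M2"])
        got = rec.channels[0]
        assert got.name == "C3-M2"
        # pointwise subtraction, up to 16-bit quantization of each input
        span = max(np.ptp(c3.samples), np.ptp(m2.samples))
        assert np.abs(got.samples -
                      (c3.samples - m2.samples)).max() <= 2 * span / 2 ** 15


class TestEpochAndAlign:
    def _record(self, stages, fs=100.0, extra_seconds=0.0):
        n = int(len(stages) * 30 * fs + extra_seconds * fs)
        rng = np.random.default_rng(0)
        ch = ChannelSignal("EEG", rng.normal(size=n), fs)
        ann = [(30.0 * i, 30.0, s) for i, s in enumerate(stages)]
        return PsgRecord("r", [ch], ann)

    def test_trailing_partial_epoch_dropped(self):
        # 95 s of signal but only 3 complete labeled epochs
        rec = self._record(["W", "N2", "N3"], extra_seconds=5.0)
        epochs, counts = epoch_and_align(rec)
        assert len(epochs) == 3
        assert counts.total == 3

    def test_n4_merge_and_nonstage_exclusion(self):
        rec = self._record(["W", "N4", "MOVEMENT", "REM"])
        epochs, counts = epoch_and_align(rec)
        assert list(epochs.labels) == ["W", "N3", "REM"]
        assert counts.as_dict()["N3"] == 1

    def test_counts_sum_to_total(self, small_epochset):
        rep = small_epochset.stage_counts()
        assert rep.total == sum(rep.counts.values()) == len(small_epochset)

    def test_wrong_rate_rejected(self):
        rec = self._record(["W"], fs=125.0)
        with pytest.raises(ValueError, match="100"):
            epoch_and_align(rec)

    def test_all_nonstage_labels_is_an_error(self):
        rec = self._record(["MOVEMENT", "?"])
        with pytest.raises(ValueError, match="no valid epochs"):
            epoch_and_align(rec)


class TestPipeline:
    def test_repeated_runs_bit_identical(self, tmp_path, small_record):
        write_psg(small_record, tmp_path / "r.edf", tmp_path / "r.csv")
        a, _ = pipeline(tmp_path / "r.edf", tmp_path / "r.csv")
        b, _ = pipeline(tmp_path / "r.edf", tmp_path / "r.csv")
        assert np.array_equal(a.data, b.data)

    def test_line_noise_and_drift_removed_20db(self):
        # synthetic record at 200 Hz so the 60 Hz notch is exercised too
        spec = default_spec(n_epochs=4, fs=200, line_freq=60, seed=3)
        spec = dataclasses.replace(spec, line_amplitude=30.0,
                                   drift_amplitude=40.0)
        rec = generate_record(spec, "noisy")
        pre = preprocess_record(rec)
        for raw, post in zip(rec.channels, pre.channels):
            f0, p0 = welch(raw.samples, fs=raw.fs, nperseg=2048)
            f1, p1 = welch(post.samples, fs=post.fs, nperseg=1024)

            def bandpower(f, p, lo, hi):
                m = (f >= lo) & (f <= hi)
                return p[m].sum() * (f[1] - f[0])

            rel0 = bandpower(f0, p0, 59, 61) / bandpower(f0, p0, 0, 100)
            rel1 = max(bandpower(f1, p1, 59, 61) / bandpower(f1, p1, 0, 50),
                       1e-15)
            assert 10 * np.log10(rel0 / rel1) >= 20
            drift0 = bandpower(f0, p0, 0.01, 0.5) / bandpower(f0, p0, 0, 100)
            drift1 = bandpower(f1, p1, 0.01, 0.5) / bandpower(f1, p1, 0, 50)
            assert 10 * np.log10(drift0 / drift1) >= 20

    def test_filtering_preserves_length(self, rng):
        sig = ChannelSignal("x", rng.normal(size=5000), 200)
        assert len(notch_filter(sig, 60).samples) == 5000
        assert len(bandpass_filter(sig).samples) == 5000

    def test_epochset_save_load_round_trip(self, tmp_path, small_epochset):
        small_epochset.save(tmp_path / "epochs")
        back = EpochSet.load(tmp_path / "epochs")
        assert np.array_equal(back.data, small_epochset.data)
        assert list(back.labels) == list(small_epochset.labels)
        assert back.channel_names == small_epochset.channel_names
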