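"""EDA preprocessing, epoch classification, validity and SCR features."""

import numpy as np
import pytest

from conftest import constant_stream
from e4physio import (
    EdaConfig,
    ScrEvent,
    SignalStream,
    SynthSpec,
    apply_validity_rules,
    classify_eda_artifacts,
    detect_scr_peaks,
    epoch_eda_features,
    peaks_per_minute,
    preprocess_eda,
    synth_scr_train,
)
from e4physio.eda_analysis import (
    AlwaysCleanModel,
    LinearModel,
    analyzable_seconds,
)
from e4physio.errors import DownsamplingUnsupported, ModelMismatch, NoAnalyzableData


class TestPreprocess:
    def test_upsamples_4_to_8_hz(self):
        out = preprocess_eda(constant_stream(2.0, duration=60.0, fs=4.0))
        assert out.fs == 8.0
        assert out.n_samples == 480
        assert out.duration == pytest.approx(60.0)

    def test_constant_signal_preserved(self):
        out = preprocess_eda(constant_stream(2.0, duration=30.0))
        assert np.allclose(out.values, 2.0, atol=1e-6)

    def test_near_nyquist_tone_attenuated_20db(self):
        # tremor-band content near the 8 Hz grid's upper range must die in
        # the 1 Hz low-pass; measure attenuation against an FFT oracle
        fs, f_tone = 8.0, 1.9
        n = 1024
        t = np.arange(n) / fs
        x = 2.0 + 0.5 * np.sin(2 * np.pi * f_tone * t)
        stream = SignalStream(start_unix=0, fs=fs, samples=x.reshape(-1, 1))
        out = preprocess_eda(stream)

        def tone_amp(sig):
            spec = np.abs(np.fft.rfft(sig - sig.mean())) / (len(sig) / 2)
            freqs = np.fft.rfftfreq(len(sig), 1 / fs)
            return spec[np.argmin(np.abs(freqs - f_tone))]

        ratio = tone_amp(out.values) / tone_amp(x)
        assert 20 * np.log10(ratio) < -20

    def test_empty_stream_passes_through(self):
        out = preprocess_eda(constant_stream(2.0, duration=0.0))
        assert out.n_samples == 0 and out.fs == 8.0

    def test_downsampling_refused(self):
        with pytest.raises(DownsamplingUnsupported):
            preprocess_eda(constant_stream(2.0, duration=10.0, fs=16.0))


class TestEpochFeatures:
    @pytest.mark.parametrize("duration,expected", [(60.0, 12), (59.0, 11), (4.0, 0)])
    def test_complete_epochs_only(self, duration, expected):
        stream = constant_stream(2.0, duration=duration, fs=8.0)
        assert len(epoch_eda_features(stream)) == expected

    def test_constant_stream_has_zero_transient_features(self):
        feats = epoch_eda_features(constant_stream(2.0, duration=30.0, fs=8.0))
        for f in feats:
            assert f.max_abs_diff1 == 0 and f.max_abs_diff2 == 0
            assert f.w1s_max == 0 and f.whalf_max == 0

    def test_gap_overlapping_epochs_dropped(self):
        stream = constant_stream(2.0, duration=30.0, fs=8.0)
        stream.gaps = [(stream.start_unix + 12.0, stream.start_unix + 13.0)]
        feats = epoch_eda_features(stream)
        # the 30 naive seconds hold 6 epochs; the one spanning the gap drops
        kept = {f.epoch_index for f in feats}
        assert len(feats) == 5 and 2 not in kept


class TestClassifier:
    def test_clean_constant_signal_all_clean(self):
        feats = epoch_eda_features(constant_stream(2.0, duration=60.0, fs=8.0))
        labels = classify_eda_artifacts(feats)
        assert all(l.label == "clean" for l in labels)

    def test_step_discontinuity_flags_artifact(self):
        x = np.full(480, 2.0)
        x[100:] += 5.0  # 5 uS in one sample: 40 uS/s at 8 Hz
        stream = SignalStream(start_unix=0, fs=8.0, samples=x.reshape(-1, 1))
        labels = classify_eda_artifacts(epoch_eda_features(stream))
        assert labels[100 // 40].label == "artifact"

    def test_binary_mode_never_unclear(self):
        rng = np.random.default_rng(0)
        x = 2.0 + np.cumsum(rng.normal(0, 0.3, 480))
        stream = SignalStream(start_unix=0, fs=8.0, samples=x.reshape(-1, 1))
        labels = classify_eda_artifacts(epoch_eda_features(stream))
        assert {l.label for l in labels} <= {"clean", "artifact"}

    def test_labels_invariant_to_constant_offset(self):
        spec = SynthSpec(duration=60, seed=3, scr_events=(ScrEvent(10.0, 0.3),))
        stream, _ = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        shifted = SignalStream(
            start_unix=pre.start_unix, fs=pre.fs, samples=pre.samples + 5.0
        )
        l1 = classify_eda_artifacts(epoch_eda_features(pre))
        l2 = classify_eda_artifacts(epoch_eda_features(shifted))
        assert l1 == l2

    def test_linear_model_and_mismatch(self):
        feats = epoch_eda_features(constant_stream(2.0, duration=10.0, fs=8.0))
        model = LinearModel(weights={"mean": 1.0}, bias=0.0)
        labels = classify_eda_artifacts(feats, model=model)
        assert all(l.label == "artifact" for l in labels)  # mean=2 -> score 2
        bad = LinearModel(weights={"nope": 1.0})
        with pytest.raises(ModelMismatch):
            classify_eda_artifacts(feats, model=bad)

    def test_ternary_unclear_band(self):
        cfg = EdaConfig(classifier_mode="ternary")
        feats = epoch_eda_features(constant_stream(2.0, duration=10.0, fs=8.0), cfg)
        model = LinearModel(weights={}, bias=0.9, margin=0.25)  # score 0.9
        labels = classify_eda_artifacts(feats, cfg, model)
        assert all(l.label == "unclear" for l in labels)


class TestValidity:
    @pytest.mark.parametrize(
        "value,valid", [(0.005, False), (5.0, True), (150.0, False), (0.01, True)]
    )
    def test_range_rules(self, value, valid):
        mask = apply_validity_rules(constant_stream(value, duration=1.0))
        assert bool(mask.all()) is valid


class TestPeakDetection:
    def test_flat_signal_no_peaks(self):
        pre = preprocess_eda(constant_stream(2.0, duration=60.0))
        assert detect_scr_peaks(pre) == []

    def test_single_scr_closed_form(self):
        spec = SynthSpec(
            duration=60.0, eda_noise_sd=0.0,
            scr_events=(ScrEvent(time=20.0, amplitude=0.5, rise=2.0, decay=4.0),),
        )
        stream, truth = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        peaks = detect_scr_peaks(pre)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.amplitude == pytest.approx(0.5, rel=0.05)
        assert p.rise_time == pytest.approx(2.0, abs=0.5)
        assert p.apex_time == pytest.approx(22.0, abs=0.5)
        # linear rise of 0.5 uS over 2 s: slope 0.25 uS/s up to filter shaping
        assert p.max_derivative == pytest.approx(0.25, rel=0.2)
        assert p.max_derivative > 0
        assert p.eda_at_start == pytest.approx(2.0, abs=0.01)
        # decay constant 4 s: half recovery ~ ln(2) x 4 = 2.8 s after apex
        assert p.decay_time == pytest.approx(4 * np.log(2), abs=0.5)
        assert p.width is not None and p.auc is not None and p.auc > 0

    def test_amplitude_threshold_straddled(self):
        spec = SynthSpec(
            duration=120.0, eda_noise_sd=0.0,
            scr_events=(
                ScrEvent(time=20.0, amplitude=0.004),
                ScrEvent(time=80.0, amplitude=0.01),
            ),
        )
        stream, _ = synth_scr_train(spec)
        peaks = detect_scr_peaks(preprocess_eda(stream))
        assert len(peaks) == 1
        assert peaks[0].apex_time == pytest.approx(82.0, abs=1.0)

    def test_every_peak_clears_threshold_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        cfg = EdaConfig()
        for trial in range(5):
            k = int(rng.integers(1, 6))
            events = tuple(
                ScrEvent(time=30.0 + 25.0 * i, amplitude=float(rng.uniform(0.01, 1.0)))
                for i in range(k)
            )
            spec = SynthSpec(duration=30.0 + 25.0 * k + 30, seed=trial,
                             scr_events=events)
            stream, _ = synth_scr_train(spec)
            for p in detect_scr_peaks(preprocess_eda(stream), cfg):
                assert p.amplitude >= cfg.peak_amplitude_threshold
                assert p.apex_time > p.start_time
                assert p.rise_time == pytest.approx(p.apex_time - p.start_time)
                assert p.max_derivative > 0

    def test_offset_shifts_only_eda_at_start(self):
        spec = SynthSpec(duration=60.0, eda_noise_sd=0.0,
                         scr_events=(ScrEvent(20.0, 0.5),))
        stream, _ = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        shifted = SignalStream(start_unix=pre.start_unix, fs=pre.fs,
                               samples=pre.samples + 3.0)
        p1 = detect_scr_peaks(pre)[0]
        p2 = detect_scr_peaks(shifted)[0]
        assert p2.eda_at_start == pytest.approx(p1.eda_at_start + 3.0, abs=1e-9)
        assert p2.amplitude == pytest.approx(p1.amplitude, abs=1e-9)
        assert p2.apex_time == p1.apex_time

    def test_peaks_in_artifact_epochs_excluded(self):
        spec = SynthSpec(duration=60.0, eda_noise_sd=0.0,
                         scr_events=(ScrEvent(20.0, 0.5),))
        stream, _ = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        feats = epoch_eda_features(pre)
        from e4physio.eda_analysis import ArtifactLabel

        labels = [
            ArtifactLabel(f.epoch_index, "artifact" if f.epoch_index in (4, 5) else "clean")
            for f in feats
        ]
        assert detect_scr_peaks(pre, labels=labels) == []

    def test_always_clean_model_equals_unmasked_detection(self):
        spec = SynthSpec(duration=120.0, seed=2,
                         scr_events=(ScrEvent(30.0, 0.3), ScrEvent(80.0, 0.2)))
        stream, _ = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        feats = epoch_eda_features(pre)
        labels = classify_eda_artifacts(feats, model=AlwaysCleanModel())
        assert detect_scr_peaks(pre, labels=labels) == detect_scr_peaks(pre)

    def test_invalid_samples_exclude_peaks(self):
        spec = SynthSpec(duration=60.0, eda_noise_sd=0.0,
                         scr_events=(ScrEvent(20.0, 0.5),))
        stream, _ = synth_scr_train(spec)
        pre = preprocess_eda(stream)
        validity = np.zeros(pre.n_samples, dtype=bool)
        assert detect_scr_peaks(pre, validity=validity) == []


class TestPeaksPerMinute:
    @pytest.mark.parametrize("n,dur,rate", [(6, 180.0, 2.0), (0, 60.0, 0.0), (10, 600.0, 1.0)])
    def test_rate_arithmetic(self, n, dur, rate):
        peaks = [object()] * n
        assert peaks_per_minute(peaks, dur) == pytest.approx(rate)

    def test_zero_duration_errors(self):
        with pytest.raises(NoAnalyzableData):
            peaks_per_minute([], 0.0)

    def test_analyzable_seconds_subtracts_artifact_epochs(self):
        from e4physio.eda_analysis import ArtifactLabel

        pre = preprocess_eda(constant_stream(2.0, duration=60.0))
        labels = [ArtifactLabel(0, "artifact"), ArtifactLabel(1, "clean")]
        assert analyzable_seconds(pre, labels=labels) == pytest.approx(55.0)
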