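"""Generator tests: paradigm timeline, AM-FM construction, injected effects."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from emovmd.bands import band_lookup
from emovmd.errors import ConfigurationError
from emovmd.features import WindowSpec, band_power, slide_windows
from emovmd.recording import RELAX, label_segments
from emovmd.synth import (
    ClassEffectSpec,
    ComponentSpec,
    ParadigmSpec,
    build_timeline,
    default_effects,
    generate_am_fm,
    generate_recording,
    null_effects,
)


class TestTimeline:
    def test_first_emotion_block_position(self):
        labels = build_timeline(ParadigmSpec())
        # 10 s initial relax, then 3 x 5 s happy images: samples [1280, 3200)
        assert set(labels[:1280]) == {RELAX}
        assert set(labels[1280:3200]) == {"happy"}
        assert labels[3200] == RELAX

    def test_single_phase_length(self):
        spec = ParadigmSpec(n_phases=1)
        labels = build_timeline(spec)
        assert labels.size == 65 * 128  # 10 + 15 + 5 + 15 + 5 + 15 seconds

    def test_label_durations_match_paradigm_arithmetic(self):
        spec = ParadigmSpec(n_phases=3)
        labels = build_timeline(spec)
        fs = spec.fs
        for emotion in spec.emotion_order:
            expected = spec.n_phases * spec.emotion_block_s * fs
            assert (labels == emotion).sum() == expected
        relax_expected = spec.n_phases * (
            spec.relax_initial_s + 2 * spec.inter_emotion_relax_s
        ) * fs
        assert (labels == RELAX).sum() == relax_expected

    def test_phase_structure_repeats(self):
        labels = build_timeline(ParadigmSpec(n_phases=2))
        segs = [lab for _s, _e, lab in label_segments(labels)]
        one_phase = ["relax", "happy", "relax", "sad", "relax", "fear"]
        assert segs == one_phase * 2

    def test_empty_emotion_order_rejected(self):
        with pytest.raises(ConfigurationError):
            ParadigmSpec(emotion_order=())

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            ParadigmSpec(image_duration_s=0)


class TestAmFm:
    def test_pure_tone_mean_square(self):
        x = generate_am_fm(lambda t: np.ones_like(t), lambda t: 2 * np.pi * 10 * t, 128, 128)
        assert np.mean(x**2) == pytest.approx(0.5, abs=1e-12)

    def test_zero_amplitude_gives_zero_signal(self):
        x = generate_am_fm(lambda t: np.zeros_like(t), lambda t: 2 * np.pi * 10 * t, 128, 256)
        assert np.all(x == 0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_am_fm(lambda t: -np.ones_like(t), lambda t: t, 128, 64)

    def test_chirp_instantaneous_frequency_tracks_phase(self):
        # linear chirp 4 -> 8 Hz over 4 s: the analytic-signal frequency of
        # the output must match the finite difference of the specified phase
        fs, dur = 128.0, 4.0
        n = int(fs * dur)

        def phase(t):
            return 2 * np.pi * (4 * t + 0.5 * t**2)  # f(t) = 4 + t

        x = generate_am_fm(lambda t: np.ones_like(t), phase, fs, n)
        analytic = sps.hilbert(x)
        inst_freq = np.diff(np.unwrap(np.angle(analytic))) * fs / (2 * np.pi)
        t = np.arange(n) / fs
        expected = 4 + t[1:]
        margin = slice(n // 8, -n // 8)  # away from edges
        assert np.max(np.abs(inst_freq[margin] - expected[margin])) < 0.2


class TestGenerateRecording:
    def test_fixed_seed_bit_identical(self):
        spec = ParadigmSpec(n_channels=4, channel_names=["Fp1", "Fp2", "Cz", "O1"])
        rec1, truth1 = generate_recording(spec, seed=5)
        rec2, truth2 = generate_recording(spec, seed=5)
        assert np.array_equal(rec1.data, rec2.data)
        assert np.array_equal(truth1.clean, truth2.clean)
        assert np.array_equal(truth1.blink_onsets, truth2.blink_onsets)

    def test_null_effects_have_no_class_band_power_difference(self):
        # pink noise only: delta power indistinguishable between classes
        spec = ParadigmSpec(n_phases=4, n_channels=2, channel_names=["Fp1", "Fp2"])
        rec, _ = generate_recording(spec, null_effects(), seed=17)
        delta = band_lookup("Delta")
        powers = {"happy": [], "sad": []}
        for s, e in slide_windows(rec.n_samples, rec.fs, WindowSpec(1.0, 0.5)):
            lab = str(rec.labels[s])
            if lab in powers and np.all(rec.labels[s:e] == lab):
                powers[lab].append(band_power(rec.data[0, s:e], rec.fs, delta))
        assert len(powers["happy"]) + len(powers["sad"]) >= 200
        _stat, p = stats.ttest_ind(powers["happy"], powers["sad"])
        assert p > 0.01

    def test_planted_amplitude_ratio_reflected_in_delta_power(self):
        # sad carries a 2 Hz component at amplitude 3 vs 1 elsewhere: the
        # delta power ratio should be ~9 (sinusoid power scales as A^2),
        # within [6, 12] allowing a small noise contribution
        comps = {
            cls: {"Delta": ComponentSpec("Delta", 2.0, 3.0 if cls == "sad" else 1.0)}
            for cls in ("happy", "sad", "fear")
        }
        effects = ClassEffectSpec(
            components=comps,
            noise_pink_scale=0.1,
            n_shared_noise_sources=0,
            drift=dataclasses.replace(default_effects().drift, amplitude=0.0),
            blink=dataclasses.replace(default_effects().blink, rate_per_min=0.0),
        )
        spec = ParadigmSpec(n_channels=2, channel_names=["Fp1", "Fp2"])
        rec, _ = generate_recording(spec, effects, seed=3)
        delta = band_lookup("Delta")
        by_class = {}
        for s, e, lab in label_segments(rec.labels):
            if lab in ("sad", "happy"):
                # average power over channels: topographies are unit mean-square
                p = np.mean(
                    [band_power(rec.data[c, s:e], rec.fs, delta) for c in range(2)]
                )
                by_class.setdefault(lab, []).append(p)
        ratio = np.mean(by_class["sad"]) / np.mean(by_class["happy"])
        assert 6 <= ratio <= 12

    def test_injected_carriers_peak_inside_their_bands(self, default_session):
        rec, truth = default_session
        for cls, bandmap in truth.carrier_hz.items():
            mask = rec.labels == cls
            freqs, psd = sps.welch(rec.data[:, mask], rec.fs, nperseg=1024, axis=-1)
            mean_psd = psd.mean(axis=0)  # channel-average: topographies vary
            for band_name, carrier in bandmap.items():
                band = band_lookup(band_name)
                in_band = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
                peak = freqs[in_band][np.argmax(mean_psd[in_band])]
                assert abs(peak - carrier) < 0.5

    def test_blink_onsets_within_recording(self, default_session):
        rec, truth = default_session
        assert truth.blink_onsets.size > 0
        assert truth.blink_onsets.min() >= 0
        assert truth.blink_onsets.max() < rec.n_samples
        assert truth.clean.shape == rec.data.shape

    def test_blinks_raise_frontal_amplitude(self, default_session):
        rec, truth = default_session
        fp1 = rec.channel_names.index("Fp1")
        artifact = rec.data[fp1] - truth.clean[fp1]
        assert np.max(np.abs(artifact)) > 50  # blink bumps dominate drift

    def test_discriminative_feature_identity(self, default_session):
        _rec, truth = default_session
        assert truth.discriminative_band == "Delta"
        assert truth.discriminative_rank == 0  # lowest carrier frequency
        assert truth.discriminative_column(mode_order="ascending") == "IMF1_Delta"
        assert truth.discriminative_column(mode_order="descending") == "IMF5_Delta"

    def test_component_outside_band_rejected(self):
        with pytest.raises(ConfigurationError):
            ComponentSpec("Delta", 6.0, 1.0)  # 6 Hz is not a Delta frequency
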