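import numpy as np
import pytest

import skitech as sk
from skitech.io import LabelTrack, Recording, ValidationError, all_channels
from skitech.segmentation import (
    DEFAULT_REFERENCE_CHANNEL,
    CycleSet,
    FilterSpec,
    NoCyclesError,
    build_cycle_set,
    detect_cycle_peaks,
    excise_noise,
    lowpass_filter,
    resample_cycle,
    segment_recording,
)
from skitech import synthetic as syn

FS = 240.0


def lockin_amplitude(y, f, fs):
    """Amplitude of the f-Hz component, interior window, integer periods."""
    n = len(y)
    margin = int(10 * fs)  # past the zero-phase filter's edge transients
    seg = y[margin:n - margin]
    periods = int(len(seg) * f / fs)
    seg = seg[:max(int(round(periods * fs / f)), 1)]
    t = np.arange(len(seg)) / fs
    z = seg * np.exp(-2j * np.pi * f * t)
    return 2 * abs(z.mean())


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        x = np.full(2000, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, FilterSpec(), FS), x, atol=1e-9)

    @pytest.mark.parametrize("ratio,expected", [
        (1.0, 0.5),            # two-pass gain at the cutoff is |H|^2 = 1/2
        (10.0, 1.0 / (1 + 10 ** 8)),
        (0.1, 1.0 / (1 + 0.1 ** 8)),
    ])
    def test_matches_closed_form_response(self, ratio, expected):
        spec = FilterSpec()
        fc = spec.cutoff_hz(FS)
        f = ratio * fc
        t = np.arange(int(120 * FS)) / FS
        y = lowpass_filter(np.sin(2 * np.pi * f * t), spec, FS)
        assert lockin_amplitude(y, f, FS) == pytest.approx(expected, rel=0.05)

    def test_high_frequency_component_removed(self):
        # 0.2 Hz passes nearly unchanged, 60 Hz is crushed below 1e-3
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 60.0 * t)
        y = lowpass_filter(x, FilterSpec(), FS)
        assert lockin_amplitude(y, 60.0, FS) < 1e-3
        assert lockin_amplitude(y, 0.2, FS) > 0.9

    def test_cutoff_modes(self):
        assert FilterSpec().cutoff_hz(FS) == pytest.approx(0.84)
        assert FilterSpec(cutoff=0.84, cutoff_mode="absolute_hz").cutoff_hz(FS) == 0.84
        with pytest.raises(ValidationError):
            FilterSpec(cutoff=1.5)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            lowpass_filter(np.zeros(10), FilterSpec(), FS)


def reference_recording(x, n_extra_channels=0, course="flat"):
    channels = [DEFAULT_REFERENCE_CHANNEL] + [f"pelvis_gyr_{a}" for a in "xyz"][:n_extra_channels]
    values = np.column_stack([x] + [np.zeros_like(x)] * n_extra_channels)
    return Recording("S1", course, values, channels)


class TestPeakDetection:
    def test_sinusoid_peak_spacing(self):
        # peaks mid-period; the first/last sit in the zero-phase filter's
        # boundary-transient zone, so the spacing oracle uses interior peaks
        t = np.arange(10 * 333)
        x = np.cos(2 * np.pi * (t - 166) / 333)
        peaks = detect_cycle_peaks(reference_recording(x))
        assert len(peaks) == 10
        true_peaks = 166 + 333 * np.arange(10)
        assert np.all(np.abs(peaks[1:-1] - true_peaks[1:-1]) <= 1)
        assert np.all(np.abs(np.diff(peaks[1:-1]) - 333) <= 1)

    def test_constant_signal_has_no_cycles(self):
        with pytest.raises(NoCyclesError):
            detect_cycle_peaks(reference_recording(np.ones(2000)))

    def test_noise_robustness(self):
        t = np.arange(3330)
        clean = np.cos(2 * np.pi * (t - 166) / 333)
        noisy = clean + np.random.default_rng(5).normal(0, 0.1, len(t))
        p_clean = detect_cycle_peaks(reference_recording(clean), min_prominence_frac=0.3)
        p_noisy = detect_cycle_peaks(reference_recording(noisy), min_prominence_frac=0.3)
        assert len(p_noisy) == len(p_clean)

    def test_min_period_suppresses_harmonics(self):
        t = np.arange(3330)
        x = np.cos(2 * np.pi * (t - 166) / 333)
        # absolute_hz mode with a generous cutoff keeps the 2nd harmonic in;
        # the distance criterion still yields one peak per cycle
        x2 = x + 0.5 * np.cos(4 * np.pi * (t - 166) / 333)
        peaks = detect_cycle_peaks(reference_recording(x2), min_period_frames=166)
        assert len(peaks) == 10


class TestExciseNoise:
    def test_single_technique_between_noise(self):
        rec = reference_recording(np.zeros(700))
        track = LabelTrack([(0, 100, 0), (100, 600, 1), (600, 700, 9)])
        segs = excise_noise(rec, track)
        assert len(segs) == 1
        seg, lab = segs[0]
        assert (seg.n_frames, lab) == (500, 1)

    def test_turn_splits_segments(self):
        rec = reference_recording(np.zeros(500))
        track = LabelTrack([(0, 200, 1), (200, 300, "TURN"), (300, 500, 1)])
        segs = excise_noise(rec, track)
        assert [(s.n_frames, lab) for s, lab in segs] == [(200, 1), (200, 1)]

    def test_only_noise_yields_nothing(self):
        rec = reference_recording(np.zeros(100))
        assert excise_noise(rec, LabelTrack([(0, 100, 0)])) == []

    def test_partition_of_frames(self, small_recording):
        rec, track, _ = small_recording
        segs = excise_noise(rec, track)
        kept = sum(s.n_frames for s, _ in segs)
        technique_frames = sum(e - s for s, e, lab in track.intervals if lab in range(1, 9))
        assert kept == technique_frames
        assert kept < rec.n_frames  # noise really is excised


class TestResampling:
    def test_identity_at_target_length(self):
        t = np.arange(333)
        x = np.column_stack([np.cos(2 * np.pi * t / 333), np.sin(6 * np.pi * t / 333)])
        out = resample_cycle(x, 333)
        assert out.shape == (333, 2)
        assert np.max(np.abs(out - x)) < 1e-6

    def test_downsample_cosine(self):
        n = 666
        x = np.cos(2 * np.pi * np.arange(n) / n)[:, None]
        out = resample_cycle(x, 333)
        ref = np.cos(2 * np.pi * np.arange(333) / 333)
        assert out.shape == (333, 1)
        rms = np.sqrt(np.mean((out[:, 0] - ref) ** 2))
        assert rms < 0.01

    def test_upsample_preserves_constant(self):
        out = resample_cycle(np.full((100, 3), 2.5), 333)
        assert out.shape == (333, 3)
        assert np.max(np.abs(out - 2.5)) < 0.025  # <1% of level

    @pytest.mark.parametrize("n", [50, 100, 333, 500, 666])
    def test_scale_equivariance(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=(n, 2))
        np.testing.assert_allclose(resample_cycle(3.5 * x), 3.5 * resample_cycle(x),
                                   rtol=1e-10, atol=1e-12)

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ValidationError):
            resample_cycle(np.zeros((1, 2)))


class TestBuildCycleSet:
    def test_ten_period_segment_gives_nine_cycles(self):
        t = np.arange(3330)
        x = np.cos(2 * np.pi * (t - 166) / 333)
        rec = reference_recording(x)
        cs = build_cycle_set([(rec, 1)])
        assert cs.n_cycles == 9
        assert set(cs.labels) == {1}
        assert cs.cycles.shape == (9, 333, 1)

    def test_empty_segment_list(self):
        cs = build_cycle_set([])
        assert cs.n_cycles == 0

    def test_short_segment_skipped_with_warning(self):
        rec = reference_recording(np.cos(2 * np.pi * np.arange(400) / 333))
        with pytest.warns(UserWarning, match="skipping"):
            cs = build_cycle_set([(rec, 1)])
        assert cs.n_cycles == 0

    def test_raw_values_survive_filtering(self):
        """The filter only localizes peaks; a high-frequency marker injected
        into a non-reference channel must persist into the cycle tensor."""
        t = np.arange(3330)
        ref = np.cos(2 * np.pi * (t - 166) / 333)
        marker = 0.8 * np.cos(2 * np.pi * 30.0 * t / FS)  # 30 Hz burst
        rec = Recording("S1", "flat", np.column_stack([ref, marker]),
                        [DEFAULT_REFERENCE_CHANNEL, "pelvis_gyr_x"])
        cs = build_cycle_set([(rec, 1)])
        stored = cs.cycles[0, :, 1].astype(np.float64)
        # 30 Hz would be annihilated by the 0.84 Hz low-pass; raw storage
        # keeps its frame-to-frame variation intact
        assert np.std(np.diff(stored)) > 0.2

    def test_shape_under_presets(self, default_cycles):
        assert default_cycles.cycles.shape[1:] == (333, 51)
        sb = default_cycles.select_channels(sk.PRESETS["sports_biomechanics"])
        assert sb.cycles.shape[1:] == (333, 15)
        np.testing.assert_array_equal(sb.labels, default_cycles.labels)

    def test_save_load_round_trip(self, small_cycles, tmp_path):
        small_cycles.save(tmp_path / "cs")
        back = CycleSet.load(tmp_path / "cs")
        np.testing.assert_array_equal(back.cycles, small_cycles.cycles)
        np.testing.assert_array_equal(back.labels, small_cycles.labels)
        assert back.channels == small_cycles.channels
        assert back.provenance.equals(small_cycles.provenance.astype(back.provenance.dtypes))


class TestBoundaryRecovery:
    def test_zero_noise_boundaries_within_two_frames(self):
        profile = syn.SubjectProfile("S1", {tr: 1.0 for tr in sk.TRACKERS},
                                     tempo_mean=333, tempo_jitter=0.0, noise_sigma=0.0)
        recipe = syn.FileRecipe("S1", "flat", "classical", ((1, 12),))
        rec, track, truth = syn.generate_recording(recipe, syn.default_templates(),
                                                   profile, seed=4)
        (seg, lab), = excise_noise(rec, track)
        offset = track.technique_intervals()[0][0]
        peaks = detect_cycle_peaks(seg) + offset
        for p in peaks:
            assert np.min(np.abs(truth - p)) <= 2

    def test_default_noise_boundaries_within_three_percent(self, small_recording):
        rec, track, truth = small_recording
        hits = total = 0
        for (s, e, lab), (seg, _) in zip(track.technique_intervals(), excise_noise(rec, track)):
            peaks = detect_cycle_peaks(seg) + s
            cycle_len = np.median(np.diff(peaks))
            for p in peaks:
                total += 1
                hits += np.min(np.abs(truth - p)) <= 0.03 * cycle_len
        assert total >= 16
        assert hits / total >= 0.95
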