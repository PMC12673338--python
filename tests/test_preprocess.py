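import numpy as np
import pytest

from fnirs_decnef import (
    EffectMap,
    Montage,
    NoiseSpec,
    concentrations_to_intensity,
    inject_motion,
    make_design,
    simulate_concentrations,
)
from fnirs_decnef.core import ConcentrationSeries, OpticalDensitySeries, RawRecording
from fnirs_decnef.preprocess import (
    ArtifactMask,
    PreprocessConfig,
    bandpass,
    block_average,
    detect_motion,
    difference_wave,
    intensity_to_od,
    od_to_concentration,
    preprocess_raw,
    segment_blocks,
    spline_correct,
)


def _constant_raw(montage, value=1.0, n=512):
    intensity = np.full(
        (montage.n_channels, montage.n_wavelengths, n), float(value)
    )
    return RawRecording(intensity=intensity, montage=montage)


class TestIntensityToOd:
    def test_constant_intensity_gives_zero_od(self, small_montage):
        od = intensity_to_od(_constant_raw(small_montage))
        assert np.allclose(od.od, 0.0)

    def test_e_fold_drop_gives_unit_od(self, small_montage):
        raw = _constant_raw(small_montage, 1.0, n=1000)
        raw.intensity[0, 0, 500] = np.exp(-1.0)
        od = intensity_to_od(raw)
        # reference is the temporal mean, slightly below 1 due to the dip
        ref = raw.intensity[0, 0].mean()
        assert od.od[0, 0, 500] == pytest.approx(1.0 + np.log(ref), abs=1e-9)

    def test_invariant_to_baseline_intensity_scale(self, small_montage):
        rng = np.random.default_rng(0)
        base = _constant_raw(small_montage, 1.0, n=256)
        base.intensity *= np.exp(0.01 * rng.standard_normal(base.intensity.shape))
        doubled = RawRecording(2.0 * base.intensity, small_montage)
        assert np.allclose(
            intensity_to_od(base).od, intensity_to_od(doubled).od, atol=1e-12
        )

    def test_nonpositive_intensity_names_location(self, small_montage):
        raw = _constant_raw(small_montage)
        raw.intensity[2, 1, 17] = 0.0
        with pytest.raises(ValueError, match="channel 2.*sample 17"):
            intensity_to_od(raw)

    def test_od_is_mean_referenced(self, small_montage):
        rng = np.random.default_rng(1)
        raw = _constant_raw(small_montage, 1.0, n=256)
        raw.intensity *= np.exp(0.01 * rng.standard_normal(raw.intensity.shape))
        od = intensity_to_od(raw)
        # -ln(I/mean) has approximately zero mean for small fluctuations
        assert np.abs(od.od.mean(axis=2)).max() < 1e-3


class TestBandpass:
    fs = 25.6

    def _sine(self, f_hz, dur=300.0):
        t = np.arange(0, dur, 1 / self.fs)
        return np.sin(2 * np.pi * f_hz * t)

    def test_passband_amplitude_preserved(self):
        x = self._sine(0.05)
        y = bandpass(x, 0.01, 0.2, self.fs)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.abs(y[mid]).max() / np.abs(x[mid]).max() >= 0.95

    def test_cardiac_band_attenuated(self):
        x = self._sine(1.2)
        y = bandpass(x, 0.01, 0.2, self.fs)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.abs(y[mid]).max() / np.abs(x[mid]).max() <= 0.1

    def test_zero_input_zero_output(self):
        y = bandpass(np.zeros(1024), 0.01, 1.0, self.fs)
        assert np.allclose(y, 0.0)

    def test_zero_phase(self):
        """Forward-backward filtering must not shift the passband peak."""
        t = np.arange(0, 400, 1 / self.fs)
        x = np.exp(-((t - 200) ** 2) / (2 * 15**2))
        y = bandpass(x, 0.001 + 1e-6, 1.0, self.fs)
        assert abs(np.argmax(y) - np.argmax(x)) <= 2

    @pytest.mark.parametrize("band", [(0.0, 1.0), (0.2, 0.01), (0.01, 13.0)])
    def test_invalid_bands_rejected(self, band):
        with pytest.raises(ValueError):
            bandpass(np.zeros(256), band[0], band[1], self.fs)


class TestDetectMotion:
    def _noise_od(self, montage, seed=0, n=4096, sd=1e-3):
        rng = np.random.default_rng(seed)
        od = sd * rng.standard_normal((montage.n_channels, montage.n_wavelengths, n))
        return OpticalDensitySeries(od=od, montage=montage)

    def test_clean_noise_unflagged(self, small_montage):
        mask = detect_motion(self._noise_od(small_montage))
        assert not mask.any_flagged

    def test_large_spike_flagged_with_window_dilation(self, small_montage):
        od = self._noise_od(small_montage, seed=1)
        od.od[1, :, 2000:2010] += 0.5
        mask = detect_motion(od)
        assert mask.mask[1, 2000:2010].all()
        assert not mask.mask[0].any()

    def test_infinite_thresholds_flag_nothing(self, small_montage):
        od = self._noise_od(small_montage, seed=2)
        od.od[0, :, 100] += 10.0
        mask = detect_motion(od, sd_thresh=np.inf, amp_thresh=np.inf)
        assert not mask.any_flagged

    def test_short_window_rejected(self, small_montage):
        with pytest.raises(ValueError, match="window"):
            detect_motion(self._noise_od(small_montage), t_window_s=0.01)

    def test_sensitivity_one_on_injected_spikes(self, default_montage):
        """Every injected 10x-threshold spike is recovered; false flags
        stay under 5% of samples."""
        sched = make_design(4, seed=0)
        conc = simulate_concentrations(
            default_montage,
            sched,
            EffectMap.null(default_montage.n_channels),
            NoiseSpec(),
            seed=0,
        )
        raw = concentrations_to_intensity(conc, default_montage)
        od_clean = intensity_to_od(raw)
        diff_sd = np.median(np.diff(od_clean.od, axis=-1).std(axis=-1))
        corrupt, truth = inject_motion(
            raw, n_events=6, magnitude_od=10 * 60 * diff_sd, seed=5
        )
        mask = detect_motion(intensity_to_od(corrupt))
        n_events_found = sum(
            any(
                mask.mask[ch, s:e].any()
                for s, e in ArtifactMask(truth).intervals(ch)
            )
            for ch in range(default_montage.n_channels)
            if truth[ch].any()
        )
        n_events_true = sum(
            len(ArtifactMask(truth).intervals(ch))
            for ch in range(default_montage.n_channels)
        )
        sensitivity = (
            sum(
                mask.mask[ch, s:e].any()
                for ch in range(default_montage.n_channels)
                for s, e in ArtifactMask(truth).intervals(ch)
            )
            / n_events_true
        )
        assert sensitivity == 1.0
        false_rate = (mask.mask & ~truth).mean()
        assert false_rate < 0.05


class TestSplineCorrect:
    def _od(self, montage, x):
        od = np.broadcast_to(
            x, (montage.n_channels, montage.n_wavelengths, len(x))
        ).copy()
        return OpticalDensitySeries(od=od, montage=montage)

    def test_empty_mask_is_identity(self, small_montage):
        rng = np.random.default_rng(0)
        od = self._od(small_montage, rng.standard_normal(512))
        mask = ArtifactMask(np.zeros((small_montage.n_channels, 512), dtype=bool))
        out = spline_correct(od, mask)
        assert np.array_equal(out.od, od.od)

    def test_step_artifact_removed(self, small_montage):
        n = 2048
        rng = np.random.default_rng(1)
        x = 0.001 * rng.standard_normal(n)
        h = 1.0
        x[1000:1100] += h  # flagged step-and-return excursion
        od = self._od(small_montage, x)
        mask_arr = np.zeros((small_montage.n_channels, n), dtype=bool)
        mask_arr[:, 990:1110] = True
        out = spline_correct(od, ArtifactMask(mask_arr))
        corrected = out.od[0, 0]
        # residual discontinuities at the interval edges are < 5% of h
        for edge in (990, 1110):
            jump = abs(
                corrected[edge - 5 : edge].mean() - corrected[edge : edge + 5].mean()
            )
            assert jump < 0.05 * h

    def test_variance_reduced_within_flagged_interval(self, small_montage):
        n = 2048
        rng = np.random.default_rng(2)
        x = 0.001 * rng.standard_normal(n)
        x[500:700] += np.linspace(0, 1.0, 200) ** 2
        od = self._od(small_montage, x)
        mask_arr = np.zeros((small_montage.n_channels, n), dtype=bool)
        mask_arr[:, 480:720] = True
        out = spline_correct(od, ArtifactMask(mask_arr))
        assert out.od[0, 0, 480:720].var() <= od.od[0, 0, 480:720].var()

    def test_unflagged_samples_far_from_artifact_unchanged_in_shape(
        self, small_montage
    ):
        n = 1024
        rng = np.random.default_rng(3)
        x = 0.001 * rng.standard_normal(n)
        x[400:500] += 0.8
        od = self._od(small_montage, x)
        mask_arr = np.zeros((small_montage.n_channels, n), dtype=bool)
        mask_arr[:, 390:510] = True
        out = spline_correct(od, ArtifactMask(mask_arr))
        # segments outside the artifact keep their shape (up to a rigid shift)
        before = out.od[0, 0, :390] - od.od[0, 0, :390]
        after = out.od[0, 0, 510:] - od.od[0, 0, 510:]
        assert np.ptp(before) < 1e-12
        assert np.ptp(after) < 1e-12

    def test_fully_masked_channel_rejected(self, small_montage):
        od = self._od(small_montage, np.zeros(256))
        mask = ArtifactMask(np.ones((small_montage.n_channels, 256), dtype=bool))
        with pytest.raises(ValueError, match="entire"):
            spline_correct(od, mask)


class TestOdToConcentration:
    def test_zero_od_gives_zero_concentration(self, small_montage):
        od = OpticalDensitySeries(
            od=np.zeros((small_montage.n_channels, 3, 64)), montage=small_montage
        )
        conc = od_to_concentration(od)
        assert np.allclose(conc.hbo, 0)
        assert np.allclose(conc.hbr, 0)

    def test_forward_round_trip_exact(self):
        """OD built from (ΔHbO, ΔHbR) = (1.0, -0.3) uM must invert to the
        same concentrations to 1e-9."""
        m = Montage(n_channels=2)
        eps = m.extinction() * 1e-6
        path = m.separation_cm * 6.0
        c = np.array([1.0, -0.3])
        d_od = (eps @ c) * path
        od_arr = np.tile(d_od[None, :, None], (2, 1, 64))
        conc = od_to_concentration(OpticalDensitySeries(od=od_arr, montage=m))
        assert np.allclose(conc.hbo, 1.0, atol=1e-9)
        assert np.allclose(conc.hbr, -0.3, atol=1e-9)

    def test_two_wavelength_solution_close_to_three(self):
        m3 = Montage(n_channels=1)
        m2 = Montage(n_channels=1, wavelengths_nm=(780.0, 830.0))
        eps = m3.extinction() * 1e-6
        d_od3 = (eps @ np.array([1.0, -0.3])) * (m3.separation_cm * 6.0)
        od3 = OpticalDensitySeries(
            od=np.tile(d_od3[None, :, None], (1, 1, 8)), montage=m3
        )
        od2 = OpticalDensitySeries(od=od3.od[:, [0, 2], :], montage=m2)
        c3 = od_to_concentration(od3)
        c2 = od_to_concentration(od2, dpf=(6.0, 6.0))
        assert np.abs(c2.hbo - c3.hbo).max() / np.abs(c3.hbo).max() < 0.05
        assert np.abs(c2.hbr - c3.hbr).max() / np.abs(c3.hbr).max() < 0.05

    def test_single_wavelength_rejected(self):
        with pytest.raises(ValueError):
            Montage(n_channels=1, wavelengths_nm=(805.0,))


class TestSegmentAndAverage:
    def test_sixty_block_schedule_gives_sixty_segments(self, default_montage):
        sched = make_design(30, seed=1)
        conc = simulate_concentrations(
            default_montage,
            sched,
            EffectMap.null(default_montage.n_channels),
            NoiseSpec.silent(),
        )
        segs = segment_blocks(conc, sched)
        assert segs.shape[0] == 60

    def test_segment_equals_direct_slice(self, small_montage):
        sched = make_design(2, seed=2)
        conc = simulate_concentrations(
            small_montage,
            sched,
            EffectMap.conflict(small_montage.n_channels, n_effect_channels=2),
            NoiseSpec(),
            seed=3,
        )
        segs = segment_blocks(conc, sched, window_s=(-5, 25))
        fs = conc.sampling_rate_hz
        b = 2
        i0 = int(round((sched.block_onsets_s[b] - 5) * fs))
        n_win = int(round(30 * fs)) + 1
        assert np.array_equal(segs[b, :, 0, :], conc.hbo[:, i0 : i0 + n_win])
        assert np.array_equal(segs[b, :, 1, :], conc.hbr[:, i0 : i0 + n_win])

    def test_zero_width_window_single_sample(self, small_montage):
        sched = make_design(1, seed=0)
        conc = simulate_concentrations(
            small_montage,
            sched,
            EffectMap.null(small_montage.n_channels),
            NoiseSpec.silent(),
        )
        segs = segment_blocks(conc, sched, window_s=(0, 0))
        assert segs.shape[-1] == 1

    def test_out_of_bounds_block_names_block(self, small_montage):
        sched = make_design(1, seed=0, start_s=2.0)
        conc = simulate_concentrations(
            small_montage,
            sched,
            EffectMap.null(small_montage.n_channels),
            NoiseSpec.silent(),
        )
        with pytest.raises(ValueError, match="block 0"):
            segment_blocks(conc, sched, window_s=(-5, 25))

    def test_identical_segments_average_with_zero_sem(self):
        segs = np.tile(np.arange(10.0)[None, None, None, :], (5, 2, 2, 1))
        hrfs = block_average(
            segs,
            ["congruent"] * 5,
            window_s=(0, 9),
            sampling_rate_hz=1.0,
            baseline_correct=False,
        )
        assert np.allclose(hrfs.mean["congruent"][0, 0], np.arange(10.0))
        assert np.allclose(hrfs.sem["congruent"], 0.0)

    def test_two_segment_average_is_midpoint(self):
        a = np.zeros((1, 1, 8))
        b = np.ones((1, 1, 8))
        segs = np.stack([a, b])
        hrfs = block_average(
            segs,
            ["incongruent", "incongruent"],
            window_s=(0, 7),
            sampling_rate_hz=1.0,
            baseline_correct=False,
        )
        assert np.allclose(hrfs.mean["incongruent"], 0.5)

    def test_noisy_average_within_3_sem_of_template(self, rng):
        template = np.sin(np.linspace(0, np.pi, 50))
        segs = template[None, None, None, :] + 0.3 * rng.standard_normal(
            (30, 1, 1, 50)
        )
        hrfs = block_average(
            segs,
            ["congruent"] * 30,
            window_s=(0, 49),
            sampling_rate_hz=1.0,
            baseline_correct=False,
        )
        dev = np.abs(hrfs.mean["congruent"][0, 0] - template)
        assert np.all(dev <= 3 * hrfs.sem["congruent"][0, 0] + 1e-12)

    def test_baseline_correction_zeroes_prestimulus_mean(self, small_montage):
        sched = make_design(3, seed=4)
        conc = simulate_concentrations(
            small_montage,
            sched,
            EffectMap.conflict(small_montage.n_channels, n_effect_channels=2),
            NoiseSpec(),
            seed=4,
        )
        segs = segment_blocks(conc, sched)
        hrfs = block_average(
            segs, sched.conditions, sampling_rate_hz=conc.sampling_rate_hz
        )
        pre = hrfs.times_s < 0
        for cond in hrfs.mean:
            assert abs(hrfs.mean[cond][..., pre].mean()) < 1e-10


class TestDifferenceWave:
    def _hrfs(self, mean_c, mean_i):
        from fnirs_decnef.preprocess import HRFSet

        times = np.arange(mean_c.shape[-1], dtype=float)
        return HRFSet(
            times_s=times,
            mean={"congruent": mean_c, "incongruent": mean_i},
            sem={
                "congruent": np.zeros_like(mean_c),
                "incongruent": np.zeros_like(mean_i),
            },
            n_blocks={"congruent": 3, "incongruent": 3},
        )

    def test_identical_conditions_give_zero_wave(self):
        m = np.ones((2, 2, 10))
        assert np.allclose(difference_wave(self._hrfs(m, m.copy())), 0.0)

    def test_linearity(self, rng):
        a = rng.standard_normal((3, 2, 12))
        b = rng.standard_normal((3, 2, 12))
        d1 = difference_wave(self._hrfs(a, b))
        d2 = difference_wave(self._hrfs(2 * a, 2 * b))
        assert np.allclose(d2, 2 * d1)

    def test_missing_condition_rejected(self):
        from fnirs_decnef.preprocess import HRFSet

        hrfs = HRFSet(
            times_s=np.arange(4.0),
            mean={"congruent": np.zeros((1, 2, 4))},
            sem={"congruent": np.zeros((1, 2, 4))},
            n_blocks={"congruent": 1},
        )
        with pytest.raises(ValueError, match="incongruent"):
            difference_wave(hrfs)


class TestFullChain:
    def test_round_trip_recovers_ground_truth(self, default_montage):
        """Forward MBLL -> intensity -> OD -> concentration recovers the
        simulated series to 1e-9 relative error (filters disabled;
        mean-referenced on both sides)."""
        sched = make_design(3, seed=6)
        conc = simulate_concentrations(
            default_montage,
            sched,
            EffectMap.conflict(default_montage.n_channels),
            NoiseSpec(),
            seed=6,
        )
        raw = concentrations_to_intensity(conc, default_montage)
        cfg = PreprocessConfig(enable_filters=False, enable_motion_correction=False)
        rec, _ = preprocess_raw(raw, cfg)

        def centered(x):
            return x - x.mean(axis=1, keepdims=True)

        scale = np.abs(centered(conc.hbo)).max()
        assert np.abs(centered(rec.hbo) - centered(conc.hbo)).max() < 1e-9 * scale
        assert np.abs(centered(rec.hbr) - centered(conc.hbr)).max() < 1e-9 * scale

    def test_linearity_of_od_to_concentration_chain(self, small_montage):
        rng = np.random.default_rng(7)
        od_arr = 1e-3 * rng.standard_normal((small_montage.n_channels, 3, 2048))
        od = OpticalDensitySeries(od=od_arr, montage=small_montage)
        c1 = od_to_concentration(od)
        c2 = od_to_concentration(
            OpticalDensitySeries(od=3.0 * od_arr, montage=small_montage)
        )
        assert np.allclose(c2.hbo, 3.0 * c1.hbo, atol=1e-12)
        band1 = bandpass(c1.hbo, 0.01, 0.2, small_montage.sampling_rate_hz)
        band2 = bandpass(c2.hbo, 0.01, 0.2, small_montage.sampling_rate_hz)
        assert np.allclose(band2, 3.0 * band1, atol=1e-10)

    def test_pipeline_hash_tracks_parameters(self):
        h1 = PreprocessConfig().pipeline_hash()
        h2 = PreprocessConfig(motion_sd_thresh=50.0).pipeline_hash()
        assert h1 != h2
        assert h1 == PreprocessConfig().pipeline_hash()
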