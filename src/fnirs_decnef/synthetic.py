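"""Synthetic fNIRS sessions, behavior, and a virtual participant.

Every downstream stage (preprocessing, decoding, feedback, statistics)
is exercisable against data generated here, with known ground truth and
full seed control. The generative model is deliberately simple but
structurally faithful to a blocked Stroop fNIRS experiment:

* condition-dependent HbO responses built from a canonical double-gamma
  HRF driven at trial resolution (one impulse per color-word trial, so a
  4-trial block produces a compound response peaking ~5-8 s after block
  onset);
* HbR as a scaled, lagged mirror of HbO (default -1/3 amplitude, 1 s lag);
* additive physiological noise: white sensor noise, 1/f drift, and
  cardiac (~1.2 Hz), respiratory (~0.27 Hz) and Mayer-wave (~0.1 Hz)
  oscillations modeled as narrowband stochastic processes with finite
  phase coherence, drawn independently per channel;
* an optical forward model (MBLL) mapping concentrations to raw light
  intensities, so the whole preprocessing chain can be round-tripped;
* seeded step/spike motion artifacts with a ground-truth mask;
* lognormal reaction times with configurable congruency effects per
  group and test stage;
* a virtual participant whose expressed channel pattern drifts toward a
  decoder's incongruent class at a configurable coupling gain, closing
  the feedback loop in silico.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    CONGRUENT,
    INCONGRUENT,
    ConcentrationSeries,
    EventSchedule,
    Montage,
    RawRecording,
    double_gamma_hrf,
)

GROUPS = ("Sham", "DecNef")
STAGES = ("pre", "post", "followup")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectMap:
    """Per-channel hemodynamic response amplitudes for the two conditions.

    Amplitudes are peak HbO concentration changes in uM. ``hbr_ratio``
    sets the HbR amplitude as a fraction of HbO (negative: washout of
    deoxyhemoglobin), applied with ``hbr_lag_s`` of delay.
    """

    hbo_amp_congruent: np.ndarray
    hbo_amp_incongruent: np.ndarray
    hbr_ratio: float = -1.0 / 3.0
    hbr_lag_s: float = 1.0
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        a = np.asarray(self.hbo_amp_congruent, dtype=float)
        b = np.asarray(self.hbo_amp_incongruent, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("amplitude maps must be equal-length 1-D arrays")
        object.__setattr__(self, "hbo_amp_congruent", a)
        object.__setattr__(self, "hbo_amp_incongruent", b)

    @property
    def n_channels(self) -> int:
        return len(self.hbo_amp_congruent)

    def amplitude(self, condition: str) -> np.ndarray:
        if condition == CONGRUENT:
            return self.hbo_amp_congruent
        if condition == INCONGRUENT:
            return self.hbo_amp_incongruent
        raise ValueError(f"unknown condition {condition!r}")

    @classmethod
    def null(cls, n_channels: int) -> "EffectMap":
        """No evoked response in either condition."""
        z = np.zeros(n_channels)
        return cls(z, z.copy())

    @classmethod
    def conflict(
        cls,
        n_channels: int,
        congruent_amp_um: float = 0.20,
        incongruent_amp_um: float = 0.35,
        n_effect_channels: int | None = None,
        background_amp_um: float = 0.15,
    ) -> "EffectMap":
        """Conflict-sensitive map: the first ``n_effect_channels`` channels
        (default 10, capped at the montage size) respond more strongly to
        incongruent blocks; the remainder respond equally to both
        conditions (task-active but non-discriminative)."""
        if n_effect_channels is None:
            n_effect_channels = min(10, n_channels)
        if not 0 <= n_effect_channels <= n_channels:
            raise ValueError("n_effect_channels out of range")
        cong = np.full(n_channels, background_amp_um)
        incong = np.full(n_channels, background_amp_um)
        cong[:n_effect_channels] = congruent_amp_um
        incong[:n_effect_channels] = incongruent_amp_um
        if np.any(incong[:n_effect_channels] < cong[:n_effect_channels]):
            raise ValueError(
                "incongruent amplitude must be >= congruent on effect channels"
            )
        return cls(cong, incong)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for synthetic concentration series.

    All amplitudes are in uM on the HbO trace; HbR receives the same
    components scaled by ``hbr_scale``. Oscillation phases are drawn per
    channel from the seeded generator, so identical seeds reproduce the
    series bit-for-bit.
    """

    white_sd_um: float = 0.05
    drift_scale_um: float = 0.03
    cardiac_hz: float = 1.2
    cardiac_amp_um: float = 0.03
    cardiac_bw_hz: float = 0.15
    respiratory_hz: float = 0.27
    respiratory_amp_um: float = 0.05
    respiratory_bw_hz: float = 0.06
    mayer_hz: float = 0.10
    mayer_amp_um: float = 0.08
    mayer_bw_hz: float = 0.04
    hbr_scale: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in (
            "white_sd_um",
            "drift_scale_um",
            "cardiac_amp_um",
            "respiratory_amp_um",
            "mayer_amp_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(
            white_sd_um=0.0,
            drift_scale_um=0.0,
            cardiac_amp_um=0.0,
            respiratory_amp_um=0.0,
            mayer_amp_um=0.0,
        )


@dataclass(frozen=True)
class StroopParams:
    """Behavioral generative parameters.

    ``effects_ms`` maps (group, stage) to the mean incongruent-congruent
    RT difference. Defaults mirror the group-level means of the study
    conditions this package emulates: an intact Stroop effect in the
    Sham group across stages, and a reduced effect after decoded
    neurofeedback training.
    """

    base_rt_ms: float = 600.0
    sigma_log: float = 0.25
    p_correct: float = 0.97
    subject_sd_ms: float = 70.0
    stage_jitter_sd_ms: float = 10.0
    effects_ms: dict = field(
        default_factory=lambda: {
            ("Sham", "pre"): 95.0,
            ("Sham", "post"): 97.0,
            ("Sham", "followup"): 104.0,
            ("DecNef", "pre"): 93.0,
            ("DecNef", "post"): 67.0,
            ("DecNef", "followup"): 83.0,
        }
    )


# ---------------------------------------------------------------------------
# design and hemodynamics
# ---------------------------------------------------------------------------

def make_design(
    n_blocks_per_condition: int = 30,
    *,
    start_s: float = 15.0,
    trials_per_block: int = 4,
    fixation_s: float = 0.4,
    stimulus_s: float = 1.1,
    rest_s: float = 19.0,
    seed: int | None = None,
) -> EventSchedule:
    """Balanced pseudo-randomized block sequence.

    Blocks of the two conditions are interleaved by a seeded random
    permutation of a balanced label multiset; onsets are laid out
    back-to-back (task + rest per block) starting at ``start_s``.
    """
    if n_blocks_per_condition < 1:
        raise ValueError("n_blocks_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.array(
        [CONGRUENT] * n_blocks_per_condition
        + [INCONGRUENT] * n_blocks_per_condition
    )
    labels = labels[rng.permutation(labels.size)]
    block_s = trials_per_block * (fixation_s + stimulus_s) + rest_s
    onsets = start_s + block_s * np.arange(labels.size)
    return EventSchedule(
        block_onsets_s=onsets,
        conditions=tuple(labels),
        trials_per_block=trials_per_block,
        fixation_s=fixation_s,
        stimulus_s=stimulus_s,
        rest_s=rest_s,
    )


def hrf_block_template(
    schedule: EventSchedule,
    effect_map: EffectMap,
    sampling_rate_hz: float,
    duration_s: float,
) -> np.ndarray:
    """Unit-amplitude block drive convolved with the double-gamma HRF.

    Returns the evoked response of a single block with onset at t=0,
    normalized so its peak is 1; used both by the simulator and as an
    independent convolution oracle in tests.
    """
    fs = sampling_rate_hz
    n = int(round(duration_s * fs))
    drive = np.zeros(n)
    for t in schedule.trial_onsets_s(0) - schedule.block_onsets_s[0]:
        idx = int(round(t * fs))
        if idx < n:
            drive[idx] = 1.0
    t_h = np.arange(int(round(32.0 * fs))) / fs
    h = double_gamma_hrf(
        t_h,
        effect_map.hrf_peak_delay_s,
        effect_map.hrf_undershoot_delay_s,
        effect_map.hrf_undershoot_ratio,
    )
    resp = np.convolve(drive, h)[:n]
    peak = np.abs(resp).max()
    return resp / peak if peak > 0 else resp


def _narrowband_noise(
    n: int,
    fs: float,
    center_hz: float,
    bandwidth_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-SD narrowband Gaussian process centered on ``center_hz``.

    Physiological oscillations (cardiac, respiratory, Mayer waves) are
    quasi-periodic: phase-coherent over a few cycles but not across a
    whole session. Bandpassed white noise reproduces that finite
    coherence time (~1/bandwidth).
    """
    from scipy import signal as _signal

    lo = max(center_hz - bandwidth_hz / 2, 1e-4)
    hi = min(center_hz + bandwidth_hz / 2, 0.999 * fs / 2)
    if hi <= lo:
        return np.zeros(n)
    sos = _signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(n + int(20 * fs)))[int(20 * fs) :]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f (pink) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _channel_noise(
    n: int, fs: float, ns: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """One channel's additive HbO noise trace (uM)."""
    noise = np.zeros(n)
    if ns.white_sd_um > 0:
        noise += ns.white_sd_um * rng.standard_normal(n)
    if ns.drift_scale_um > 0:
        noise += ns.drift_scale_um * _pink_noise(n, rng)
    for f_hz, amp, bw in (
        (ns.cardiac_hz, ns.cardiac_amp_um, ns.cardiac_bw_hz),
        (ns.respiratory_hz, ns.respiratory_amp_um, ns.respiratory_bw_hz),
        (ns.mayer_hz, ns.mayer_amp_um, ns.mayer_bw_hz),
    ):
        if amp > 0:
            noise += amp * _narrowband_noise(n, fs, f_hz, bw, rng)
    return noise


def simulate_concentrations(
    montage: Montage,
    schedule: EventSchedule,
    effect_map: EffectMap,
    noise_spec: NoiseSpec,
    *,
    duration_s: float | None = None,
    seed: int | None = None,
) -> ConcentrationSeries:
    """Ground-truth HbO/HbR concentration series for one session.

    With a null effect map and silent noise the output is identically
    zero. The evoked HbO response of each block is the trial-resolution
    double-gamma template scaled by the channel's condition amplitude;
    HbR mirrors HbO with ``hbr_ratio`` scaling and ``hbr_lag_s`` delay.
    """
    if effect_map.n_channels != montage.n_channels:
        raise ValueError("effect map channel count does not match montage")
    fs = montage.sampling_rate_hz
    if duration_s is None:
        duration_s = schedule.duration_s + 10.0
    if schedule.duration_s > duration_s + 1e-9:
        raise ValueError("schedule exceeds the requested series duration")
    n = int(round(duration_s * fs))
    n_ch = montage.n_channels
    rng = np.random.default_rng(seed)

    # template support: full HRF tail after the last trial of the block
    template = hrf_block_template(
        schedule, effect_map, fs, 32.0 + schedule.task_duration_s
    )
    n_t = len(template)
    hbo = np.zeros((n_ch, n))
    for b in range(schedule.n_blocks):
        amp = effect_map.amplitude(schedule.conditions[b])
        i0 = int(round(schedule.block_onsets_s[b] * fs))
        i1 = min(i0 + n_t, n)
        hbo[:, i0:i1] += amp[:, None] * template[: i1 - i0]

    lag = int(round(effect_map.hbr_lag_s * fs))
    hbr = np.zeros_like(hbo)
    if lag < n:
        hbr[:, lag:] = effect_map.hbr_ratio * hbo[:, : n - lag]

    ns = noise_spec
    for ch in range(n_ch):
        noise = _channel_noise(n, fs, ns, rng)
        hbo[ch] += noise
        hbr[ch] += ns.hbr_scale * noise * -1.0  # physiology is anti-phase

    return ConcentrationSeries(hbo=hbo, hbr=hbr, sampling_rate_hz=fs)


# ---------------------------------------------------------------------------
# optical forward model
# ---------------------------------------------------------------------------

def concentrations_to_intensity(
    conc: ConcentrationSeries,
    montage: Montage,
    baseline_intensity: float | np.ndarray = 1.0,
    dpf: tuple[float, float, float] | None = None,
) -> RawRecording:
    """Forward modified Beer-Lambert model: concentrations -> intensities.

    ΔOD(λ, t) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · d · DPF(λ), and
    I(λ, t) = I₀(λ) · exp(−ΔOD(λ, t)). Concentrations are in uM, the
    extinction table in cm⁻¹/M, and separation d in cm.
    """
    if conc.n_channels != montage.n_channels:
        raise ValueError("concentration channel count does not match montage")
    base = np.asarray(baseline_intensity, dtype=float)
    if np.any(base <= 0):
        raise ValueError("baseline intensity must be strictly positive")
    if dpf is None:
        dpf = tuple(6.0 for _ in montage.wavelengths_nm)
    if len(dpf) != montage.n_wavelengths:
        raise ValueError("one DPF per wavelength required")
    eps = montage.extinction() * 1e-6  # cm^-1 / uM
    path = montage.separation_cm * np.asarray(dpf)  # effective path, cm
    # dOD: (channels, wavelengths, time)
    c = np.stack([conc.hbo, conc.hbr], axis=1)  # (ch, 2, T)
    d_od = np.einsum("wk,ckt->cwt", eps, c) * path[None, :, None]
    base = np.broadcast_to(base, d_od.shape[:2])
    intensity = base[:, :, None] * np.exp(-d_od)
    return RawRecording(intensity=intensity, montage=montage)


def inject_motion(
    raw: RawRecording,
    n_events: int,
    magnitude_od: float = 0.5,
    *,
    duration_s: float = 0.5,
    kind: str = "spike",
    seed: int | None = None,
) -> tuple[RawRecording, np.ndarray]:
    """Add step/spike motion artifacts to a raw recording.

    Artifacts are applied multiplicatively in intensity (additively in
    OD, magnitude ``magnitude_od``) at seeded random times, identically
    across wavelengths of a randomly chosen channel. Returns the
    corrupted recording and a boolean truth mask of shape
    (n_channels, n_samples) marking artifact supports.
    """
    n_samp = raw.n_samples
    mask = np.zeros((raw.montage.n_channels, n_samp), dtype=bool)
    if n_events == 0:
        return RawRecording(raw.intensity.copy(), raw.montage), mask
    if magnitude_od <= 0:
        raise ValueError("magnitude_od must be positive")
    if kind not in ("spike", "step"):
        raise ValueError("kind must be 'spike' or 'step'")
    fs = raw.sampling_rate_hz
    width = max(2, int(round(duration_s * fs)))
    rng = np.random.default_rng(seed)
    intensity = raw.intensity.copy()
    # disjoint, margin-separated artifact windows
    margin = 4 * width
    slots = np.arange(margin, n_samp - margin - width)
    starts: list[int] = []
    guard = 0
    while len(starts) < n_events:
        cand = int(rng.choice(slots))
        if all(abs(cand - s) > 2 * (width + margin // 2) for s in starts):
            starts.append(cand)
        guard += 1
        if guard > 100_000:
            raise ValueError("could not place disjoint artifacts; too many events")
    for s in sorted(starts):
        ch = int(rng.integers(raw.montage.n_channels))
        art = np.zeros(n_samp)
        if kind == "spike":
            half = width // 2
            shape = 1.0 - np.abs(np.arange(width) - half) / max(half, 1)
            art[s : s + width] = magnitude_od * shape
            mask[ch, s : s + width] = True
        else:
            art[s:] = magnitude_od
            mask[ch, s : s + width] = True
        intensity[ch] = intensity[ch] * np.exp(-art)[None, :]
    return RawRecording(intensity=intensity, montage=raw.montage), mask


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    group: str,
    stage: str,
    params: StroopParams | None = None,
    n_blocks_per_condition: int = 30,
    *,
    subject: str = "s01",
    subject_offset_ms: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial-level Stroop behavior for one subject in one test stage.

    Reaction times are lognormal (right-skewed) with means set so the
    expected incongruent - congruent difference equals the configured
    effect for (group, stage) plus ``subject_offset_ms``. Accuracy is an
    independent Bernoulli with no congruency effect.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    params = params or StroopParams()
    rng = np.random.default_rng(seed)
    effect = params.effects_ms[(group, stage)] + subject_offset_ms
    rows = []
    trials = 4
    order = np.array(
        [CONGRUENT] * n_blocks_per_condition + [INCONGRUENT] * n_blocks_per_condition
    )
    order = order[rng.permutation(order.size)]
    for block, cond in enumerate(order):
        mean_rt = params.base_rt_ms + (effect if cond == INCONGRUENT else 0.0)
        mu = np.log(mean_rt) - params.sigma_log**2 / 2.0
        for trial in range(trials):
            rt = float(rng.lognormal(mu, params.sigma_log))
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "stage": stage,
                    "block": block,
                    "trial": trial,
                    "condition": cond,
                    "rt_ms": rt,
                    "correct": bool(rng.random() < params.p_correct),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    stages: tuple[str, ...] = STAGES,
    params: StroopParams | None = None,
    n_blocks_per_condition: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial-level behavior for a two-group longitudinal cohort.

    Each subject carries a random Stroop-effect intercept (shared across
    stages, SD ``subject_sd_ms``) plus independent per-stage jitter,
    giving realistic between-subject variance and within-subject
    correlation for the mixed-ANOVA analyses.
    """
    n_per_group = n_per_group or {"Sham": 25, "DecNef": 20}
    params = params or StroopParams()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    frames = []
    idx = 0
    for group, n_sub in n_per_group.items():
        for _ in range(n_sub):
            idx += 1
            subject = f"s{idx:03d}"
            intercept = rng.normal(0.0, params.subject_sd_ms)
            for stage in stages:
                jitter = rng.normal(0.0, params.stage_jitter_sd_ms)
                frames.append(
                    simulate_behavior(
                        group,
                        stage,
                        params,
                        n_blocks_per_condition,
                        subject=subject,
                        subject_offset_ms=intercept + jitter,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# closed-loop virtual participant
# ---------------------------------------------------------------------------

class VirtualParticipant:
    """Stateful source of concentration blocks coupled to a decoder.

    The participant emits physiological noise during the baseline period
    of each block and, during regulation, adds a channel-space pattern
    aligned with the decoder's incongruent class, ramping up over
    ``ramp_s`` seconds to an amplitude of ``gain`` uM. ``gain = 0``
    yields stationary noise; the expected feedback score is
    non-decreasing in the gain.

    Decoder weights on derivative features are ignored when building the
    target direction (a static pattern cannot hold a nonzero derivative
    indefinitely); this only reduces the attainable score, never the
    monotonicity in gain.
    """

    def __init__(
        self,
        decoder,
        gain: float,
        *,
        montage: Montage | None = None,
        noise_spec: NoiseSpec | None = None,
        ramp_s: float = 5.0,
        seed: int | None = None,
    ) -> None:
        self.decoder = decoder
        self.gain = float(gain)
        self.montage = montage or Montage()
        self.noise_spec = noise_spec or NoiseSpec()
        self.ramp_s = float(ramp_s)
        self._rng = np.random.default_rng(seed)
        self._dir_hbo, self._dir_hbr = self._target_direction()

    def _target_direction(self) -> tuple[np.ndarray, np.ndarray]:
        n_ch = self.montage.n_channels
        d_hbo = np.zeros(n_ch)
        d_hbr = np.zeros(n_ch)
        spec = self.decoder.feature_spec
        # average the calibrated (sign-corrected) weights over post-onset bins
        post = self.decoder.bin_times_s >= 0
        w = (self.decoder.platt_a[post, None] * self.decoder.weights[post]).mean(axis=0)
        for j, (ch, kindname) in enumerate(spec.features):
            if kindname == "hbo":
                d_hbo[ch] += w[j]
            elif kindname == "hbr":
                d_hbr[ch] += w[j]
        norm = max(np.abs(np.concatenate([d_hbo, d_hbr])).max(), 1e-12)
        return d_hbo / norm, d_hbr / norm

    def next_block(
        self, baseline_s: float = 15.0, regulate_s: float = 25.0
    ) -> ConcentrationSeries:
        """Concentration series for one feedback block (baseline + regulation)."""
        fs = self.montage.sampling_rate_hz
        n = int(round((baseline_s + regulate_s) * fs))
        n_ch = self.montage.n_channels
        t = np.arange(n) / fs
        ns = self.noise_spec
        hbo = np.zeros((n_ch, n))
        hbr = np.zeros((n_ch, n))
        rng = self._rng
        for ch in range(n_ch):
            noise = _channel_noise(n, fs, ns, rng)
            hbo[ch] = noise
            hbr[ch] = -ns.hbr_scale * noise
        if self.gain != 0.0:
            elapsed = t - baseline_s
            ramp = np.clip(elapsed / self.ramp_s, 0.0, 1.0)
            ramp[elapsed < 0] = 0.0
            hbo += self.gain * ramp[None, :] * self._dir_hbo[:, None]
            hbr += self.gain * ramp[None, :] * self._dir_hbr[:, None]
        return ConcentrationSeries(hbo=hbo, hbr=hbr, sampling_rate_hz=fs)


def simulate_session(
    montage: Montage | None = None,
    *,
    n_blocks_per_condition: int = 30,
    effect_map: EffectMap | None = None,
    noise_spec: NoiseSpec | None = None,
    seed: int | None = None,
) -> tuple[EventSchedule, ConcentrationSeries]:
    """One full Stroop session: schedule plus concentration ground truth.

    Convenience wrapper; the default effect map is the conflict
    configuration, pass ``EffectMap.null`` for a null session.
    """
    montage = montage or Montage()
    ss = np.random.SeedSequence(seed)
    s_design, s_conc = ss.spawn(2)
    schedule = make_design(
        n_blocks_per_condition, seed=int(s_design.generate_state(1)[0] % (2**31))
    )
    if effect_map is None:
        effect_map = EffectMap.conflict(montage.n_channels)
    conc = simulate_concentrations(
        montage,
        schedule,
        effect_map,
        noise_spec or NoiseSpec(),
        seed=int(s_conc.generate_state(1)[0] % (2**31)),
    )
    return schedule, conc
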