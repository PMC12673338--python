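"""Offline preprocessing: intensity -> OD -> denoised concentrations -> HRFs.

The chain follows standard continuous-wave fNIRS practice (Homer-style
conventions): optical-density conversion against the channel temporal
mean, zero-phase Butterworth bandpass (0.01-1 Hz), threshold-based
motion-artifact detection, cubic-spline correction, a narrower bandpass
(0.01-0.2 Hz), modified Beer-Lambert conversion with DPF [6, 6, 6],
then block segmentation and averaging into hemodynamic response
functions for task data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import make_smoothing_spline

from .core import (
    CONDITIONS,
    ConcentrationSeries,
    EventSchedule,
    Montage,
    OpticalDensitySeries,
    RawRecording,
)


# ---------------------------------------------------------------------------
# step 1: optical density
# ---------------------------------------------------------------------------

def intensity_to_od(raw: RawRecording) -> OpticalDensitySeries:
    """Convert raw intensities to optical-density changes.

    ΔOD(t) = -ln(I(t) / Ī) with Ī the temporal mean of the trace, so the
    result is zero-mean-referenced per (channel, wavelength) and invariant
    to the absolute source intensity.
    """
    intensity = raw.intensity
    if np.any(intensity <= 0):
        ch, wl, t = np.unravel_index(
            int(np.argmax(intensity <= 0)), intensity.shape
        )
        raise ValueError(
            f"non-positive intensity at channel {ch}, wavelength index {wl}, "
            f"sample {t}"
        )
    ref = intensity.mean(axis=2, keepdims=True)
    od = -np.log(intensity / ref)
    return OpticalDensitySeries(od=od, montage=raw.montage)


# ---------------------------------------------------------------------------
# steps 2 & 5: bandpass
# ---------------------------------------------------------------------------

def bandpass(
    series: np.ndarray,
    low_hz: float,
    high_hz: float,
    sampling_rate_hz: float,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis.

    Applied forward-backward (``sosfiltfilt``) so the passband is
    phase-neutral; the effective attenuation is twice the single-pass
    order. Accepts any array whose last axis is time.
    """
    nyq = sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def bandpass_od(
    od: OpticalDensitySeries, low_hz: float, high_hz: float, order: int = 3
) -> OpticalDensitySeries:
    return OpticalDensitySeries(
        od=bandpass(od.od, low_hz, high_hz, od.sampling_rate_hz, order),
        montage=od.montage,
    )


def bandpass_concentration(
    conc: ConcentrationSeries, low_hz: float, high_hz: float, order: int = 3
) -> ConcentrationSeries:
    fs = conc.sampling_rate_hz
    return ConcentrationSeries(
        hbo=bandpass(conc.hbo, low_hz, high_hz, fs, order),
        hbr=bandpass(conc.hbr, low_hz, high_hz, fs, order),
        sampling_rate_hz=fs,
        dpf=conc.dpf,
    )


# ---------------------------------------------------------------------------
# step 3: motion-artifact detection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactMask:
    """Per-channel boolean motion-artifact mask.

    ``mask`` has shape (n_channels, n_samples); flagged samples are the
    full detection windows around threshold crossings. Wavelengths of a
    channel share one mask (motion moves the optode, not the light).
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be (channels, samples)")

    @property
    def any_flagged(self) -> bool:
        return bool(self.mask.any())

    def intervals(self, channel: int) -> list[tuple[int, int]]:
        """Maximal flagged [start, stop) sample intervals for a channel."""
        m = self.mask[channel]
        if not m.any():
            return []
        edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
        return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def detect_motion(
    od: OpticalDensitySeries,
    t_window_s: float = 3.0,
    sd_thresh: float = 60.0,
    amp_thresh: float = 6.0,
) -> ArtifactMask:
    """Threshold-based motion detection on optical-density traces.

    A sample is flagged when the signal excursion (max - min) within the
    ``t_window_s`` window around it exceeds ``sd_thresh`` times the
    channel's SD of sample-to-sample differences, or exceeds the absolute
    amplitude criterion ``amp_thresh`` (in OD units). Flags are dilated
    to the full window, and a channel's wavelengths are OR-combined.
    """
    if sd_thresh <= 0 or amp_thresh <= 0:
        raise ValueError("thresholds must be positive")
    fs = od.sampling_rate_hz
    win = int(round(t_window_s * fs))
    if win < 2:
        raise ValueError("detection window shorter than 2 samples")
    x = od.od  # (ch, wl, T)
    mx = ndimage.maximum_filter1d(x, size=win, axis=-1, mode="nearest")
    mn = ndimage.minimum_filter1d(x, size=win, axis=-1, mode="nearest")
    excursion = mx - mn
    # robust SD of the first differences (1.4826 * MAD): the plain SD is
    # inflated by the very artifacts being detected
    d = np.diff(x, axis=-1)
    med = np.median(d, axis=-1, keepdims=True)
    diff_sd = 1.4826 * np.median(np.abs(d - med), axis=-1, keepdims=True)
    flagged = (excursion > sd_thresh * diff_sd) | (excursion > amp_thresh)
    flagged = flagged.any(axis=1)  # combine wavelengths -> (ch, T)
    dilated = ndimage.binary_dilation(
        flagged, structure=np.ones((1, win), dtype=bool)
    )
    return ArtifactMask(mask=dilated)


# ---------------------------------------------------------------------------
# step 4: cubic-spline correction
# ---------------------------------------------------------------------------

def _spline_correct_1d(
    x: np.ndarray, mask: np.ndarray, fs: float, p: float
) -> np.ndarray:
    """Homer-style spline motion correction of one trace.

    Within each flagged interval a cubic smoothing spline (smoothing
    parameter ``p``; p -> 1 interpolates, p -> 0 fits a line) is fit and
    subtracted, removing the slow artifact excursion; the residual
    segment is then shifted so its mean joins the preceding clean data.
    Subsequent clean segments are shifted rigidly so no step is left at
    segment boundaries. Clean samples keep their shape.
    """
    y = x.astype(float).copy()
    n = len(y)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    intervals = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    lam = (1.0 - p) / max(p, 1e-12)  # csaps p -> scipy lam convention
    anchor = max(2, int(round(0.25 * fs)))  # mean window used to re-join segments
    for start, stop in intervals:
        seg = y[start:stop]
        t = np.arange(len(seg), dtype=float)
        if len(seg) >= 4:
            spl = make_smoothing_spline(t, seg, lam=lam * len(seg))
            resid = seg - spl(t)
        else:
            resid = seg - seg.mean()
        if start > 0:
            left = y[max(0, start - anchor) : start]
            target = left.mean()
        else:
            target = seg.mean()
        resid = resid - resid[: min(anchor, len(resid))].mean() + target
        # rigid shift of everything after the artifact to meet the corrected tail
        if stop < n:
            right = y[stop : min(n, stop + anchor)]
            shift = resid[-min(anchor, len(resid)) :].mean() - right.mean()
            y[stop:] += shift
        y[start:stop] = resid
    return y


def spline_correct(
    od: OpticalDensitySeries, mask: ArtifactMask, p: float = 0.99
) -> OpticalDensitySeries:
    """Cubic-spline motion correction on flagged intervals.

    Identity when the mask is empty. Raises if a channel is flagged for
    its entire duration (no clean reference remains).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if mask.mask.shape != (od.od.shape[0], od.od.shape[2]):
        raise ValueError("mask shape does not match series")
    if np.any(mask.mask.all(axis=1)):
        bad = int(np.argmax(mask.mask.all(axis=1)))
        raise ValueError(f"mask covers the entire series on channel {bad}")
    if not mask.any_flagged:
        return OpticalDensitySeries(od=od.od.copy(), montage=od.montage)
    out = od.od.copy()
    fs = od.sampling_rate_hz
    for ch in range(out.shape[0]):
        if not mask.mask[ch].any():
            continue
        for wl in range(out.shape[1]):
            out[ch, wl] = _spline_correct_1d(out[ch, wl], mask.mask[ch], fs, p)
    return OpticalDensitySeries(od=out, montage=od.montage)


# ---------------------------------------------------------------------------
# step 6: modified Beer-Lambert conversion
# ---------------------------------------------------------------------------

def od_to_concentration(
    od: OpticalDensitySeries,
    dpf: tuple[float, ...] = (6.0, 6.0, 6.0),
) -> ConcentrationSeries:
    """Solve the MBLL for HbO/HbR concentration changes (uM).

    Per channel and sample, least-squares solution of
    ΔOD(λ) = [ε_HbO(λ), ε_HbR(λ)] · [ΔHbO, ΔHbR]ᵀ · d · DPF(λ)
    over the montage wavelengths. Requires >= 2 wavelengths and a
    well-conditioned extinction matrix.
    """
    montage = od.montage
    if montage.n_wavelengths < 2:
        raise ValueError("at least two wavelengths required to resolve HbO/HbR")
    if len(dpf) != montage.n_wavelengths:
        raise ValueError("one DPF per wavelength required")
    eps = montage.extinction() * 1e-6  # cm^-1 / uM
    path = montage.separation_cm * np.asarray(dpf, dtype=float)
    a = eps * path[:, None]  # (n_wl, 2)
    if np.linalg.cond(a) > 1e8:
        raise ValueError("extinction matrix is singular or near-singular")
    pinv = np.linalg.pinv(a)  # (2, n_wl)
    conc = np.einsum("kw,cwt->ckt", pinv, od.od)
    return ConcentrationSeries(
        hbo=conc[:, 0],
        hbr=conc[:, 1],
        sampling_rate_hz=od.sampling_rate_hz,
        dpf=tuple(float(d) for d in dpf),
    )


# ---------------------------------------------------------------------------
# step 7: segmentation and HRF averaging
# ---------------------------------------------------------------------------

def segment_blocks(
    conc: ConcentrationSeries,
    schedule: EventSchedule,
    window_s: tuple[float, float] = (-5.0, 25.0),
) -> np.ndarray:
    """Slice the series into per-block segments.

    Returns an array of shape (n_blocks, n_channels, 2, n_window) where
    axis 2 stacks (HbO, HbR). Time-zero per block is the onset of the
    block's first fixation; the window endpoints are inclusive on the
    sample grid (``n_window = round((t1 - t0) * fs) + 1``).
    """
    fs = conc.sampling_rate_hz
    t0, t1 = window_s
    if t1 < t0:
        raise ValueError("window must satisfy t0 <= t1")
    n_win = int(round((t1 - t0) * fs)) + 1
    segs = np.empty((schedule.n_blocks, conc.n_channels, 2, n_win))
    stacked = np.stack([conc.hbo, conc.hbr], axis=1)  # (ch, 2, T)
    for b, onset in enumerate(schedule.block_onsets_s):
        i0 = int(round((onset + t0) * fs))
        i1 = i0 + n_win
        if i0 < 0 or i1 > conc.n_samples:
            raise ValueError(
                f"block {b} window [{onset + t0:.2f}, {onset + t1:.2f}] s "
                "outside the recording"
            )
        segs[b] = stacked[:, :, i0:i1]
    return segs


@dataclass
class HRFSet:
    """Block-averaged hemodynamic responses per condition.

    ``mean`` and ``sem`` map condition -> array (n_channels, 2, n_window)
    with axis 1 stacking (HbO, HbR); ``n_blocks`` gives the number of
    segments averaged per condition.
    """

    times_s: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_blocks: dict[str, int]
    baseline_corrected: bool = True


def block_average(
    segments: np.ndarray,
    conditions,
    window_s: tuple[float, float] = (-5.0, 25.0),
    sampling_rate_hz: float = 25.6,
    baseline_correct: bool = True,
) -> HRFSet:
    """Arithmetic mean and SEM of block segments per condition.

    With ``baseline_correct`` each segment first has its pre-stimulus
    mean (window [t0, 0) s) subtracted per channel and chromophore, so
    the averaged HRFs are referenced to the immediately preceding rest.
    """
    conditions = np.asarray(conditions)
    if len(conditions) != segments.shape[0]:
        raise ValueError("one condition label per segment required")
    t0, _ = window_s
    fs = sampling_rate_hz
    times = t0 + np.arange(segments.shape[-1]) / fs
    segs = segments.astype(float)
    if baseline_correct:
        pre = times < 0
        if pre.any():
            segs = segs - segs[..., pre].mean(axis=-1, keepdims=True)
    mean: dict[str, np.ndarray] = {}
    sem: dict[str, np.ndarray] = {}
    n_blocks: dict[str, int] = {}
    for cond in np.unique(conditions):
        sel = segs[conditions == cond]
        if sel.shape[0] < 1:
            raise ValueError(f"no segments for condition {cond!r}")
        mean[str(cond)] = sel.mean(axis=0)
        sd = sel.std(axis=0, ddof=1) if sel.shape[0] > 1 else np.zeros_like(sel[0])
        sem[str(cond)] = sd / np.sqrt(sel.shape[0])
        n_blocks[str(cond)] = int(sel.shape[0])
    return HRFSet(
        times_s=times,
        mean=mean,
        sem=sem,
        n_blocks=n_blocks,
        baseline_corrected=baseline_correct,
    )


def difference_wave(
    hrfs: HRFSet, chromophore: str = "hbo", average_channels: bool = True
) -> np.ndarray:
    """Incongruent minus congruent HRF (conflict-specific response).

    By default the HbO difference averaged over all channels (matching
    the channel-heterogeneity rationale for decoding montages); with
    ``average_channels=False`` the per-channel difference is returned.
    """
    for cond in CONDITIONS:
        if cond not in hrfs.mean:
            raise ValueError(f"condition {cond!r} missing from HRF set")
    k = {"hbo": 0, "hbr": 1}[chromophore]
    diff = hrfs.mean["incongruent"][:, k] - hrfs.mean["congruent"][:, k]
    return diff.mean(axis=0) if average_channels else diff


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """Every tunable of the offline chain, in execution order."""

    bandpass1_hz: tuple[float, float] = (0.01, 1.0)
    motion_window_s: float = 3.0
    motion_sd_thresh: float = 60.0
    motion_amp_thresh: float = 6.0
    spline_p: float = 0.99
    bandpass2_hz: tuple[float, float] = (0.01, 0.2)
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0)
    filter_order: int = 3
    enable_filters: bool = True
    enable_motion_correction: bool = True

    def pipeline_hash(self) -> str:
        """Stable digest of the step order and all parameters."""
        payload = {
            "order": [
                "intensity_to_od",
                "bandpass1",
                "detect_motion",
                "spline_correct",
                "bandpass2",
                "od_to_concentration",
                "segment_and_average",
            ],
            "params": {
                k: getattr(self, k)
                for k in (
                    "bandpass1_hz",
                    "motion_window_s",
                    "motion_sd_thresh",
                    "motion_amp_thresh",
                    "spline_p",
                    "bandpass2_hz",
                    "dpf",
                    "filter_order",
                    "enable_filters",
                    "enable_motion_correction",
                )
            },
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_raw(
    raw: RawRecording, config: PreprocessConfig | None = None
) -> tuple[ConcentrationSeries, ArtifactMask]:
    """Run the continuous part of the chain (steps 1-6) in order.

    Returns the denoised concentration series plus the motion mask that
    was applied. Disabling filters/motion correction (``config``) leaves
    a pure OD->MBLL conversion, which inverts the synthetic forward
    model to numerical precision.
    """
    config = config or PreprocessConfig()
    od = intensity_to_od(raw)
    if config.enable_filters:
        od = bandpass_od(od, *config.bandpass1_hz, order=config.filter_order)
    mask = detect_motion(
        od,
        t_window_s=config.motion_window_s,
        sd_thresh=config.motion_sd_thresh,
        amp_thresh=config.motion_amp_thresh,
    )
    if config.enable_motion_correction and mask.any_flagged:
        od = spline_correct(od, mask, p=config.spline_p)
    if config.enable_filters:
        od = bandpass_od(od, *config.bandpass2_hz, order=config.filter_order)
    dpf = config.dpf
    if len(dpf) != raw.montage.n_wavelengths:
        dpf = tuple(dpf[0] for _ in raw.montage.wavelengths_nm)
    conc = od_to_concentration(od, dpf=dpf)
    return conc, mask


def preprocess_task(
    raw: RawRecording,
    schedule: EventSchedule,
    config: PreprocessConfig | None = None,
    window_s: tuple[float, float] = (-5.0, 25.0),
) -> tuple[ConcentrationSeries, HRFSet]:
    """Full task-state chain (steps 1-7): concentrations plus averaged HRFs."""
    conc, _ = preprocess_raw(raw, config)
    segments = segment_blocks(conc, schedule, window_s)
    hrfs = block_average(
        segments, schedule.conditions, window_s, conc.sampling_rate_hz
    )
    return conc, hrfs
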