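"""Core domain objects shared across the pipeline.

The package models a continuous-wave fNIRS experiment: a laser/detector
montage measures light attenuation at several near-infrared wavelengths;
attenuation changes are converted to oxy-/deoxy-hemoglobin concentration
changes through the modified Beer-Lambert law (MBLL); a blocked Stroop
design drives condition-dependent hemodynamic responses.

This module holds the montage geometry, the event schedule of the block
design, the in-memory time-series containers, the hemoglobin extinction
coefficient table, and the canonical double-gamma hemodynamic response
function used by the synthetic generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONDITIONS = (CONGRUENT, INCONGRUENT)

# Molar extinction coefficients of hemoglobin, cm^-1 / (mol/L), compiled
# from the Prahl/Gratzer tabulation (see docs/methods.md for the source).
# Keys are wavelengths in nm; values are (epsilon_HbO, epsilon_HbR).
EXTINCTION_CM_PER_M: dict[float, tuple[float, float]] = {
    760.0: (586.0, 1548.5),
    780.0: (710.0, 1075.4),
    805.0: (840.0, 753.4),
    830.0: (974.0, 693.0),
    850.0: (1058.0, 691.3),
}


def extinction_matrix(wavelengths_nm) -> np.ndarray:
    """Extinction-coefficient matrix for a set of wavelengths.

    Parameters
    ----------
    wavelengths_nm : sequence of float
        Wavelengths in nm. Tabulated wavelengths are returned exactly;
        intermediate wavelengths are linearly interpolated on the table.

    Returns
    -------
    ndarray, shape (n_wavelengths, 2)
        Columns are (epsilon_HbO, epsilon_HbR) in cm^-1/M.
    """
    grid = np.array(sorted(EXTINCTION_CM_PER_M))
    eps = np.array([EXTINCTION_CM_PER_M[w] for w in grid])
    wls = np.asarray(wavelengths_nm, dtype=float)
    if wls.ndim != 1 or wls.size < 1:
        raise ValueError("wavelengths_nm must be a non-empty 1-D sequence")
    if wls.min() < grid[0] or wls.max() > grid[-1]:
        raise ValueError(
            f"wavelengths outside tabulated range [{grid[0]}, {grid[-1]}] nm"
        )
    out = np.column_stack(
        [np.interp(wls, grid, eps[:, 0]), np.interp(wls, grid, eps[:, 1])]
    )
    return out


@dataclass(frozen=True)
class Montage:
    """Optode-array geometry and acquisition metadata.

    Defaults describe a 35-channel prefrontal "T" layout measured with a
    three-wavelength (780/805/830 nm) CW system at 25.6 Hz with 3.0 cm
    source-detector separation.

    ``labels`` optionally maps channel index to an anatomical string
    (e.g. a Brodmann-area label); it is carried as metadata only.
    """

    n_channels: int = 35
    wavelengths_nm: tuple[float, ...] = (780.0, 805.0, 830.0)
    separation_cm: float = 3.0
    sampling_rate_hz: float = 25.6
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        wls = tuple(float(w) for w in self.wavelengths_nm)
        if len(wls) < 2:
            raise ValueError("at least two wavelengths are required")
        if any(w <= 0 for w in wls):
            raise ValueError("wavelengths must be strictly positive")
        if len(set(wls)) != len(wls):
            raise ValueError("wavelengths must be distinct")
        if self.separation_cm <= 0:
            raise ValueError("separation_cm must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "wavelengths_nm", wls)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    def extinction(self) -> np.ndarray:
        """(n_wavelengths, 2) extinction matrix for this montage."""
        return extinction_matrix(self.wavelengths_nm)


@dataclass(frozen=True)
class EventSchedule:
    """Block design of the color-word Stroop session.

    Each block is ``trials_per_block`` consecutive trials of a single
    condition (a 0.4 s fixation plus a 1.1 s color-word per trial),
    followed by ``rest_s`` of rest. Block time-zero is the onset of the
    block's first fixation.
    """

    block_onsets_s: np.ndarray
    conditions: tuple[str, ...]
    trials_per_block: int = 4
    fixation_s: float = 0.4
    stimulus_s: float = 1.1
    rest_s: float = 19.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.block_onsets_s, dtype=float)
        conds = tuple(self.conditions)
        if onsets.ndim != 1 or onsets.size != len(conds):
            raise ValueError("one condition label per block onset required")
        if onsets.size == 0:
            raise ValueError("schedule must contain at least one block")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("block onsets must be strictly increasing")
        unknown = set(conds) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        # allow a small tolerance for float round-off on the 1/fs grid
        min_gap = self.task_duration_s + self.rest_s
        if onsets.size > 1 and np.any(np.diff(onsets) < min_gap - 1e-9):
            raise ValueError(
                f"inter-onset gap must be >= task + rest = {min_gap} s"
            )
        object.__setattr__(self, "block_onsets_s", onsets)
        object.__setattr__(self, "conditions", conds)

    @property
    def n_blocks(self) -> int:
        return len(self.conditions)

    @property
    def trial_duration_s(self) -> float:
        return self.fixation_s + self.stimulus_s

    @property
    def task_duration_s(self) -> float:
        """Active (stimulus-presentation) span of one block, in seconds."""
        return self.trials_per_block * self.trial_duration_s

    @property
    def block_duration_s(self) -> float:
        return self.task_duration_s + self.rest_s

    @property
    def duration_s(self) -> float:
        """End of the last block's rest period."""
        return float(self.block_onsets_s[-1] + self.block_duration_s)

    def trial_onsets_s(self, block: int) -> np.ndarray:
        """Stimulus-train onsets (one per trial) within a block."""
        t0 = self.block_onsets_s[block]
        return t0 + self.trial_duration_s * np.arange(self.trials_per_block)

    def block_indices(self, condition: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.conditions) == condition)


@dataclass
class RawRecording:
    """Raw light-intensity time series, one trace per (channel, wavelength).

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary units; values must be strictly positive.
    """

    intensity: np.ndarray
    montage: Montage

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, time)")
        n_ch, n_wl, _ = self.intensity.shape
        if n_ch != self.montage.n_channels or n_wl != self.montage.n_wavelengths:
            raise ValueError("intensity shape inconsistent with montage")

    @property
    def sampling_rate_hz(self) -> float:
        return self.montage.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class OpticalDensitySeries:
    """Optical-density change per (channel, wavelength) over time."""

    od: np.ndarray
    montage: Montage

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be (channels, wavelengths, time)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density contains non-finite values")

    @property
    def sampling_rate_hz(self) -> float:
        return self.montage.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]


@dataclass
class ConcentrationSeries:
    """Hemoglobin concentration changes, per channel over time.

    ``hbo`` and ``hbr`` have shape (n_channels, n_samples) in uM
    (micromolar, with the geometric pathlength d*DPF already divided out;
    the DPF used is recorded in ``dpf``).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate_hz: float
    dpf: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValueError("hbo and hbr must be equal-shape 2-D arrays")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def copy(self) -> "ConcentrationSeries":
        return dataclasses.replace(
            self, hbo=self.hbo.copy(), hbr=self.hbr.copy()
        )


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    The standard parameterization used throughout fMRI/fNIRS modeling:
    a gamma density with shape ``peak_delay_s`` (unit scale) minus a
    scaled gamma with shape ``undershoot_delay_s``. With the default
    delays (6, 16) the positive lobe peaks near 5 s. The output is
    normalized to a unit peak, so response amplitudes quoted elsewhere
    are peak concentration changes.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, peak_delay_s) - undershoot_ratio * _gamma_dist.pdf(
        t, undershoot_delay_s
    )
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h
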