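"""File formats: plain-CSV dialects and a minimal SNIRF (HDF5) layer.

CSV dialects (all with a header row):

* raw intensity — ``time_s, ch<i>_wl<λ>`` (one column per channel /
  wavelength pair, channel indices and wavelengths in nm);
* concentrations — ``time_s, ch<i>_hbo, ch<i>_hbr`` in uM;
* events — ``onset_s, condition, block_id``;
* behavior — ``subject, group, stage, block, trial, condition, rt_ms,
  correct``;
* HRF sets — tidy ``condition, channel, chromophore, time_s, mean, sem, n``;
* MVPA curves — ``time_s, mean_acc, sd, n``.

The SNIRF layer writes/reads continuous-wave raw intensity using the
standard HDF5 group layout (``/nirs/data1`` with ``dataTimeSeries``,
``time`` and per-column ``measurementList`` entries); it covers what
this package produces, not the full breadth of the format.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ConcentrationSeries, EventSchedule, Montage, RawRecording
from .mvpa import MVPACurve
from .preprocess import HRFSet


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_raw_csv(path: str | Path, raw: RawRecording) -> None:
    cols = {"time_s": raw.times_s}
    for ch in range(raw.montage.n_channels):
        for w, wl in enumerate(raw.montage.wavelengths_nm):
            cols[f"ch{ch}_wl{wl:g}"] = raw.intensity[ch, w]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_raw_csv(path: str | Path, montage: Montage | None = None) -> RawRecording:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time_s"]
    pairs = []
    for name in names:
        ch_s, wl_s = name.split("_wl")
        pairs.append((int(ch_s[2:]), float(wl_s)))
    channels = sorted({c for c, _ in pairs})
    wavelengths = sorted({w for _, w in pairs})
    if montage is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
        montage = Montage(
            n_channels=len(channels),
            wavelengths_nm=tuple(wavelengths),
            sampling_rate_hz=fs,
        )
    intensity = np.empty((len(channels), len(wavelengths), len(df)))
    for ch in channels:
        for w, wl in enumerate(wavelengths):
            intensity[ch, w] = df[f"ch{ch}_wl{wl:g}"].to_numpy()
    return RawRecording(intensity=intensity, montage=montage)


def write_concentration_csv(path: str | Path, conc: ConcentrationSeries) -> None:
    cols = {"time_s": conc.times_s}
    for ch in range(conc.n_channels):
        cols[f"ch{ch}_hbo"] = conc.hbo[ch]
        cols[f"ch{ch}_hbr"] = conc.hbr[ch]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_concentration_csv(path: str | Path) -> ConcentrationSeries:
    df = pd.read_csv(path)
    n_ch = sum(1 for c in df.columns if c.endswith("_hbo"))
    hbo = np.stack([df[f"ch{ch}_hbo"].to_numpy() for ch in range(n_ch)])
    hbr = np.stack([df[f"ch{ch}_hbr"].to_numpy() for ch in range(n_ch)])
    dt = np.diff(df["time_s"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    return ConcentrationSeries(hbo=hbo, hbr=hbr, sampling_rate_hz=fs)


def write_events_csv(path: str | Path, schedule: EventSchedule) -> None:
    pd.DataFrame(
        {
            "onset_s": schedule.block_onsets_s,
            "condition": list(schedule.conditions),
            "block_id": np.arange(schedule.n_blocks),
        }
    ).to_csv(path, index=False)


def read_events_csv(
    path: str | Path,
    trials_per_block: int = 4,
    fixation_s: float = 0.4,
    stimulus_s: float = 1.1,
    rest_s: float = 19.0,
) -> EventSchedule:
    df = pd.read_csv(path).sort_values("block_id")
    return EventSchedule(
        block_onsets_s=df["onset_s"].to_numpy(),
        conditions=tuple(df["condition"]),
        trials_per_block=trials_per_block,
        fixation_s=fixation_s,
        stimulus_s=stimulus_s,
        rest_s=rest_s,
    )


def write_behavior_csv(path: str | Path, behavior: pd.DataFrame) -> None:
    behavior.to_csv(path, index=False)


def read_behavior_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_hrf_csv(path: str | Path, hrfs: HRFSet) -> None:
    rows = []
    for cond, mean in hrfs.mean.items():
        sem = hrfs.sem[cond]
        n = hrfs.n_blocks[cond]
        for ch in range(mean.shape[0]):
            for k, chrom in enumerate(("hbo", "hbr")):
                for j, t in enumerate(hrfs.times_s):
                    rows.append(
                        {
                            "condition": cond,
                            "channel": ch,
                            "chromophore": chrom,
                            "time_s": t,
                            "mean": mean[ch, k, j],
                            "sem": sem[ch, k, j],
                            "n": n,
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mvpa_curve_csv(path: str | Path, curve: MVPACurve) -> None:
    pd.DataFrame(
        {
            "time_s": curve.bin_starts_s,
            "mean_acc": curve.mean_accuracy,
            "sd": curve.sd,
            "n": curve.n_shuffles,
        }
    ).to_csv(path, index=False)


def read_mvpa_curve_csv(path: str | Path) -> MVPACurve:
    df = pd.read_csv(path)
    return MVPACurve(
        bin_starts_s=df["time_s"].to_numpy(),
        mean_accuracy=df["mean_acc"].to_numpy(),
        sd=df["sd"].to_numpy(),
        n_shuffles=int(df["n"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def write_snirf(path: str | Path, raw: RawRecording) -> None:
    """Write continuous-wave raw intensity to a SNIRF (HDF5) file.

    Channels are encoded as one source-detector pair per measurement
    channel (sourceIndex == detectorIndex == channel + 1), which keeps
    the montage geometry abstract but the data layout standard.
    """
    montage = raw.montage
    n_ch, n_wl, n_t = raw.intensity.shape
    data = raw.intensity.reshape(n_ch * n_wl, n_t).T  # time x measurement
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset(
            "wavelengths", data=np.asarray(montage.wavelengths_nm, dtype=float)
        )
        pos = np.zeros((n_ch, 3))
        pos[:, 0] = np.arange(n_ch) * montage.separation_cm
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=raw.times_s)
        idx = 0
        for ch in range(n_ch):
            for w in range(n_wl):
                idx += 1
                ml = d1.create_group(f"measurementList{idx}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)


def read_snirf(path: str | Path) -> RawRecording:
    """Read a continuous-wave SNIRF file written by :func:`write_snirf`
    (or any file using the same one-pair-per-channel encoding)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        wavelengths = tuple(float(w) for w in nirs["probe/wavelengths"][()])
        d1 = nirs["data1"]
        data = d1["dataTimeSeries"][()]
        time = d1["time"][()]
        n_meas = data.shape[1]
        meta = []
        for idx in range(1, n_meas + 1):
            ml = d1[f"measurementList{idx}"]
            meta.append(
                (int(ml["sourceIndex"][()]), int(ml["wavelengthIndex"][()]))
            )
    channels = sorted({s for s, _ in meta})
    n_ch, n_wl = len(channels), len(wavelengths)
    fs = 1.0 / float(np.median(np.diff(time)))
    montage = Montage(
        n_channels=n_ch, wavelengths_nm=wavelengths, sampling_rate_hz=fs
    )
    intensity = np.empty((n_ch, n_wl, data.shape[0]))
    for col, (src, wl_idx) in enumerate(meta):
        intensity[src - 1, wl_idx - 1] = data[:, col]
    return RawRecording(intensity=intensity, montage=montage)
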