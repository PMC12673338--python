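"""Real-time feedback-score loop.

Each training block has two phases: a 15 s relaxation baseline and a
25 s regulation period. Baseline statistics (per-feature mean and SD at
the native sampling rate) are computed per block. During regulation,
every 0.1 s the trailing 1-s window is sub-sampled at 10 Hz, reduced to
the decoder's selected features, averaged, z-scored against the
baseline, and passed to the per-second model for the elapsed time;
the model emits the probability of the incongruent pattern
(0 <= score <= 1). The on-screen disk accumulates these probabilities;
here the block score is 100 x the mean instantaneous score (other
accumulation operators are available).

Every update uses only samples strictly before its time point, so
replaying a recorded stream reproduces the online scores exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ConcentrationSeries
from .mvpa import FeatureSpec, TimeResolvedDecoder, signal_stack

ACCUMULATORS = ("mean", "sum", "leaky")


@dataclass
class BaselineStats:
    """Per-feature mean and SD over the relaxation baseline."""

    mean: np.ndarray
    sd: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal shape")


@dataclass
class FeedbackTrace:
    """Instantaneous and accumulated scores for one block."""

    times_s: np.ndarray
    scores: np.ndarray
    block_score: float
    accumulator: str = "mean"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("instantaneous scores must lie in [0, 1]")


def feature_matrix(conc: ConcentrationSeries, spec: FeatureSpec) -> np.ndarray:
    """(n_selected_features, T) native-rate matrix for a feature spec."""
    full = signal_stack(conc)
    idx = spec.indices_in(FeatureSpec.complete(conc.n_channels))
    return full[idx]


def compute_baseline(
    conc: ConcentrationSeries,
    spec: FeatureSpec,
    duration_s: float = 15.0,
) -> BaselineStats:
    """Baseline mean/SD per selected feature from the stream's start.

    Raises if the stream is shorter than the baseline or if any feature
    has zero variance (its z-score would be undefined).
    """
    fs = conc.sampling_rate_hz
    n = int(round(duration_s * fs))
    if conc.n_samples < n:
        raise ValueError(
            f"stream provides {conc.n_samples} samples; baseline needs {n}"
        )
    feats = feature_matrix(conc, spec)[:, :n]
    mu = feats.mean(axis=1)
    sd = feats.std(axis=1, ddof=0)
    if np.any(sd == 0):
        f = int(np.argmax(sd == 0))
        raise ValueError(
            f"zero variance in baseline for feature {spec.features[f]}"
        )
    return BaselineStats(mean=mu, sd=sd, duration_s=duration_s)


def window_features(
    feats: np.ndarray,
    sampling_rate_hz: float,
    t_i_s: float,
    width_s: float = 1.0,
    rate_hz: float = 10.0,
) -> np.ndarray:
    """Average of the trailing window's 10 Hz sub-samples at time ``t_i_s``.

    Sub-samples are taken at the midpoints of the ``1/rate`` slots
    tiling [t_i - width, t_i) — all strictly before ``t_i``, keeping the
    loop causal — and mapped to the nearest preceding native-rate
    sample. For a linear ramp the average is the window-midpoint value.
    """
    n_sub = int(round(width_s * rate_hz))
    sub_t = t_i_s - ((np.arange(1, n_sub + 1) - 0.5) / rate_hz)
    if sub_t.min() < -1e-9:
        raise ValueError(
            f"insufficient history at t={t_i_s:.2f} s for a {width_s} s window"
        )
    idx = np.floor(sub_t * sampling_rate_hz + 1e-9).astype(int)
    if idx.max() >= feats.shape[1]:
        raise ValueError(f"stream underrun at t={t_i_s:.2f} s")
    return feats[:, idx].mean(axis=1)


def zscore(y: np.ndarray, baseline: BaselineStats) -> np.ndarray:
    """Elementwise standardization against the block baseline."""
    return (np.asarray(y, dtype=float) - baseline.mean) / baseline.sd


def instantaneous_score(
    decoder: TimeResolvedDecoder, z: np.ndarray, elapsed_s: float
) -> float:
    """Incongruent-class probability from the model at bin floor(elapsed).

    Elapsed times outside the decoder's trained bins are clamped to the
    nearest model with a warning.
    """
    target = np.floor(elapsed_s)
    in_range = np.any(np.isclose(decoder.bin_times_s, target))
    if not in_range:
        warnings.warn(
            f"elapsed time {elapsed_s:.1f} s outside decoder bins; "
            "clamping to nearest model",
            stacklevel=2,
        )
    j = decoder.bin_index(elapsed_s, clamp=True)
    return float(decoder.predict_proba(z, j)[0])


def run_block(
    decoder: TimeResolvedDecoder,
    conc: ConcentrationSeries,
    baseline_s: float = 15.0,
    regulate_s: float = 25.0,
    rate_hz: float = 10.0,
    accumulator: str = "mean",
    leak: float = 0.9,
) -> FeedbackTrace:
    """Score one feedback block from a concentration stream.

    The stream must cover ``baseline_s + regulate_s``. Updates occur at
    ``rate_hz`` during regulation (250 scores at the defaults); the
    block score is 100 x the mean instantaneous probability (or the sum
    / leaky-integrated variant).
    """
    if accumulator not in ACCUMULATORS:
        raise ValueError(f"accumulator must be one of {ACCUMULATORS}")
    fs = conc.sampling_rate_hz
    needed = int(round((baseline_s + regulate_s) * fs))
    if conc.n_samples < needed:
        raise ValueError(
            f"stream underrun: have {conc.n_samples} samples, block needs "
            f"{needed} (position {conc.n_samples / fs:.2f} s)"
        )
    spec = decoder.feature_spec
    baseline = compute_baseline(conc, spec, duration_s=baseline_s)
    feats = feature_matrix(conc, spec)
    n_scores = int(round(regulate_s * rate_hz))
    times = baseline_s + (np.arange(1, n_scores + 1) / rate_hz)
    scores = np.empty(n_scores)
    for i, t in enumerate(times):
        y = window_features(feats, fs, t, width_s=1.0, rate_hz=rate_hz)
        z = zscore(y, baseline)
        elapsed = t - baseline_s
        scores[i] = instantaneous_score(decoder, z, min(elapsed, regulate_s - 1e-9))
    if accumulator == "mean":
        block_score = 100.0 * scores.mean()
    elif accumulator == "sum":
        block_score = float(scores.sum())
    else:
        acc = 0.0
        for s in scores:
            acc = leak * acc + (1 - leak) * s
        block_score = 100.0 * acc
    return FeedbackTrace(
        times_s=times,
        scores=scores,
        block_score=block_score,
        accumulator=accumulator,
    )


@dataclass
class SessionSummary:
    """Per-block and aggregate feedback scores for one training session."""

    block_scores: np.ndarray
    mean_score: float
    sd_score: float
    n_blocks: int
    rest_every: int
    decoder_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "block_scores": self.block_scores.tolist(),
            "mean_score": self.mean_score,
            "sd_score": self.sd_score,
            "n_blocks": self.n_blocks,
            "rest_every": self.rest_every,
            "decoder_meta": self.decoder_meta,
        }


def run_session(
    decoder: TimeResolvedDecoder,
    participant,
    n_blocks: int = 30,
    rest_every: int = 5,
    baseline_s: float = 15.0,
    regulate_s: float = 25.0,
    rate_hz: float = 10.0,
) -> SessionSummary:
    """Run a full training session against a participant source.

    ``participant`` must provide ``next_block(baseline_s, regulate_s)``
    returning a :class:`ConcentrationSeries` (the virtual participant in
    :mod:`fnirs_decnef.synthetic` does). The 1-min rests after every
    fifth block carry no signal; they are recorded as metadata only.
    """
    scores = np.empty(n_blocks)
    for b in range(n_blocks):
        conc = participant.next_block(baseline_s, regulate_s)
        trace = run_block(
            decoder,
            conc,
            baseline_s=baseline_s,
            regulate_s=regulate_s,
            rate_hz=rate_hz,
        )
        scores[b] = trace.block_score
    return SessionSummary(
        block_scores=scores,
        mean_score=float(scores.mean()),
        sd_score=float(scores.std(ddof=1)) if n_blocks > 1 else 0.0,
        n_blocks=n_blocks,
        rest_every=rest_every,
        decoder_meta=dict(decoder.meta),
    )
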