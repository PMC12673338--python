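"""Time-resolved multivariate pattern analysis and decoder construction.

For a 35-channel montage each 1-s time bin yields a 140-dimensional
pattern per block: HbO, HbR, and their first temporal derivatives per
channel. Decoding proceeds per bin with a shuffle-bin-average
leave-one-out linear-SVM procedure:

1. within each condition, blocks are randomly permuted;
2. each condition's blocks are partitioned into 4 near-equal bins and
   bin-averaged, giving 8 averaged patterns (4 congruent + 4 incongruent);
3. leave-one-pair-out cross-validation over the 4 pairs with a linear
   SVM gives an accuracy out of 8 test classifications;
4. the shuffle is repeated (default 100 times) and accuracies averaged;
5. repeating over every 1-s bin in the [-5, 25] s window yields the
   time-resolved accuracy curve.

Feature screening ranks the 140 candidates by their single-feature
accuracy in the 10-17 s post-stimulus window and keeps the best 35.
The final product is one probability-emitting linear model per 1-s bin
(the decoder "changes every second") sharing a single screened feature
space, persisted as a JSON bundle for the online feedback loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import CONGRUENT, INCONGRUENT, ConcentrationSeries, EventSchedule

SIGNAL_KINDS = ("hbo", "hbr", "dhbo", "dhbr")


# ---------------------------------------------------------------------------
# feature space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Ordered list of (channel index, signal kind) features.

    The complete space for ``n`` channels has ``4 n`` features ordered
    kind-major: all HbO channels, all HbR, then the two derivative sets.
    """

    features: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        feats = tuple((int(c), str(k)) for c, k in self.features)
        if len(set(feats)) != len(feats):
            raise ValueError("feature list contains duplicates")
        for _, kind in feats:
            if kind not in SIGNAL_KINDS:
                raise ValueError(f"unknown signal kind {kind!r}")
        object.__setattr__(self, "features", feats)

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def complete(cls, n_channels: int) -> "FeatureSpec":
        return cls(
            tuple(
                (ch, kind) for kind in SIGNAL_KINDS for ch in range(n_channels)
            )
        )

    def indices_in(self, parent: "FeatureSpec") -> np.ndarray:
        """Positions of this spec's features inside ``parent``."""
        lookup = {f: i for i, f in enumerate(parent.features)}
        try:
            return np.array([lookup[f] for f in self.features])
        except KeyError as err:  # pragma: no cover - defensive
            raise ValueError(f"feature {err} not present in parent spec")

    def of_kind(self, kind: str) -> "FeatureSpec":
        if kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {kind!r}")
        return FeatureSpec(tuple(f for f in self.features if f[1] == kind))


@dataclass
class PatternTensor:
    """Per-block, per-bin feature patterns plus block metadata.

    ``data`` has shape (n_blocks, n_features, n_bins) with bins on a 1-s
    grid starting at ``bin_starts_s`` (bin t covers [t, t+1) s relative
    to block onset). ``baseline_mean``/``baseline_sd`` are per-block
    native-rate statistics over the pre-stimulus window, used to z-score
    patterns the same way the online loop z-scores its input.
    """

    data: np.ndarray
    labels: np.ndarray
    bin_starts_s: np.ndarray
    feature_spec: FeatureSpec
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.bin_starts_s = np.asarray(self.bin_starts_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (blocks, features, bins)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per block required")
        if self.data.shape[1] != len(self.feature_spec):
            raise ValueError("feature axis inconsistent with feature spec")
        if len(self.bin_starts_s) != self.data.shape[2]:
            raise ValueError("bin axis inconsistent with bin starts")

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def class_patterns(self, bin_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(congruent, incongruent) pattern matrices at one time bin."""
        at = self.data[:, :, bin_index]
        return at[self.labels == CONGRUENT], at[self.labels == INCONGRUENT]

    def select_features(self, spec: FeatureSpec) -> "PatternTensor":
        idx = spec.indices_in(self.feature_spec)
        return PatternTensor(
            data=self.data[:, idx, :],
            labels=self.labels.copy(),
            bin_starts_s=self.bin_starts_s.copy(),
            feature_spec=spec,
            baseline_mean=self.baseline_mean[:, idx],
            baseline_sd=self.baseline_sd[:, idx],
        )

    def select_window(self, t0_s: float, t1_s: float) -> "PatternTensor":
        """Bins whose start time lies in [t0_s, t1_s] (inclusive)."""
        keep = (self.bin_starts_s >= t0_s - 1e-9) & (self.bin_starts_s <= t1_s + 1e-9)
        if not keep.any():
            raise ValueError("no bins inside the requested window")
        return PatternTensor(
            data=self.data[:, :, keep],
            labels=self.labels.copy(),
            bin_starts_s=self.bin_starts_s[keep],
            feature_spec=self.feature_spec,
            baseline_mean=self.baseline_mean.copy(),
            baseline_sd=self.baseline_sd.copy(),
        )

    def first_blocks(self, n_per_condition: int) -> "PatternTensor":
        """Restrict to the first ``n_per_condition`` blocks of each condition,
        preserving session order."""
        keep = np.zeros(self.n_blocks, dtype=bool)
        for cond in (CONGRUENT, INCONGRUENT):
            idx = np.flatnonzero(self.labels == cond)
            if len(idx) < n_per_condition:
                raise ValueError(
                    f"only {len(idx)} {cond} blocks available, "
                    f"{n_per_condition} requested"
                )
            keep[idx[:n_per_condition]] = True
        return PatternTensor(
            data=self.data[keep],
            labels=self.labels[keep],
            bin_starts_s=self.bin_starts_s.copy(),
            feature_spec=self.feature_spec,
            baseline_mean=self.baseline_mean[keep],
            baseline_sd=self.baseline_sd[keep],
        )


def signal_stack(conc: ConcentrationSeries) -> np.ndarray:
    """(4*n_channels, T) stack of HbO, HbR and their first derivatives.

    Derivatives are central differences at the native rate (one-sided at
    the edges), in uM/s. Row order matches ``FeatureSpec.complete``.
    """
    fs = conc.sampling_rate_hz
    dhbo = np.gradient(conc.hbo, axis=1) * fs
    dhbr = np.gradient(conc.hbr, axis=1) * fs
    return np.concatenate([conc.hbo, conc.hbr, dhbo, dhbr], axis=0)


def extract_patterns(
    conc: ConcentrationSeries,
    schedule: EventSchedule,
    window_s: tuple[float, float] = (-5.0, 25.0),
) -> PatternTensor:
    """Build the block x feature x time-bin tensor from concentrations.

    Each 1-s bin value is the mean of the native-rate samples falling in
    [t, t+1) s relative to block onset; the window produces bins at every
    integer start from ``window_s[0]`` through ``window_s[1]`` (31 bins
    for the default [-5, 25] s window).
    """
    fs = conc.sampling_rate_hz
    t0, t1 = window_s
    starts = np.arange(np.ceil(t0), np.floor(t1) + 1)
    stack = signal_stack(conc)
    n_feat = stack.shape[0]
    spec = FeatureSpec.complete(conc.n_channels)
    n_blocks = schedule.n_blocks
    data = np.empty((n_blocks, n_feat, len(starts)))
    base_mu = np.empty((n_blocks, n_feat))
    base_sd = np.empty((n_blocks, n_feat))
    for b, onset in enumerate(schedule.block_onsets_s):
        for j, t in enumerate(starts):
            i0 = int(round((onset + t) * fs))
            i1 = int(round((onset + t + 1.0) * fs))
            if i0 < 0 or i1 > stack.shape[1]:
                raise ValueError(
                    f"bin [{t}, {t + 1}) s of block {b} outside the recording"
                )
            data[b, :, j] = stack[:, i0:i1].mean(axis=1)
        j0 = int(round((onset + t0) * fs))
        j1 = int(round(onset * fs))
        if j0 < 0:
            raise ValueError(f"baseline window of block {b} outside the recording")
        base_mu[b] = stack[:, j0:j1].mean(axis=1)
        base_sd[b] = stack[:, j0:j1].std(axis=1, ddof=0)
    return PatternTensor(
        data=data,
        labels=np.asarray(schedule.conditions),
        bin_starts_s=starts,
        feature_spec=spec,
        baseline_mean=base_mu,
        baseline_sd=base_sd,
    )


# ---------------------------------------------------------------------------
# shuffle - bin - average - LOOCV accuracy
# ---------------------------------------------------------------------------

def bin_and_average(
    congruent: np.ndarray,
    incongruent: np.ndarray,
    n_bins: int = 4,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle each class and average within near-equal partitions.

    Returns (averaged_congruent, averaged_incongruent), each of shape
    (n_bins, n_features). Partition sizes differ by at most one (e.g.
    30 blocks -> {8, 8, 7, 7}; 14 -> {4, 4, 3, 3}).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    for patterns in (congruent, incongruent):
        patterns = np.asarray(patterns, dtype=float)
        n = patterns.shape[0]
        if n < n_bins:
            raise ValueError(f"{n} patterns cannot fill {n_bins} bins")
        perm = rng.permutation(n)
        parts = np.array_split(perm, n_bins)
        out.append(np.stack([patterns[p].mean(axis=0) for p in parts]))
    return out[0], out[1]


def loocv_accuracy(
    averaged_congruent: np.ndarray,
    averaged_incongruent: np.ndarray,
    C: float = 1.0,
) -> float:
    """Leave-one-pair-out linear-SVM accuracy over averaged patterns.

    With ``n`` averaged patterns per class, fold ``i`` holds out the
    i-th congruent and i-th incongruent pattern, trains a linear SVM on
    the remaining ``2(n-1)``, and tests on the held-out pair; accuracy
    is the fraction of correct test classifications over all ``2n``.
    """
    a = np.asarray(averaged_congruent, dtype=float)
    b = np.asarray(averaged_incongruent, dtype=float)
    if a.shape != b.shape:
        raise ValueError("class pattern sets must be balanced and equal-shape")
    n = a.shape[0]
    correct = 0
    labels = np.array([0] * (n - 1) + [1] * (n - 1))
    for i in range(n):
        keep = np.arange(n) != i
        x_train = np.vstack([a[keep], b[keep]])
        x_test = np.vstack([a[i], b[i]])
        clf = SVC(kernel="linear", C=C)
        clf.fit(x_train, labels)
        pred = clf.predict(x_test)
        correct += int(pred[0] == 0) + int(pred[1] == 1)
    return correct / (2 * n)


def shuffle_accuracy(
    congruent: np.ndarray,
    incongruent: np.ndarray,
    n_bins: int = 4,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
) -> float:
    """One shuffle-bin-average-LOOCV draw (steps 1-3 of the procedure)."""
    avg_c, avg_i = bin_and_average(congruent, incongruent, n_bins, rng)
    return loocv_accuracy(avg_c, avg_i, C=C)


@dataclass
class MVPACurve:
    """Time-resolved mean classification accuracy with shuffle spread."""

    bin_starts_s: np.ndarray
    mean_accuracy: np.ndarray
    sd: np.ndarray
    n_shuffles: int

    def window_mean(self, t0_s: float, t1_s: float) -> float:
        keep = (self.bin_starts_s >= t0_s - 1e-9) & (
            self.bin_starts_s <= t1_s + 1e-9
        )
        if not keep.any():
            raise ValueError("no bins inside the requested window")
        return float(self.mean_accuracy[keep].mean())


def time_resolved_accuracy(
    patterns: PatternTensor,
    n_shuffles: int = 100,
    seed: int | None = None,
    n_bins: int = 4,
    C: float = 1.0,
) -> MVPACurve:
    """Mean LOOCV accuracy per 1-s bin over independent shuffles.

    A single master seed spawns one independent stream per (bin,
    shuffle), so curves are reproducible and bins are uncorrelated.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(patterns.n_bins)
    means = np.empty(patterns.n_bins)
    sds = np.empty(patterns.n_bins)
    for j in range(patterns.n_bins):
        cong, incong = patterns.class_patterns(j)
        rng = np.random.default_rng(children[j])
        accs = np.array(
            [
                shuffle_accuracy(cong, incong, n_bins, rng, C=C)
                for _ in range(n_shuffles)
            ]
        )
        means[j] = accs.mean()
        sds[j] = accs.std(ddof=1) if n_shuffles > 1 else 0.0
    return MVPACurve(
        bin_starts_s=patterns.bin_starts_s.copy(),
        mean_accuracy=means,
        sd=sds,
        n_shuffles=n_shuffles,
    )


# ---------------------------------------------------------------------------
# feature screening
# ---------------------------------------------------------------------------

def screen_features(
    patterns: PatternTensor,
    window_s: tuple[float, float] = (10.0, 17.0),
    k: int = 35,
    n_shuffles: int = 20,
    seed: int | None = None,
) -> FeatureSpec:
    """Rank features by single-feature accuracy; keep the top ``k``.

    Each candidate is scored by its own time-resolved accuracy averaged
    over the ranking window (default 10-17 s post-stimulus, reduced
    shuffle count for tractability — screening is rank-based). Ties are
    broken toward the lower feature index. ``k`` equal to the number of
    candidates returns the identity spec in original order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > patterns.n_features:
        raise ValueError("k exceeds the number of candidate features")
    if k == patterns.n_features:
        return patterns.feature_spec
    windowed = patterns.select_window(*window_s)
    children = np.random.SeedSequence(seed).spawn(patterns.n_features)
    scores = np.empty(patterns.n_features)
    for f in range(patterns.n_features):
        sub = PatternTensor(
            data=windowed.data[:, [f], :],
            labels=windowed.labels,
            bin_starts_s=windowed.bin_starts_s,
            feature_spec=FeatureSpec((patterns.feature_spec.features[f],)),
            baseline_mean=windowed.baseline_mean[:, [f]],
            baseline_sd=windowed.baseline_sd[:, [f]],
        )
        curve = time_resolved_accuracy(
            sub,
            n_shuffles=n_shuffles,
            seed=int(children[f].generate_state(1)[0] % (2**31)),
        )
        scores[f] = curve.mean_accuracy.mean()
    order = np.argsort(-scores, kind="stable")[:k]
    order = np.sort(order)  # keep original feature ordering inside the subset
    return FeatureSpec(tuple(patterns.feature_spec.features[i] for i in order))


# ---------------------------------------------------------------------------
# decoder training and persistence
# ---------------------------------------------------------------------------

@dataclass
class TimeResolvedDecoder:
    """One probability-calibrated linear model per 1-s time bin.

    ``weights``/``bias`` are the linear-SVM hyperplanes per bin on the
    z-scored screened features; ``platt_a``/``platt_b`` map the SVM
    margin to the incongruent-class probability via the logistic
    sigmoid(a * margin + b). A single :class:`FeatureSpec` is shared by
    every bin, matching the fixed online feature space.
    """

    bin_times_s: np.ndarray
    weights: np.ndarray
    bias: np.ndarray
    platt_a: np.ndarray
    platt_b: np.ndarray
    feature_spec: FeatureSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_times_s = np.asarray(self.bin_times_s, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n_bins = len(self.bin_times_s)
        if self.weights.shape != (n_bins, len(self.feature_spec)):
            raise ValueError("weights shape inconsistent with bins/features")

    @property
    def n_models(self) -> int:
        return len(self.bin_times_s)

    def bin_index(self, time_s: float, clamp: bool = True) -> int:
        """Model index whose bin start is floor(time_s)."""
        target = np.floor(time_s)
        matches = np.flatnonzero(np.isclose(self.bin_times_s, target))
        if matches.size:
            return int(matches[0])
        if not clamp:
            raise ValueError(f"no model for time {time_s} s")
        return int(np.argmin(np.abs(self.bin_times_s - target)))

    def margin(self, z: np.ndarray, bin_index: int) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return z @ self.weights[bin_index] + self.bias[bin_index]

    def predict_proba(self, z: np.ndarray, bin_index: int) -> np.ndarray:
        """Probability of the incongruent class; bounded in (0, 1)."""
        m = self.margin(z, bin_index)
        logit = np.clip(
            self.platt_a[bin_index] * m + self.platt_b[bin_index], -500, 500
        )
        return 1.0 / (1.0 + np.exp(-logit))

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "fnirs-decnef-decoder/1",
            "bin_times_s": self.bin_times_s.tolist(),
            "weights": self.weights.tolist(),
            "bias": np.asarray(self.bias).tolist(),
            "platt_a": np.asarray(self.platt_a).tolist(),
            "platt_b": np.asarray(self.platt_b).tolist(),
            "features": [[ch, kind] for ch, kind in self.feature_spec.features],
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TimeResolvedDecoder":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "fnirs-decnef-decoder/1":
            raise ValueError("unrecognized decoder bundle format")
        return cls(
            bin_times_s=np.array(payload["bin_times_s"]),
            weights=np.array(payload["weights"]),
            bias=np.array(payload["bias"]),
            platt_a=np.array(payload["platt_a"]),
            platt_b=np.array(payload["platt_b"]),
            feature_spec=FeatureSpec(
                tuple((int(c), str(k)) for c, k in payload["features"])
            ),
            meta=payload.get("meta", {}),
        )


def zscore_patterns(patterns: PatternTensor) -> np.ndarray:
    """Z-score each block's patterns against its own pre-stimulus baseline.

    Mirrors the online loop, which standardizes incoming features by the
    baseline-period mean and SD, so training and inference see the same
    input distribution. Returns (n_blocks, n_features, n_bins).
    """
    sd = patterns.baseline_sd
    if np.any(sd <= 0):
        b, f = np.unravel_index(int(np.argmax(sd <= 0)), sd.shape)
        raise ValueError(
            f"zero baseline variance for block {b}, feature "
            f"{patterns.feature_spec.features[f]}"
        )
    return (patterns.data - patterns.baseline_mean[:, :, None]) / sd[:, :, None]


def train_decoder(
    patterns: PatternTensor,
    feature_spec: FeatureSpec | None = None,
    seed: int | None = None,
    C: float = 1.0,
) -> TimeResolvedDecoder:
    """Fit the per-second probability-emitting linear models.

    Per bin: a linear SVM (C=1) on all blocks' z-scored screened
    features, followed by Platt scaling — a logistic fit on
    cross-validated decision values — so the online score is a
    calibrated incongruent-class probability.
    """
    if feature_spec is not None:
        patterns = patterns.select_features(feature_spec)
    labels = np.asarray(patterns.labels)
    y = (labels == INCONGRUENT).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both conditions are required to train a decoder")
    z = zscore_patterns(patterns)
    n_bins = patterns.n_bins
    k = patterns.n_features
    weights = np.empty((n_bins, k))
    bias = np.empty(n_bins)
    pa = np.empty(n_bins)
    pb = np.empty(n_bins)
    rng = np.random.default_rng(seed)
    for j in range(n_bins):
        x = z[:, :, j]
        clf = SVC(kernel="linear", C=C)
        clf.fit(x, y)
        weights[j] = clf.coef_[0]
        bias[j] = clf.intercept_[0]
        # Platt scaling on cross-validated margins
        df = np.empty(len(y))
        skf = StratifiedKFold(
            n_splits=3, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for tr, te in skf.split(x, y):
            fold = SVC(kernel="linear", C=C)
            fold.fit(x[tr], y[tr])
            df[te] = fold.decision_function(x[te])
        platt = LogisticRegression(C=1e6, max_iter=1000)
        platt.fit(df[:, None], y)
        pa[j] = platt.coef_[0, 0]
        pb[j] = platt.intercept_[0]
    return TimeResolvedDecoder(
        bin_times_s=patterns.bin_starts_s.copy(),
        weights=weights,
        bias=bias,
        platt_a=pa,
        platt_b=pb,
        feature_spec=patterns.feature_spec,
        meta={
            "n_blocks": {
                CONGRUENT: int((labels == CONGRUENT).sum()),
                INCONGRUENT: int((labels == INCONGRUENT).sum()),
            },
            "seed": seed,
            "C": C,
        },
    )


def train_sham_decoder(
    patterns: PatternTensor,
    n_per_condition: int = 14,
    screen_k: int = 35,
    screen_window_s: tuple[float, float] = (10.0, 17.0),
    screen_shuffles: int = 20,
    seed: int | None = None,
) -> TimeResolvedDecoder:
    """Decoder trained on a reduced sample (first 14 blocks per condition).

    Runs the identical pipeline — screening then per-bin training — but
    restricted to the first ``n_per_condition`` blocks of each
    condition, which degrades accuracy toward chance while leaving the
    feedback procedure unchanged (the sham-control mechanism).
    """
    reduced = patterns.first_blocks(n_per_condition)
    ss = np.random.SeedSequence(seed)
    s_screen, s_train = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    k = min(screen_k, reduced.n_features)
    spec = screen_features(
        reduced,
        window_s=screen_window_s,
        k=k,
        n_shuffles=screen_shuffles,
        seed=s_screen,
    )
    decoder = train_decoder(reduced, spec, seed=s_train)
    decoder.meta["sham"] = True
    decoder.meta["n_training_blocks"] = int(reduced.n_blocks)
    return decoder


def build_decoder(
    patterns: PatternTensor,
    screen_k: int = 35,
    screen_window_s: tuple[float, float] = (10.0, 17.0),
    screen_shuffles: int = 20,
    seed: int | None = None,
) -> TimeResolvedDecoder:
    """Full-sample decoder: screening on all blocks, then per-bin training."""
    ss = np.random.SeedSequence(seed)
    s_screen, s_train = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    k = min(screen_k, patterns.n_features)
    spec = screen_features(
        patterns,
        window_s=screen_window_s,
        k=k,
        n_shuffles=screen_shuffles,
        seed=s_screen,
    )
    decoder = train_decoder(patterns, spec, seed=s_train)
    decoder.meta["sham"] = False
    decoder.meta["n_training_blocks"] = int(patterns.n_blocks)
    return decoder
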