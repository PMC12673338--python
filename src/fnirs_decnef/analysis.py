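"""Offline statistics: Stroop effects, mixed ANOVA, pointwise t-tests,
accuracy-behavior correlation, chromophore comparison, and the
repeated-measures power computation.

Behavioral inputs are tidy trial-level DataFrames (subject, group,
stage, condition, rt_ms, correct); the ANOVAs are delegated to
pingouin, the field-standard implementation, and every statistic is
cross-checked against hand-formula oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .mvpa import MVPACurve, PatternTensor, SIGNAL_KINDS, time_resolved_accuracy


# ---------------------------------------------------------------------------
# Stroop effects
# ---------------------------------------------------------------------------

def stroop_effect(behavior: pd.DataFrame, correct_only: bool = True) -> pd.DataFrame:
    """Per subject x stage Stroop effects.

    ``rt_effect_ms`` is the incongruent - congruent mean RT difference
    (correct trials only by default; error trials confound RT with
    failure modes); ``acc_effect`` is the proportion-correct difference
    computed over all trials.
    """
    required = {"subject", "group", "stage", "condition", "rt_ms", "correct"}
    missing = required - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    rows = []
    for (subject, group, stage), cell in behavior.groupby(
        ["subject", "group", "stage"], sort=False
    ):
        rt_source = cell[cell["correct"]] if correct_only else cell
        means = rt_source.groupby("condition")["rt_ms"].mean()
        accs = cell.groupby("condition")["correct"].mean()
        for cond in ("congruent", "incongruent"):
            if cond not in means.index or cell[cell["condition"] == cond].empty:
                raise ValueError(
                    f"no usable {cond} trials for subject {subject!r}, "
                    f"stage {stage!r}"
                )
        rows.append(
            {
                "subject": subject,
                "group": group,
                "stage": stage,
                "rt_effect_ms": means["incongruent"] - means["congruent"],
                "acc_effect": accs["incongruent"] - accs["congruent"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(
    effects: pd.DataFrame,
    dv: str = "rt_effect_ms",
    within: str = "stage",
    between: str = "group",
    subject: str = "subject",
) -> pd.DataFrame:
    """Two-way mixed ANOVA (between-group x within-stage).

    Returns one row per source (between main effect, within main
    effect, interaction) with F, degrees of freedom, p, and partial
    eta-squared. Requires a complete balanced-within design (every
    subject observed at every within level).
    """
    counts = effects.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("each subject must have exactly one row per stage")
    per_subj = effects.groupby(subject)[within].nunique()
    if per_subj.nunique() != 1:
        raise ValueError("missing cells: subjects differ in observed stages")
    if effects[between].nunique() < 2 or effects[within].nunique() < 2:
        raise ValueError("both factors need at least two levels")
    table = pg.mixed_anova(
        data=effects, dv=dv, within=within, between=between, subject=subject
    )
    out = table.rename(
        columns={
            "Source": "source",
            "p-unc": "p",
            "p_unc": "p",
            "np2": "partial_eta_sq",
        }
    )
    return out[["source", "SS", "DF1", "DF2", "F", "p", "partial_eta_sq"]]


# ---------------------------------------------------------------------------
# point-by-point paired t-tests
# ---------------------------------------------------------------------------

@dataclass
class PointwiseTestResult:
    """Per-sample paired-t statistics and the significant time intervals."""

    times_s: np.ndarray
    t: np.ndarray
    p: np.ndarray
    alpha: float
    significant_intervals_s: list[tuple[float, float]]


def pointwise_paired_t(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times_s: np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
) -> PointwiseTestResult:
    """Paired t-test at every time sample, with contiguous-run reporting.

    ``series_a``/``series_b`` are (n_subjects, n_times) paired
    observations on a common time grid. Maximal runs of p < alpha are
    reported as [start, end] second intervals (uncorrected by default;
    ``fdr`` applies Benjamini-Hochberg before thresholding).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired series must be equal-shape (subjects, times)")
    if a.shape[0] < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    if a.shape[1] != len(times_s):
        raise ValueError("time grid does not match the series")
    t_stat, p_val = stats.ttest_rel(a, b, axis=0)
    p_thresh = p_val.copy()
    if fdr:
        p_thresh = stats.false_discovery_control(p_val)
    sig = p_thresh < alpha
    intervals: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8), [0]])))
    for i in range(0, len(edges), 2):
        start, stop = edges[i], edges[i + 1]
        intervals.append((float(times_s[start]), float(times_s[stop - 1])))
    return PointwiseTestResult(
        times_s=times_s,
        t=np.asarray(t_stat),
        p=np.asarray(p_val),
        alpha=alpha,
        significant_intervals_s=intervals,
    )


# ---------------------------------------------------------------------------
# accuracy vs. behavior
# ---------------------------------------------------------------------------

def accuracy_behavior_correlation(
    window_accuracy: np.ndarray,
    behavioral_change: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation of per-subject decoding accuracy with behavior.

    ``window_accuracy`` is each subject's mean classification accuracy
    over the ranking window (10-17 s by default upstream);
    ``behavioral_change`` is the matched behavioral quantity (default
    convention: post minus pre change in the RT Stroop effect).
    """
    x = np.asarray(window_accuracy, dtype=float)
    y = np.asarray(behavioral_change, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matched 1-D arrays")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def curve_window_accuracies(
    curves: list[MVPACurve], window_s: tuple[float, float] = (10.0, 17.0)
) -> np.ndarray:
    """Window-mean accuracy per subject curve."""
    return np.array([c.window_mean(*window_s) for c in curves])


# ---------------------------------------------------------------------------
# chromophore / feature-kind comparison
# ---------------------------------------------------------------------------

def chromophore_comparison(
    pattern_sets: list[PatternTensor],
    window_s: tuple[float, float] = (10.0, 17.0),
    n_shuffles: int = 20,
    seed: int | None = None,
) -> dict:
    """Decoding capability of each signal kind, compared across sessions.

    Restricts each session's patterns to one 35-feature kind (HbO, HbR,
    HbO', HbR'), computes its window-mean time-resolved accuracy, then
    runs a one-way repeated-measures ANOVA over kinds and all pairwise
    paired t-tests.

    Returns a dict with the per-kind accuracy table (sessions x kinds),
    the RM-ANOVA table, and the post hoc pairwise results.
    """
    if len(pattern_sets) < 2:
        raise ValueError("at least 2 sessions/subjects required")
    children = np.random.SeedSequence(seed).spawn(len(pattern_sets))
    rows = []
    for s, patterns in enumerate(pattern_sets):
        sub_seed = int(children[s].generate_state(1)[0] % (2**31))
        for kind in SIGNAL_KINDS:
            sub = patterns.select_features(patterns.feature_spec.of_kind(kind))
            curve = time_resolved_accuracy(
                sub.select_window(*window_s), n_shuffles=n_shuffles, seed=sub_seed
            )
            rows.append(
                {
                    "session": s,
                    "kind": kind,
                    "accuracy": curve.mean_accuracy.mean(),
                }
            )
    acc = pd.DataFrame(rows)
    anova = pg.rm_anova(
        data=acc, dv="accuracy", within="kind", subject="session", detailed=True
    )
    pairs = []
    kinds = list(SIGNAL_KINDS)
    wide = acc.pivot(index="session", columns="kind", values="accuracy")
    for i in range(len(kinds)):
        for j in range(i + 1, len(kinds)):
            t, p = stats.ttest_rel(wide[kinds[i]], wide[kinds[j]])
            pairs.append(
                {"a": kinds[i], "b": kinds[j], "t": float(t), "p": float(p)}
            )
    return {"accuracies": acc, "anova": anova, "posthoc": pd.DataFrame(pairs)}


# ---------------------------------------------------------------------------
# repeated-measures ANOVA power / sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Configuration of the within-between interaction power analysis.

    Follows the G*Power convention for "ANOVA: repeated measures,
    within-between interaction": effect size f, number of groups k,
    number of measurements m, repeated-measures correlation rho, and
    nonsphericity correction epsilon.
    """

    effect_size_f: float = 0.25
    alpha: float = 0.05
    power: float = 0.80
    n_groups: int = 2
    n_measurements: int = 2
    corr_rm: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be positive")
        if self.n_groups < 2 or self.n_measurements < 2:
            raise ValueError("need at least 2 groups and 2 measurements")
        if not -1 < self.corr_rm < 1:
            raise ValueError("repeated-measures correlation must be in (-1, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def interaction_power(total_n: int, spec: PowerSpec) -> float:
    """Achieved power of the within-between interaction at sample size N.

    Noncentral-F formulation:
    lambda = f^2 * N * m * eps / (1 - rho),
    df1 = (k - 1)(m - 1) eps, df2 = (N - k)(m - 1) eps.
    """
    k, m = spec.n_groups, spec.n_measurements
    if total_n <= k:
        raise ValueError("total N must exceed the number of groups")
    lam = spec.effect_size_f**2 * total_n * m * spec.epsilon / (1.0 - spec.corr_rm)
    df1 = (k - 1) * (m - 1) * spec.epsilon
    df2 = (total_n - k) * (m - 1) * spec.epsilon
    f_crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest balanced total N whose interaction power meets the target.

    Balanced means N is a multiple of the number of groups; the search
    increments one subject per group at a time.
    """
    k = spec.n_groups
    n_per_group = 2
    while True:
        total = k * n_per_group
        if total > max_n:
            raise ValueError(f"target power unreachable below N = {max_n}")
        if interaction_power(total, spec) >= spec.power:
            return total
        n_per_group += 1
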