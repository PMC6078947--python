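"""Session 1 sliding-window decoding of high- vs low-competition states.

For each window start time (20 ms grid), the per-channel means over the
next 50 ms form one feature vector per trial. A binary L2-penalized
logistic regression is evaluated by stratified 5-fold cross-validation at
each start time, within subject. Per-timepoint significance is a
within-subject permutation test (label shuffles re-running the full CV);
subject p values are combined by the inverse-normal transform and a
one-sample t-test of the z values against zero, Bonferroni-corrected at
``alpha / n_timepoints``. The discriminative time window is the contiguous
run of start times that are both group-significant and more than one
across-subject SD above chance, with short internal dips bridged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._exceptions import ConfigurationError
from .containers import ClassifierModel, DecodingCurve, EpochSet, WindowFeatures

__all__ = [
    "sliding_window_features",
    "fit_logistic",
    "crossval_decode",
    "within_subject_permutation_p",
    "PermutationDecodingResult",
    "group_significance",
    "select_time_window",
    "decode_localizer",
]

logger = logging.getLogger(__name__)


def sliding_window_features(
    epochs: EpochSet,
    window_ms: float = 50.0,
    step_ms: float = 20.0,
    tmin: float = 0.0,
    tmax: float | None = None,
) -> WindowFeatures:
    """Channel-mean features over half-open windows ``[t, t + window_ms)``.

    Start times run from ``tmin`` (default: stimulus onset) in ``step_ms``
    increments; a start time whose window extends past the end of the epoch
    is excluded (logged). Window membership is evaluated on the epoch's
    sample-time grid.
    """
    times = epochs.times
    if tmax is None:
        tmax = times[-1]
    starts = np.arange(tmin, tmax + 0.5 * step_ms, step_ms)
    # half-open windows must fit inside the sampled epoch
    last_time = times[-1] + 1000.0 / epochs.sfreq
    valid = starts + window_ms <= last_time + 1e-9
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("sliding_window_features: excluded %d windows past epoch end", n_excluded)
    starts = starts[valid]
    if starts.size == 0:
        raise ConfigurationError("no window fits inside the epoch")

    feats = np.empty((epochs.n_trials, starts.size, epochs.n_channels))
    for k, t0 in enumerate(starts):
        sel = (times >= t0 - 1e-9) & (times < t0 + window_ms - 1e-9)
        if not sel.any():
            raise ConfigurationError(f"window starting at {t0} ms contains no samples")
        feats[:, k, :] = epochs.data[:, :, sel].mean(axis=2)
    return WindowFeatures(
        features=feats, start_times=starts, window_ms=window_ms, metadata=epochs.metadata.copy()
    )


def fit_logistic(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, train_time: float = np.nan
) -> ClassifierModel:
    """Fit the binary L2 logistic regression used throughout the pipeline."""
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ConfigurationError("training labels must contain exactly two classes")
    clf = LogisticRegression(C=C, solver="liblinear")
    clf.fit(X, y)
    return ClassifierModel(
        weights=clf.coef_[0], intercept=float(clf.intercept_[0]), C=C, train_time=train_time
    )


def crossval_decode(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    standardize: bool = False,
) -> float:
    """Mean held-out accuracy of stratified k-fold L2 logistic decoding.

    Fold assignment is stratified, shuffled under ``seed``, and independent
    of trial order. Features are used on their native (common voltage)
    scale unless ``standardize`` is set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ConfigurationError("decoding requires exactly two classes")
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"minority class has {counts.min()} trials; cannot stratify into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    clf = LogisticRegression(C=C, solver="liblinear")
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf.fit(Xtr, y[train_idx])
        accs.append(float(np.mean(clf.predict(Xte) == y[test_idx])))
    return float(np.mean(accs))


@dataclass
class PermutationDecodingResult:
    """Observed CV accuracy with its within-subject permutation p value."""

    accuracy: float
    p: float
    null_accuracies: np.ndarray


def within_subject_permutation_p(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    n_folds: int = 5,
    C: float = 1.0,
) -> PermutationDecodingResult:
    """Permutation test of CV decoding accuracy against label exchange.

    Each permutation shuffles the labels and re-runs the full stratified CV.
    The p value uses the add-one estimator
    ``(1 + #{perm >= observed}) / (n_perm + 1)``, so p is always in (0, 1].
    """
    rng = np.random.default_rng(seed)
    observed = crossval_decode(X, y, n_folds=n_folds, seed=seed, C=C)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = crossval_decode(X, rng.permutation(y), n_folds=n_folds, seed=seed, C=C)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationDecodingResult(accuracy=observed, p=float(p), null_accuracies=null)


def group_significance(
    p_matrix: np.ndarray, alpha: float = 0.001, n_perm: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Combine within-subject permutation p values across subjects.

    Each p is clipped to ``[1/(n_perm+1), 1 - 1/(n_perm+1)]`` (keeping the
    inverse-normal z finite for p values on the permutation grid) and
    transformed as ``z = Phi^-1(1 - p)``. Per timepoint, a one-sample
    t-test of the subjects' z values against zero (one-sided, greater)
    gives the group p; the significance mask applies the Bonferroni
    threshold ``alpha / n_timepoints``.

    Returns ``(mask, group_p)``.
    """
    p_matrix = np.atleast_2d(np.asarray(p_matrix, dtype=float))
    n_subjects, n_t = p_matrix.shape
    if n_subjects < 3:
        raise ConfigurationError("group t-test needs at least 3 subjects")
    eps = 1.0 / (n_perm + 1.0)
    z = stats.norm.ppf(1.0 - np.clip(p_matrix, eps, 1.0 - eps))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-identical z values trigger scipy's precision-loss warning;
        # the degenerate case is resolved explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(z, 0.0, axis=0, alternative="greater")
    group_p = np.asarray(res.pvalue, dtype=float)
    # degenerate case: all z equal and nonzero gives 0/0; resolve by sign
    sd = z.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        mean = z.mean(axis=0)
        group_p[degenerate & (mean > 0)] = 0.0
        group_p[degenerate & (mean <= 0)] = 1.0
    mask = group_p < alpha / n_t
    return mask, group_p


def select_time_window(
    curve: DecodingCurve, sd_mult: float = 1.0, bridge_ms: float = 120.0
) -> tuple[float, float] | None:
    """Pick the contiguous discriminative window from a decoding curve.

    A start time qualifies when it is in the Bonferroni-corrected group
    significance mask *and* its group-mean accuracy exceeds chance by more
    than ``sd_mult`` across-subject SDs. Internal dips strictly shorter
    than ``bridge_ms`` are bridged (kept in the window rather than
    splitting it). Among the resulting runs the longest wins; ties go to
    the earlier run. Returns ``(t_start, t_end)`` in window-start ms, or
    ``None`` when no start time qualifies.
    """
    starts = np.asarray(curve.start_times, dtype=float)
    qual = curve.sig_mask & (curve.mean_accuracy - curve.chance > sd_mult * curve.sd_accuracy)
    if not qual.any():
        return None
    step = float(np.median(np.diff(starts))) if starts.size > 1 else bridge_ms
    idx = np.flatnonzero(qual)
    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        gap_ms = (i - runs[-1][-1] - 1) * step
        if gap_ms < bridge_ms:
            runs[-1].append(i)
        else:
            runs.append([i])
    best = max(runs, key=lambda r: (r[-1] - r[0], -r[0]))
    return float(starts[best[0]]), float(starts[best[-1]])


def decode_localizer(
    features: WindowFeatures,
    label_column: str = "condition",
    subject_column: str = "subject",
    n_folds: int = 5,
    n_perm: int = 100,
    alpha: float = 0.001,
    C: float = 1.0,
    seed: int = 0,
) -> DecodingCurve:
    """Per-subject sliding-window decoding with group-level significance.

    Runs :func:`crossval_decode` and :func:`within_subject_permutation_p` at
    every window start for every subject, then combines subjects with
    :func:`group_significance`.
    """
    meta = features.metadata
    subjects = sorted(meta[subject_column].unique())
    n_t = features.n_windows
    acc = np.empty((len(subjects), n_t))
    pvals = np.empty((len(subjects), n_t))
    for si, subject in enumerate(subjects):
        rows = np.flatnonzero((meta[subject_column] == subject).to_numpy())
        y = meta[label_column].to_numpy()[rows]
        for t in range(n_t):
            res = within_subject_permutation_p(
                features.features[rows, t, :],
                y,
                n_perm=n_perm,
                seed=seed + 1000 * si + t,
                n_folds=n_folds,
                C=C,
            )
            acc[si, t] = res.accuracy
            pvals[si, t] = res.p
    mask, group_p = group_significance(pvals, alpha=alpha, n_perm=n_perm)
    return DecodingCurve(
        start_times=features.start_times,
        accuracy=acc,
        p_within=pvals,
        group_p=group_p,
        sig_mask=mask,
        subjects=subjects,
    )
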