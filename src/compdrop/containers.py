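"""In-memory containers shared across the analysis stages.

The pipeline passes four kinds of objects between stages:

* :class:`EpochSet` — stimulus-locked multichannel EEG epochs with a
  per-trial metadata table (subject, session, condition/item/round labels).
* :class:`WindowFeatures` — per-trial, per-window-start channel-mean
  feature vectors produced by the sliding-window featurizer.
* :class:`CompetitionGrid` — the temporal-generalization grid of classifier
  probabilities, one (train time x test time) matrix per retrieval trial.
* :class:`DropTable` — the per-item competition-drop analysis table joining
  neural drop values with behavioral configurations and delayed-recall
  outcomes.

All containers are thin dataclasses over numpy arrays and pandas frames;
they validate shape consistency on construction and otherwise stay out of
the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import DataFormatError

__all__ = [
    "EpochSet",
    "WindowFeatures",
    "ClassifierModel",
    "DecodingCurve",
    "CompetitionGrid",
    "DropTable",
    "ClusterResult",
]


@dataclass
class EpochSet:
    """Trials x channels x time array of voltage (or band power).

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_times)``.
    times
        Epoch time axis in milliseconds relative to stimulus onset,
        length ``n_times``.
    sfreq
        Sampling rate in Hz.
    metadata
        One row per trial. Columns depend on the session: Session 1 epochs
        carry ``subject``/``condition`` labels, Session 2 epochs carry
        ``subject``/``item``/``round``/``trial_type``.
    channel_names
        Optional channel labels; defaults to ``ch00, ch01, ...``.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise DataFormatError(
                f"epoch data must be 3-D (trials, channels, times); got {self.data.shape}"
            )
        if self.times.shape != (self.data.shape[2],):
            raise DataFormatError(
                f"time axis length {self.times.shape} does not match data {self.data.shape}"
            )
        if len(self.metadata) != self.data.shape[0]:
            raise DataFormatError(
                f"metadata has {len(self.metadata)} rows for {self.data.shape[0]} trials"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise DataFormatError("channel_names length does not match channel dimension")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            metadata=self.metadata.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
        )


@dataclass
class WindowFeatures:
    """Per-trial channel-mean features for a grid of window start times.

    ``features[i, t, c]`` is the mean of channel ``c`` over the half-open
    window ``[start_times[t], start_times[t] + window_ms)`` for trial ``i``.
    """

    features: np.ndarray  # (n_trials, n_windows, n_channels)
    start_times: np.ndarray  # ms
    window_ms: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.features.ndim != 3:
            raise DataFormatError("features must be (trials, windows, channels)")
        if self.start_times.shape != (self.features.shape[1],):
            raise DataFormatError("start_times length does not match feature windows")
        if np.any(np.diff(self.start_times) <= 0):
            raise DataFormatError("start_times must be strictly increasing")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_windows(self) -> int:
        return self.features.shape[1]

    @property
    def n_channels(self) -> int:
        return self.features.shape[2]

    def at(self, t_index: int) -> np.ndarray:
        """Feature matrix (trials x channels) at one window start."""
        return self.features[:, t_index, :]


@dataclass
class ClassifierModel:
    """A fitted per-timepoint linear decoder (L2 logistic regression)."""

    weights: np.ndarray  # (n_channels,)
    intercept: float
    C: float
    train_time: float  # window start, ms

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise DataFormatError("classifier weights must be finite")

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(high-competition class) via the logistic link."""
        from scipy.special import expit

        return expit(self.decision(X))


@dataclass
class DecodingCurve:
    """Group-level sliding-window decoding result for the localizer.

    Accuracies are per subject x window start; ``p_within`` holds the
    within-subject permutation p values, ``group_p`` the inverse-normal /
    one-sample-t group combination, and ``sig_mask`` the Bonferroni-corrected
    significance mask.
    """

    start_times: np.ndarray
    accuracy: np.ndarray  # (n_subjects, n_windows)
    p_within: np.ndarray  # (n_subjects, n_windows)
    group_p: np.ndarray  # (n_windows,)
    sig_mask: np.ndarray  # (n_windows,) bool
    subjects: list
    chance: float = 0.5

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def sd_accuracy(self) -> np.ndarray:
        """SD of subject-mean accuracies at each window (the Fig-style band)."""
        return self.accuracy.std(axis=0, ddof=1)


@dataclass
class CompetitionGrid:
    """Per-trial temporal-generalization grid of competition probabilities.

    ``values[i, a, b]`` is the probability that trial ``i`` is in a
    high-competition state, from the classifier trained at Session 1 time
    ``train_times[a]`` applied at Session 2 time ``test_times[b]``.
    ``trials`` carries subject/item/round/trial_type for each row.
    """

    values: np.ndarray  # (n_trials, n_train, n_test)
    train_times: np.ndarray
    test_times: np.ndarray
    trials: pd.DataFrame
    trial_type: str = "retrieval"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataFormatError("grid values must be (trials, train_times, test_times)")
        if len(self.trials) != self.values.shape[0]:
            raise DataFormatError("trials table does not match grid first dimension")
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise DataFormatError("competition probabilities must lie strictly in (0, 1)")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class DropTable:
    """Per retained item: competition drop per grid square plus behavior.

    ``drops[k]`` is the (train x test) drop matrix for row ``k`` of
    ``items``; columns of ``items`` include ``subject``, ``item``,
    ``configuration`` (4-bit string), ``first_correct_round`` (1-based),
    ``recalled_s3`` and, when reaction times are available, ``rt_drop``.
    """

    drops: np.ndarray  # (n_items, n_train, n_test)
    items: pd.DataFrame
    train_times: np.ndarray
    test_times: np.ndarray

    def __post_init__(self) -> None:
        if self.drops.ndim != 3:
            raise DataFormatError("drops must be (items, train_times, test_times)")
        if len(self.items) != self.drops.shape[0]:
            raise DataFormatError("items table does not match drops first dimension")
        self.items = self.items.reset_index(drop=True)

    @property
    def n_items(self) -> int:
        return self.drops.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.drops.shape[1], self.drops.shape[2]

    def subset(self, mask) -> "DropTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return DropTable(
            drops=self.drops[idx],
            items=self.items.iloc[idx],
            train_times=self.train_times,
            test_times=self.test_times,
        )


@dataclass
class ClusterResult:
    """Output of the grid-wise cluster permutation test.

    ``clusters`` lists, largest first, arrays of (train, test) index pairs;
    ``familywise_p`` gives each cluster's corrected p value against the
    permutation null of maximum cluster sizes.
    """

    t_grid: np.ndarray
    p_right: np.ndarray
    p_left: np.ndarray
    mask: np.ndarray  # thresholded mask used for clustering
    clusters: list  # list of (k, 2) int arrays
    cluster_sizes: np.ndarray
    familywise_p: np.ndarray
    null_max_sizes: np.ndarray
    alpha: float
    threshold: float

    @property
    def significant(self) -> np.ndarray:
        return self.familywise_p < self.alpha

    def significant_mask(self) -> np.ndarray:
        """Boolean grid marking squares inside any family-wise significant cluster."""
        out = np.zeros(self.t_grid.shape, dtype=bool)
        for cluster, sig in zip(self.clusters, self.significant):
            if sig:
                out[cluster[:, 0], cluster[:, 1]] = True
        return out
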