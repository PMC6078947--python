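"""Cross-session transfer: Session-1-trained decoders applied across Session 2.

For each selected localizer train time, an L2 logistic decoder is fit on
*all* Session 1 trials (no held-out split) and applied to every Session 2
window start, per subject. The unthresholded logistic output is read as
the *competition probability* — the probability that the epoch reflects a
high-competition retrieval state — yielding, per trial, a
(train time x test time) temporal-generalization grid. Study-block trials
run through the identical path for the recall-specificity control.
Probabilities are clipped to ``[eps, 1 - eps]`` for downstream arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .containers import ClassifierModel, CompetitionGrid, WindowFeatures
from .localizer import fit_logistic

__all__ = ["train_full_models", "apply_grid", "transfer_by_subject", "PROB_EPS"]

PROB_EPS = 1e-6


def train_full_models(
    features: WindowFeatures,
    labels: np.ndarray,
    train_times: np.ndarray,
    C: float = 1.0,
) -> list[ClassifierModel]:
    """Fit one full-data decoder per requested train time.

    ``train_times`` must be a subset of the feature start times (the
    selected discriminative window).
    """
    labels = np.asarray(labels)
    models = []
    for t in np.asarray(train_times, dtype=float):
        matches = np.flatnonzero(np.isclose(features.start_times, t))
        if matches.size != 1:
            raise ConfigurationError(f"train time {t} ms is not on the feature start-time grid")
        k = matches[0]
        models.append(fit_logistic(features.at(k), labels, C=C, train_time=t))
    return models


def apply_grid(
    models: list[ClassifierModel],
    features: WindowFeatures,
    trial_type: str = "retrieval",
) -> CompetitionGrid:
    """Apply per-train-time decoders across all test times.

    Returns a :class:`CompetitionGrid` whose ``values[i, a, b]`` is the
    competition probability of trial ``i`` under the model trained at
    ``train_times[a]``, evaluated on the feature window starting at
    ``test_times[b]``.
    """
    if not models:
        raise ConfigurationError("no models supplied")
    d = models[0].weights.size
    if features.n_channels != d:
        raise ConfigurationError(
            f"feature dimension {features.n_channels} does not match model dimension {d}"
        )
    W = np.stack([m.weights for m in models], axis=0)  # (n_train, d)
    b = np.array([m.intercept for m in models])
    from scipy.special import expit

    # (trials, test, d) @ (d, train) -> (trials, test, train)
    logits = np.einsum("itd,ad->ita", features.features, W) + b[None, None, :]
    values = np.clip(expit(np.transpose(logits, (0, 2, 1))), PROB_EPS, 1.0 - PROB_EPS)
    trials = features.metadata.copy()
    if "trial_type" in trials.columns:
        mask = (trials["trial_type"] == trial_type).to_numpy()
        values, trials = values[mask], trials.loc[mask]
    return CompetitionGrid(
        values=values,
        train_times=np.array([m.train_time for m in models], dtype=float),
        test_times=features.start_times.copy(),
        trials=trials,
        trial_type=trial_type,
    )


def transfer_by_subject(
    s1_features: WindowFeatures,
    s2_features: WindowFeatures,
    train_times: np.ndarray,
    label_column: str = "condition",
    subject_column: str = "subject",
    trial_type: str = "retrieval",
    C: float = 1.0,
) -> CompetitionGrid:
    """Within-subject train-on-Session-1 / apply-to-Session-2 convenience.

    Trains full-data models per subject and concatenates the per-subject
    grids into one pooled :class:`CompetitionGrid`.
    """
    subjects = sorted(s1_features.metadata[subject_column].unique())
    values, frames = [], []
    for subject in subjects:
        m1 = (s1_features.metadata[subject_column] == subject).to_numpy()
        m2 = (s2_features.metadata[subject_column] == subject).to_numpy()
        if not m2.any():
            continue
        sub1 = WindowFeatures(
            features=s1_features.features[m1],
            start_times=s1_features.start_times,
            window_ms=s1_features.window_ms,
            metadata=s1_features.metadata.loc[m1],
        )
        sub2 = WindowFeatures(
            features=s2_features.features[m2],
            start_times=s2_features.start_times,
            window_ms=s2_features.window_ms,
            metadata=s2_features.metadata.loc[m2],
        )
        models = train_full_models(
            sub1, sub1.metadata[label_column].to_numpy(), train_times, C=C
        )
        grid = apply_grid(models, sub2, trial_type=trial_type)
        values.append(grid.values)
        frames.append(grid.trials)
    if not values:
        raise ConfigurationError("no subjects with Session 2 trials")
    return CompetitionGrid(
        values=np.concatenate(values, axis=0),
        train_times=np.asarray(train_times, dtype=float),
        test_times=s2_features.start_times.copy(),
        trials=pd.concat(frames, ignore_index=True),
        trial_type=trial_type,
    )
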