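"""Characterize what the decoder learned: weight RDM and Haufe patterns.

The cosine-distance RDM over per-timepoint weight vectors shows whether
the discriminative representation is stable over time; the Haufe transform
(pattern = feature covariance times weights) converts backward-model
weights into interpretable activation patterns, which should recover the
planted channel topography.
"""

import numpy as np

from compdrop import (
    SimulationConfig,
    average_patterns,
    fit_logistic,
    haufe_pattern,
    simulate_session1,
    sliding_window_features,
    weight_rdm,
)

config = SimulationConfig(
    n_subjects=4,
    n_channels=16,
    sampling_rate=128.0,
    epoch_span=(-100.0, 700.0),
    n_categories=6,
    n_exemplars_per_category=4,
    signal_window=(80.0, 400.0),
    effect_size=3.0,
    seed=3,
)
epochs, truth = simulate_session1(config)
features = sliding_window_features(epochs, step_ms=40.0)
meta = features.metadata

in_window = np.flatnonzero(
    (features.start_times >= 80) & (features.start_times <= 360)
)
weights, patterns = [], []
for subject in sorted(meta["subject"].unique()):
    rows = np.flatnonzero((meta["subject"] == subject).to_numpy())
    y = meta["condition"].to_numpy()[rows]
    for t in in_window:
        X = features.features[rows, t, :]
        model = fit_logistic(X, y)
        weights.append(model.weights)
        patterns.append(haufe_pattern(model.weights, X))

rdm = weight_rdm(np.array(weights)[: len(in_window)])  # one subject's timepoints
print("Weight RDM (one subject, in-window timepoints), cosine distance:")
print(np.array_str(rdm, precision=2, suppress_small=True))
print("Low off-diagonal distances -> a stable discriminative representation "
      "across the window (the planted signal has a fixed topography).")

mean_pattern = average_patterns(np.array(patterns))
r = np.corrcoef(mean_pattern, truth.topography)[0, 1]
print(f"\nCorrelation of the averaged Haufe pattern with the planted "
      f"topography: r = {r:.3f} (|r| > 0.9 expected at this SNR)")
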