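"""Characterizing learned decoders: weight-vector RDMs and Haufe patterns.

The representational dissimilarity matrix (RDM) holds the cosine distance
``1 - cos(w_i, w_j)`` between the decoder weight vectors at every pair of
window start times; blocks of low distance indicate a stable discriminative
representation. Because backward-model weights are not directly
interpretable as activation strength, weights are converted to activation
patterns via the Haufe transform ``a = Sigma_X w`` (the binary-classifier
case), where ``Sigma_X`` is the empirical covariance of the training
features at that timepoint. Patterns are normalized to unit norm before
averaging across subjects and timepoints, so high-variance subjects do not
dominate the mean; the pattern is therefore defined up to positive scale.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._exceptions import ConfigurationError

__all__ = ["weight_rdm", "haufe_pattern", "average_patterns"]


def weight_rdm(weights: np.ndarray) -> np.ndarray:
    """Cosine-distance RDM over per-timepoint weight vectors.

    ``weights`` is (n_timepoints, n_channels); the result is symmetric with
    zero diagonal and entries in [0, 2].
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2:
        raise ConfigurationError("weights must be (n_timepoints, n_channels)")
    norms = np.linalg.norm(weights, axis=1)
    if np.any(norms == 0):
        raise ConfigurationError("zero-norm weight vector: cosine distance undefined")
    rdm = squareform(pdist(weights, metric="cosine"))
    np.fill_diagonal(rdm, 0.0)
    return rdm


def haufe_pattern(weights: np.ndarray, training_features: np.ndarray) -> np.ndarray:
    """Haufe activation pattern ``a = Sigma_X w`` for a linear binary decoder.

    ``training_features`` is the (n_trials, n_channels) matrix the decoder
    was trained on; ``Sigma_X`` is its empirical (maximum-likelihood)
    covariance. The returned pattern is unnormalized (see
    :func:`average_patterns` for the unit-norm averaging convention).
    """
    w = np.asarray(weights, dtype=float).ravel()
    X = np.asarray(training_features, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ConfigurationError("training features must be (n_trials, n_channels) matching w")
    if X.shape[0] < 2:
        raise ConfigurationError("covariance not estimable from fewer than 2 trials")
    Xc = X - X.mean(axis=0)
    sigma = (Xc.T @ Xc) / X.shape[0]
    return sigma @ w


def average_patterns(patterns: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Element-wise mean over a stack of activation patterns.

    ``patterns`` is (n_patterns, n_channels) — typically one pattern per
    (subject, timepoint) pair inside a time window of interest. With
    ``normalize`` (default) each pattern is scaled to unit norm first.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise ConfigurationError("cannot average an empty pattern selection")
    if normalize:
        norms = np.linalg.norm(patterns, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ConfigurationError("zero-norm pattern cannot be normalized")
        patterns = patterns / norms
    return patterns.mean(axis=0)
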