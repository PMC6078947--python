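"""Behavioral analyses of the four-round learning task.

Each item's Session 2 recall record is encoded as a 4-bit *response
configuration* (bit i = correct in test round i, e.g. ``0111`` = correct in
every round but the first). A cross-validated L2 logistic regression on
these 4-bit features, items pooled over subjects, measures how well
Session 2 behavior alone predicts one-week delayed recall; significance
comes from a label permutation test. Round-by-round summaries use the
mean-of-subject-means convention (each subject contributes equally,
regardless of item counts), with SEM over subject means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataFormatError
from .localizer import PermutationDecodingResult, crossval_decode

__all__ = [
    "encode_configurations",
    "predict_s3_from_configurations",
    "behavior_permutation_test",
    "summarize_rounds",
]

logger = logging.getLogger(__name__)


def encode_configurations(behavior: pd.DataFrame, n_rounds: int = 4) -> pd.DataFrame:
    """Per-item response configurations from the long behavioral table.

    Returns one row per (subject, item) with the bit matrix (``bit_1`` ..
    ``bit_n``), the configuration string, and the delayed-recall label.
    Raises if any item is missing a round.
    """
    required = {"subject", "item", "round", "correct", "recalled_s3"}
    missing = required - set(behavior.columns)
    if missing:
        raise DataFormatError(f"behavior table is missing columns: {sorted(missing)}")
    rows = []
    for (subject, item), grp in behavior.groupby(["subject", "item"], sort=True):
        grp = grp.sort_values("round")
        if list(grp["round"]) != list(range(1, n_rounds + 1)):
            raise DataFormatError(
                f"subject {subject} item {item}: expected rounds 1..{n_rounds}, "
                f"got {list(grp['round'])}"
            )
        bits = grp["correct"].to_numpy().astype(int)
        rec = {"subject": subject, "item": item, "recalled_s3": int(grp["recalled_s3"].iloc[0])}
        for r in range(n_rounds):
            rec[f"bit_{r + 1}"] = int(bits[r])
        rec["configuration"] = "".join(map(str, bits))
        rows.append(rec)
    return pd.DataFrame(rows)


def _design(configs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bit_cols = sorted(
        (c for c in configs.columns if c.startswith("bit_")), key=lambda c: int(c.split("_")[1])
    )
    if not bit_cols:
        raise DataFormatError("configuration table has no bit_* columns")
    X = configs[bit_cols].to_numpy(dtype=float)
    y = configs["recalled_s3"].to_numpy().astype(int)
    return X, y


def predict_s3_from_configurations(
    configs: pd.DataFrame, n_folds: int = 5, seed: int = 0, C: float = 1.0
) -> float:
    """Cross-validated accuracy of predicting delayed recall from the 4 bits.

    Items are pooled over subjects (stratified k-fold on the pooled set).
    Chance for balanced outcomes is 50%.
    """
    X, y = _design(configs)
    if np.unique(y).size < 2:
        raise ConfigurationError("delayed-recall labels contain a single class")
    return crossval_decode(X, y, n_folds=n_folds, seed=seed, C=C)


def behavior_permutation_test(
    configs: pd.DataFrame, n_perm: int = 1000, seed: int = 0, n_folds: int = 5, C: float = 1.0
) -> PermutationDecodingResult:
    """Permutation test of the behavioral configuration classifier.

    Recall labels are shuffled over the pooled items before each
    cross-validation re-run; ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    X, y = _design(configs)
    if np.unique(y).size < 2:
        raise ConfigurationError("delayed-recall labels contain a single class")
    rng = np.random.default_rng(seed)
    observed = crossval_decode(X, y, n_folds=n_folds, seed=seed, C=C)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = crossval_decode(X, rng.permutation(y), n_folds=n_folds, seed=seed, C=C)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationDecodingResult(accuracy=observed, p=float(p), null_accuracies=null)


def summarize_rounds(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-round mean accuracy split by delayed-recall outcome.

    Each cell is the mean over within-subject mean performance (not the
    pooled-trial mean), with SEM over the subject means; ``n_subjects``
    records how many subjects contributed. Subjects with no items in a cell
    are excluded from that cell (logged). With one contributing subject the
    SEM is reported as NaN.
    """
    if behavior.empty:
        raise ConfigurationError("behavior table is empty")
    per_subject = (
        behavior.groupby(["round", "recalled_s3", "subject"])["correct"].mean().reset_index()
    )
    rows = []
    for (rnd, outcome), grp in per_subject.groupby(["round", "recalled_s3"]):
        means = grp["correct"].to_numpy()
        rows.append(
            {
                "round": rnd,
                "recalled_s3": outcome,
                "mean_accuracy": float(means.mean()),
                "sem": float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else np.nan,
                "n_subjects": int(means.size),
            }
        )
    return pd.DataFrame(rows)
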