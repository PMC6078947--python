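"""Competition-drop scores and the pooled analysis table.

For each item, the *competition drop* at a grid square is the competition
probability in the first round the participant answered correctly minus the
probability in the final round (R4). Items that were never answered
correctly, or answered incorrectly in round 4, are dropped from the
analysis (counts logged). The same retention rule defines the
reaction-time drop control: RT at the first correct round minus RT at
round 4.

Optionally, drop values can be restricted to one behavioral response
configuration (e.g. ``0011``) to control for Session 2 accuracy, and
z-scored within subject (n-1 SD denominator) to remove between-subject
variance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, DataFormatError
from .containers import CompetitionGrid, DropTable

__all__ = [
    "competition_drop",
    "filter_by_configuration",
    "zscore_within_subject",
    "rt_drop",
    "rt_drop_test",
]

logger = logging.getLogger(__name__)


def _item_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    """Wide per-item behavior: configuration, first-correct round, retention."""
    required = {"subject", "item", "round", "correct", "recalled_s3"}
    missing = required - set(behavior.columns)
    if missing:
        raise DataFormatError(f"behavior table is missing columns: {sorted(missing)}")
    n_rounds = int(behavior["round"].max())
    rows = []
    for (subject, item), grp in behavior.groupby(["subject", "item"], sort=True):
        grp = grp.sort_values("round")
        if list(grp["round"]) != list(range(1, n_rounds + 1)):
            raise DataFormatError(
                f"subject {subject} item {item}: rounds {list(grp['round'])} are incomplete"
            )
        correct = grp["correct"].to_numpy().astype(int)
        any_correct = bool(correct.any())
        rows.append(
            {
                "subject": subject,
                "item": item,
                "configuration": "".join(map(str, correct)),
                "first_correct_round": int(correct.argmax() + 1) if any_correct else 0,
                "retained": any_correct and correct[-1] == 1,
                "recalled_s3": int(grp["recalled_s3"].iloc[0]),
                "rts": grp["rt_s"].to_numpy() if "rt_s" in grp.columns else None,
                "n_rounds": n_rounds,
            }
        )
    return pd.DataFrame(rows)


def competition_drop(grid: CompetitionGrid, behavior: pd.DataFrame) -> DropTable:
    """Per-item competition drop at every grid square.

    ``drop = P(first-correct round) - P(round 4)``. Items failing the
    retention rule (never correct, or incorrect in the final round) are
    excluded; exclusion counts are logged.
    """
    items = _item_behavior(behavior)
    key = items.set_index(["subject", "item"])
    trial_rounds: dict[tuple, dict[int, int]] = {}
    for row, rec in grid.trials.iterrows():
        trial_rounds.setdefault((rec["subject"], rec["item"]), {})[int(rec["round"])] = row

    n_never = n_r4 = 0
    drops, kept = [], []
    for (subject, item), rounds in trial_rounds.items():
        if (subject, item) not in key.index:
            raise DataFormatError(f"grid item (subject={subject}, item={item}) has no behavior")
        rec = key.loc[(subject, item)]
        n_rounds = int(rec["n_rounds"])
        if sorted(rounds) != list(range(1, n_rounds + 1)):
            raise DataFormatError(
                f"grid item (subject={subject}, item={item}) is missing rounds"
            )
        if rec["first_correct_round"] == 0:
            n_never += 1
            continue
        if not rec["retained"]:
            n_r4 += 1
            continue
        first = int(rec["first_correct_round"])
        drops.append(grid.values[rounds[first]] - grid.values[rounds[n_rounds]])
        rts = rec["rts"]
        kept.append(
            {
                "subject": subject,
                "item": item,
                "configuration": rec["configuration"],
                "first_correct_round": first,
                "recalled_s3": int(rec["recalled_s3"]),
                "rt_drop": float(rts[first - 1] - rts[n_rounds - 1]) if rts is not None else np.nan,
            }
        )
    logger.info(
        "competition_drop: retained %d items (excluded %d never-correct, %d R4-incorrect)",
        len(kept),
        n_never,
        n_r4,
    )
    if not kept:
        raise ConfigurationError("no items satisfy the retention rule")
    return DropTable(
        drops=np.stack(drops, axis=0),
        items=pd.DataFrame(kept),
        train_times=grid.train_times.copy(),
        test_times=grid.test_times.copy(),
    )


def filter_by_configuration(table: DropTable, config_pattern: str) -> DropTable:
    """Restrict the drop table to items with one 4-bit response configuration."""
    if not (set(config_pattern) <= {"0", "1"}):
        raise ConfigurationError(f"configuration pattern must be binary, got '{config_pattern}'")
    mask = (table.items["configuration"] == config_pattern).to_numpy()
    if not mask.any():
        warnings.warn(f"no items match configuration {config_pattern}", stacklevel=2)
    return table.subset(mask)


def zscore_within_subject(table: DropTable, ddof: int = 1) -> DropTable:
    """Z-score drop values within subject, per grid square.

    Subjects with fewer than 2 retained items, or zero variance at any grid
    square, are excluded (logged). After the transform each remaining
    subject's drops have mean 0 and SD 1 at every square.
    """
    subjects = table.items["subject"].to_numpy()
    keep = np.ones(table.n_items, dtype=bool)
    drops = table.drops.copy()
    n_excluded = 0
    for subject in np.unique(subjects):
        rows = np.flatnonzero(subjects == subject)
        if rows.size < 2:
            keep[rows] = False
            n_excluded += 1
            continue
        block = drops[rows]
        sd = block.std(axis=0, ddof=ddof)
        if np.any(sd == 0):
            keep[rows] = False
            n_excluded += 1
            continue
        drops[rows] = (block - block.mean(axis=0)) / sd
    if n_excluded:
        logger.info("zscore_within_subject: excluded %d subjects", n_excluded)
    if not keep.any():
        raise ConfigurationError("no subject has enough variance to z-score")
    return DropTable(
        drops=drops[keep],
        items=table.items.loc[keep],
        train_times=table.train_times,
        test_times=table.test_times,
    )


def rt_drop(behavior: pd.DataFrame) -> pd.DataFrame:
    """Reaction-time drop per retained item: RT(first correct) - RT(round 4).

    Applies the same retention rule as :func:`competition_drop`; items with
    missing reaction times are excluded (logged).
    """
    if "rt_s" not in behavior.columns:
        raise DataFormatError("behavior table has no rt_s column")
    items = _item_behavior(behavior)
    rows = []
    n_missing = 0
    for _, rec in items.iterrows():
        if rec["first_correct_round"] == 0 or not rec["retained"]:
            continue
        rts = rec["rts"]
        first = int(rec["first_correct_round"])
        value = rts[first - 1] - rts[int(rec["n_rounds"]) - 1]
        if not np.isfinite(value):
            n_missing += 1
            continue
        rows.append(
            {
                "subject": rec["subject"],
                "item": rec["item"],
                "rt_drop": float(value),
                "recalled_s3": int(rec["recalled_s3"]),
            }
        )
    if n_missing:
        logger.info("rt_drop: excluded %d items with missing reaction times", n_missing)
    return pd.DataFrame(rows, columns=["subject", "item", "rt_drop", "recalled_s3"])


def rt_drop_test(rt_table: pd.DataFrame) -> tuple[float, float]:
    """One-tailed pooled t-test: is RT drop larger for remembered items?

    Returns ``(t, p_right)``; the control analysis expects this to be null
    when reaction times are generated independently of delayed recall.
    """
    remembered = rt_table.loc[rt_table["recalled_s3"] == 1, "rt_drop"].to_numpy()
    forgotten = rt_table.loc[rt_table["recalled_s3"] == 0, "rt_drop"].to_numpy()
    if remembered.size < 2 or forgotten.size < 2:
        raise ConfigurationError("both outcome classes need at least 2 items")
    res = stats.ttest_ind(remembered, forgotten, equal_var=True, alternative="greater")
    return float(res.statistic), float(res.pvalue)
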