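"""Grid-wise subsequent-memory tests with cluster permutation correction.

Per grid square, a pooled (fixed-effects) two-sample t-test compares the
competition drops of subsequently-remembered vs subsequently-forgotten
items; the right tail (drop larger for remembered) carries the directional
hypothesis, and the left tail is reported descriptively. Uncorrected p
values are liberal by construction; family-wise error is controlled by the
cluster permutation test: threshold the right-tail p grid at 0.10, find
connected components under 4-connectivity (no diagonal adjacency), and
compare each observed cluster's size (number of squares) to the null
distribution of maximum cluster sizes obtained by permuting item labels.
A subject-level bootstrap (resampling participants with replacement and
re-running the whole cluster analysis) measures how consistently each grid
square falls inside a significant cluster across the population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._exceptions import ConfigurationError
from .containers import ClusterResult, DropTable

__all__ = [
    "grid_ttest",
    "ks_normality_check",
    "find_clusters",
    "cluster_permutation",
    "subject_bootstrap",
    "BootstrapResult",
]

logger = logging.getLogger(__name__)

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


def _pooled_t(
    sum1: np.ndarray, sumsq1: np.ndarray, n1: int, total: np.ndarray, totalsq: np.ndarray, n: int
) -> np.ndarray:
    """Student (pooled-variance) two-sample t from sufficient statistics.

    Group 1 statistics are given; group 0 follows from the totals. Inputs
    may carry a leading permutation axis.
    """
    n0 = n - n1
    m1 = sum1 / n1
    m0 = (total - sum1) / n0
    ss1 = sumsq1 - n1 * m1**2
    ss0 = (totalsq - sumsq1) - n0 * m0**2
    pooled = (ss1 + ss0) / (n - 2)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m0) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def grid_ttest(table: DropTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled two-sample t-test per grid square.

    Returns ``(t, p_right, p_left)`` grids, where the right tail tests
    "drop larger for remembered items". Items are pooled over subjects.
    """
    y = table.items["recalled_s3"].to_numpy().astype(int)
    n1 = int(y.sum())
    n = y.size
    if n1 < 2 or n - n1 < 2:
        raise ConfigurationError("need at least 2 items in each outcome class")
    X = table.drops.reshape(n, -1)
    sum1 = y @ X
    sumsq1 = y @ X**2
    t = _pooled_t(sum1, sumsq1, n1, X.sum(axis=0), (X**2).sum(axis=0), n)
    df = n - 2
    p_right = stats.t.sf(t, df)
    p_left = stats.t.cdf(t, df)
    shape = table.grid_shape
    return t.reshape(shape), p_right.reshape(shape), p_left.reshape(shape)


def ks_normality_check(table: DropTable, min_n: int = 10) -> dict:
    """Kolmogorov-Smirnov check of drop-score normality per outcome class.

    Each class's pooled drop values (flattened over grid squares) are tested
    against a normal with that class's estimated mean/SD. Diagnostics only —
    the t-test is not gated on the outcome. Classes with fewer than
    ``min_n`` values are skipped with a warning.
    """
    out = {}
    y = table.items["recalled_s3"].to_numpy().astype(int)
    for label, name in ((1, "remembered"), (0, "forgotten")):
        values = table.drops[y == label].ravel()
        if values.size < min_n:
            warnings.warn(f"{name}: too few values ({values.size}) for KS check", stacklevel=2)
            out[name] = None
            continue
        res = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
        out[name] = (float(res.statistic), float(res.pvalue))
    return out


def find_clusters(p_grid: np.ndarray, threshold: float = 0.10) -> list[np.ndarray]:
    """Connected components of sub-threshold squares under 4-connectivity.

    Diagonal adjacency does not connect. Returns clusters as (k, 2) index
    arrays, sorted largest first.
    """
    mask = np.asarray(p_grid) < threshold
    labels, n = ndimage.label(mask, structure=_CROSS)
    clusters = [np.argwhere(labels == i + 1) for i in range(n)]
    clusters.sort(key=lambda c: (-len(c), c[0, 0], c[0, 1]))
    return clusters


def _null_max_sizes(
    X: np.ndarray,
    y: np.ndarray,
    shape: tuple[int, int],
    n_perm: int,
    threshold: float,
    rng: np.random.Generator,
    subjects: np.ndarray | None = None,
) -> np.ndarray:
    """Max cluster size per permutation of item-to-outcome assignment.

    Permutations shuffle labels over the pooled item set (class counts
    preserved); when ``subjects`` is given, labels are instead shuffled
    within subject (the stratified sensitivity variant). The null uses the
    same right-tail mask as the observed directional test.
    """
    n = y.size
    n1 = int(y.sum())
    perm_labels = np.tile(y, (n_perm, 1))
    if subjects is None:
        perm_labels = rng.permuted(perm_labels, axis=1)
    else:
        for subject in np.unique(subjects):
            cols = np.flatnonzero(subjects == subject)
            block = rng.permuted(np.tile(y[cols], (n_perm, 1)), axis=1)
            perm_labels[:, cols] = block
    sum1 = perm_labels @ X
    sumsq1 = perm_labels @ X**2
    t = _pooled_t(sum1, sumsq1, n1, X.sum(axis=0), (X**2).sum(axis=0), n)
    # right-tail p < threshold  <=>  t > t-quantile(1 - threshold)
    t_crit = stats.t.isf(threshold, n - 2)
    masks = t > t_crit
    out = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        labels, k = ndimage.label(masks[b].reshape(shape), structure=_CROSS)
        if k:
            out[b] = np.bincount(labels.ravel())[1:].max()
    return out


def cluster_permutation(
    table: DropTable,
    n_perm: int = 1000,
    threshold: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
    stratify_by_subject: bool = False,
) -> ClusterResult:
    """Cluster permutation test of the drop-vs-subsequent-memory grid.

    Observed clusters come from the right-tail p grid thresholded at
    ``threshold``; each cluster's family-wise p is
    ``(1 + #{perm max size >= observed size}) / (n_perm + 1)``. Clusters
    with family-wise p below ``alpha`` are significant.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable null tail", stacklevel=2)
    t, p_right, p_left = grid_ttest(table)
    clusters = find_clusters(p_right, threshold)
    sizes = np.array([len(c) for c in clusters], dtype=int)

    y = table.items["recalled_s3"].to_numpy().astype(int)
    X = table.drops.reshape(y.size, -1)
    rng = np.random.default_rng(seed)
    subjects = table.items["subject"].to_numpy() if stratify_by_subject else None
    null_max = _null_max_sizes(X, y, table.grid_shape, n_perm, threshold, rng, subjects)
    fw_p = (1.0 + (null_max[None, :] >= sizes[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return ClusterResult(
        t_grid=t,
        p_right=p_right,
        p_left=p_left,
        mask=p_right < threshold,
        clusters=clusters,
        cluster_sizes=sizes,
        familywise_p=fw_p,
        null_max_sizes=null_max,
        alpha=alpha,
        threshold=threshold,
    )


@dataclass
class BootstrapResult:
    """Subject-bootstrap reliability of the significant-cluster map."""

    frequency: np.ndarray  # fraction of draws each square was in a significant cluster
    n_draws: int
    n_skipped: int


def subject_bootstrap(
    table: DropTable,
    n_boot: int = 1000,
    n_perm: int = 1000,
    threshold: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapResult:
    """Resample subjects with replacement and re-run the cluster analysis.

    Each draw duplicates resampled subjects' items, reruns
    :func:`cluster_permutation`, and marks the squares inside family-wise
    significant clusters. Draws whose pooled items contain a single outcome
    class are skipped (logged; the frequency denominator is adjusted).
    """
    subjects = np.unique(table.items["subject"].to_numpy())
    if subjects.size < 2:
        raise ConfigurationError("subject bootstrap needs at least 2 subjects")
    rows_by_subject = {
        s: np.flatnonzero((table.items["subject"] == s).to_numpy()) for s in subjects
    }
    rng = np.random.default_rng(seed)
    counts = np.zeros(table.grid_shape, dtype=float)
    n_used = n_skipped = 0
    for _ in range(n_boot):
        draw = rng.choice(subjects, size=subjects.size, replace=True)
        rows = np.concatenate([rows_by_subject[s] for s in draw])
        y = table.items["recalled_s3"].to_numpy()[rows]
        if y.min() == y.max() or y.sum() < 2 or (y.size - y.sum()) < 2:
            n_skipped += 1
            continue
        sub = table.subset(rows)
        result = cluster_permutation(
            sub,
            n_perm=n_perm,
            threshold=threshold,
            alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        counts += result.significant_mask()
        n_used += 1
    if n_skipped:
        logger.info("subject_bootstrap: skipped %d single-class draws", n_skipped)
    if n_used == 0:
        raise ConfigurationError("every bootstrap draw was single-class")
    return BootstrapResult(frequency=counts / n_used, n_draws=n_used, n_skipped=n_skipped)
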