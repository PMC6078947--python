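"""Synthetic multi-subject EEG + behavior generator with planted ground truth.

The generator emulates the two-session structure the analysis assumes:

* **Session 1 (competition localizer)** — a balanced two-class trial set
  (one trial per category x exemplar x condition cell). High- and
  low-competition trials differ by a spatiotemporally localized mean
  pattern: a fixed channel topography times a smooth temporal envelope
  supported only inside ``signal_window``, embedded in spatially correlated,
  temporally autocorrelated Gaussian noise.

* **Session 2/3 (retrieval practice + delayed test)** — each vocabulary item
  carries a latent competition level per round, decreasing in expectation
  across the four rounds with item-level variance. Retrieval-trial epochs
  scale the same planted topography by that latent level, so a classifier
  trained on Session 1 can track it. Recall correctness follows a monotone
  learning curve with an item-ability random effect; the one-week delayed
  recall label is drawn from a logistic link whose log-odds include the
  planted competition drop (coupling ``drop_memory_coupling``) and, by
  default, a behavioral term in the number of correct rounds. Study-block
  epochs carry a per-item constant (round-independent) signal so the study
  control analysis is null by construction. Reaction times are log-normal
  with a dominant item random effect and a weak negative round trend, and
  are generated independently of the delayed-recall outcome.

Identical ``(config, seed)`` give bit-identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from ._exceptions import ConfigurationError
from .containers import EpochSet

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "GroundTruth",
    "default_topography",
    "simulate_session1",
    "simulate_session2",
    "simulate_behavior",
]

logger = logging.getLogger(__name__)

_S1_STREAM = 11
_S2_STREAM = 22


@dataclass
class NoiseModel:
    """Spatially correlated Gaussian noise with AR(1) temporal structure.

    Channel covariance defaults to ``exp(-|i - j| / spatial_decay)`` over
    channel index distance (unit marginal variance); an explicit covariance
    matrix may be supplied instead. ``ar_coeff`` is the lag-1 temporal
    autocorrelation; the process is initialized at stationarity so marginal
    variance is ``std**2`` at every sample.
    """

    spatial_decay: float = 5.0
    ar_coeff: float = 0.95
    std: float = 1.0
    spatial_cov: np.ndarray | None = None

    def channel_cholesky(self, n_channels: int) -> np.ndarray:
        if self.spatial_cov is not None:
            cov = np.asarray(self.spatial_cov, dtype=float)
            if cov.shape != (n_channels, n_channels):
                raise ConfigurationError(
                    f"spatial_cov shape {cov.shape} does not match {n_channels} channels"
                )
        else:
            idx = np.arange(n_channels)
            cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / self.spatial_decay)
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ConfigurationError("noise spatial covariance is not positive definite") from err


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic study.

    Defaults mirror the experimental design being emulated: 64-channel EEG at
    512 Hz; Session 1 uses 19 semantic categories x 8 exemplars x 2
    competition conditions (304 test-phase trials per subject); Session 2
    uses 60 vocabulary items over 4 study/test rounds for 40 subjects, with
    delayed recall near 50% so remembered/forgotten classes are roughly
    balanced.
    """

    n_subjects: int = 40
    n_channels: int = 64
    sampling_rate: float = 512.0
    epoch_span: tuple[float, float] = (-100.0, 1000.0)  # ms
    n_categories: int = 19
    n_exemplars_per_category: int = 8
    n_items_s2: int = 60
    n_rounds: int = 4
    signal_window: tuple[float, float] = (80.0, 600.0)  # ms
    signal_topography: np.ndarray | None = None
    effect_size: float = 1.0
    drop_memory_coupling: float = 4.0  # beta: log-odds of delayed recall per unit drop
    accuracy_memory_coupling: float = 0.8  # log-odds per correct round (centered)
    recall_s3_rate: float = 0.5
    recall_learning_curve: tuple[float, ...] = (0.30, 0.55, 0.75, 0.85)
    ability_sd: float = 1.0  # item random effect on correctness log-odds
    competition_start_range: tuple[float, float] = (0.60, 0.95)
    competition_drop_mean: float = 0.12  # per-round expected decrement
    competition_drop_item_sd: float = 0.08
    competition_drop_round_sd: float = 0.05
    rt_delay_s: float = 2.0  # enforced response delay; RTs measured from onset
    rt_base_s: float = 0.8  # median latency of first keystroke past the delay
    rt_item_sd: float = 0.50  # log-scale; item variance dominates round trend
    rt_round_slope: float = 0.05  # log-scale decrease per round
    rt_noise_sd: float = 0.15
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "n_channels",
            "n_categories",
            "n_exemplars_per_category",
            "n_items_s2",
            "n_rounds",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.epoch_span[1] <= self.epoch_span[0]:
            raise ConfigurationError("epoch_span must be an increasing (pre, post) pair")
        curve = np.asarray(self.recall_learning_curve, dtype=float)
        if curve.shape != (self.n_rounds,):
            raise ConfigurationError("recall_learning_curve must have one entry per round")
        if np.any(curve < 0) or np.any(curve > 1):
            raise ConfigurationError("recall probabilities must lie in [0, 1]")
        if np.any(np.diff(curve) < 0):
            raise ConfigurationError("recall_learning_curve must be non-decreasing")
        if not 0 < self.recall_s3_rate < 1:
            raise ConfigurationError("recall_s3_rate must lie in (0, 1)")
        if self.signal_topography is not None:
            topo = np.asarray(self.signal_topography, dtype=float)
            if topo.shape != (self.n_channels,):
                raise ConfigurationError("signal_topography length must equal n_channels")

    # --- derived quantities -------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms (sample grid over epoch_span)."""
        t0, t1 = self.epoch_span
        n = int(round((t1 - t0) * self.sampling_rate / 1000.0))
        return t0 + np.arange(n) * 1000.0 / self.sampling_rate

    @property
    def n_trials_s1(self) -> int:
        return self.n_categories * self.n_exemplars_per_category * 2

    def topography(self) -> np.ndarray:
        if self.signal_topography is not None:
            topo = np.asarray(self.signal_topography, dtype=float)
        else:
            topo = default_topography(self.n_channels)
        return topo

    def envelope(self) -> np.ndarray:
        """Temporal envelope supported exactly on signal_window.

        A tapered plateau (Tukey window, 30% taper): the signal rises
        smoothly from zero at the window edges and sustains full amplitude
        over the interior, mimicking a sustained evoked component rather
        than a transient peak.
        """
        from scipy.signal.windows import tukey

        t = self.times
        lo, hi = self.signal_window
        env = np.zeros_like(t)
        inside = (t >= lo) & (t < hi)
        if inside.any():
            env[inside] = tukey(inside.sum() + 2, alpha=0.3)[1:-1]
        return env

    def recall_link(self) -> tuple[float, float, float]:
        """(alpha, drop_center, correct_center) of the delayed-recall logistic link.

        log-odds(recalled) = alpha + beta * (drop - drop_center)
                                   + gamma * (n_correct - correct_center)
        with beta = drop_memory_coupling, gamma = accuracy_memory_coupling.
        Centers are config-level expectations, so the marginal recall rate
        stays near ``recall_s3_rate``.
        """
        alpha = float(logit(self.recall_s3_rate))
        drop_center = (self.n_rounds - 1) * self.competition_drop_mean
        correct_center = float(np.sum(self.recall_learning_curve))
        return alpha, drop_center, correct_center


def default_topography(n_channels: int) -> np.ndarray:
    """Smooth dipolar channel loading pattern, unit norm.

    Positive lobe near one third of the array, negative lobe near two
    thirds — a minimal stand-in for a posterior/frontal dipole so that
    pattern-recovery (Haufe) checks have a nontrivial target.
    """
    idx = np.arange(n_channels, dtype=float)
    width = max(n_channels / 8.0, 1.0)
    topo = np.exp(-0.5 * ((idx - n_channels / 3.0) / width) ** 2)
    topo -= 0.6 * np.exp(-0.5 * ((idx - 2.0 * n_channels / 3.0) / width) ** 2)
    return topo / np.linalg.norm(topo)


@dataclass
class GroundTruth:
    """Planted parameters underlying a simulated dataset.

    ``items`` (Session 2) has one row per subject x item with the latent
    competition level per round, the generative total drop (round 1 minus
    round 4 latent), the planted analysis drop (first-correct round minus
    round 4; NaN for items failing the retention rule), correctness bits,
    reaction times, and the delayed-recall label. ``s1_trials`` (Session 1)
    records the class label per trial.
    """

    topography: np.ndarray
    signal_window: tuple[float, float]
    s1_trials: pd.DataFrame | None = None
    items: pd.DataFrame | None = None
    recall_link: tuple[float, float, float] | None = None

    def behavior_table(self) -> pd.DataFrame:
        """Long-format behavioral table (one row per subject x item x round)."""
        if self.items is None:
            raise ValueError("no Session 2 ground truth present")
        rounds = [c for c in self.items.columns if c.startswith("correct_r")]
        n_rounds = len(rounds)
        rows = []
        for _, rec in self.items.iterrows():
            for r in range(1, n_rounds + 1):
                rows.append(
                    {
                        "subject": rec["subject"],
                        "item": rec["item"],
                        "round": r,
                        "correct": int(rec[f"correct_r{r}"]),
                        "rt_s": float(rec[f"rt_r{r}"]),
                        "recalled_s3": int(rec["recalled_s3"]),
                    }
                )
        return pd.DataFrame(rows)


# --- noise ------------------------------------------------------------------


def _correlated_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_channels: int,
    n_times: int,
    chol: np.ndarray,
    model: NoiseModel,
) -> np.ndarray:
    z = rng.standard_normal((n_trials, n_channels, n_times))
    phi = model.ar_coeff
    if phi:
        scale = np.sqrt(1.0 - phi**2)
        # stationary AR(1): x[0] = z[0], x[t] = phi x[t-1] + scale z[t]
        z[..., 0] /= scale
        z = lfilter([scale], [1.0, -phi], z, axis=-1)
    out = np.einsum("ij,njt->nit", chol, z)
    out *= model.std
    return out


def _signal_pattern(config: SimulationConfig) -> np.ndarray:
    """(channels x times) unit-amplitude planted pattern."""
    return config.topography()[:, None] * config.envelope()[None, :]


def _subject_rng(config: SimulationConfig, stream: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream, subject]))


# --- Session 1 --------------------------------------------------------------


def simulate_session1(config: SimulationConfig) -> tuple[EpochSet, GroundTruth]:
    """Simulate the competition-localizer test phase for all subjects.

    One trial per category x exemplar x condition cell, randomly
    interleaved per subject; high-competition trials carry ``+0.5`` and
    low-competition trials ``-0.5`` times ``effect_size`` times the planted
    spatiotemporal pattern.
    """
    chol = config.noise.channel_cholesky(config.n_channels)
    pattern = _signal_pattern(config)
    times = config.times
    n_trials = config.n_trials_s1

    data_blocks, meta_blocks = [], []
    for subject in range(config.n_subjects):
        rng = _subject_rng(config, _S1_STREAM, subject)
        cat, exe, cond = np.meshgrid(
            np.arange(config.n_categories),
            np.arange(config.n_exemplars_per_category),
            np.array([0, 1]),
            indexing="ij",
        )
        order = rng.permutation(n_trials)
        meta = pd.DataFrame(
            {
                "subject": subject,
                "category": cat.ravel()[order],
                "exemplar": exe.ravel()[order],
                "condition": cond.ravel()[order],  # 1 = high competition
            }
        )
        noise = _correlated_noise(rng, n_trials, config.n_channels, times.size, chol, config.noise)
        amp = (meta["condition"].to_numpy() - 0.5) * config.effect_size
        data = noise + amp[:, None, None] * pattern[None, :, :]
        data_blocks.append(data)
        meta_blocks.append(meta)

    epochs = EpochSet(
        data=np.concatenate(data_blocks, axis=0),
        times=times,
        sfreq=config.sampling_rate,
        metadata=pd.concat(meta_blocks, ignore_index=True),
    )
    truth = GroundTruth(
        topography=config.topography(),
        signal_window=config.signal_window,
        s1_trials=epochs.metadata.copy(),
    )
    return epochs, truth


# --- Session 2/3 ------------------------------------------------------------


def _simulate_items(config: SimulationConfig, subject: int, rng: np.random.Generator) -> pd.DataFrame:
    """Latent trajectories, correctness, RTs and delayed recall for one subject."""
    n_items, n_rounds = config.n_items_s2, config.n_rounds
    lo, hi = config.competition_start_range
    c = np.empty((n_items, n_rounds))
    c[:, 0] = rng.uniform(lo, hi, size=n_items)
    item_drop = np.clip(
        rng.normal(config.competition_drop_mean, config.competition_drop_item_sd, size=n_items),
        0.0,
        None,
    )
    for r in range(1, n_rounds):
        step = np.clip(
            rng.normal(item_drop, config.competition_drop_round_sd), 0.0, None
        )
        c[:, r] = np.clip(c[:, r - 1] - step, 0.0, 1.0)

    curve = np.asarray(config.recall_learning_curve, dtype=float)
    ability = rng.normal(0.0, config.ability_sd, size=n_items)
    p_correct = np.empty((n_items, n_rounds))
    for r in range(n_rounds):
        if curve[r] <= 0.0:
            p_correct[:, r] = 0.0
        elif curve[r] >= 1.0:
            p_correct[:, r] = 1.0
        else:
            p_correct[:, r] = expit(logit(curve[r]) + ability)
    correct = (rng.random((n_items, n_rounds)) < p_correct).astype(int)

    any_correct = correct.any(axis=1)
    first_correct = np.where(any_correct, correct.argmax(axis=1) + 1, 0)  # 1-based, 0 = never
    retained = any_correct & (correct[:, -1] == 1)
    generative_drop = c[:, 0] - c[:, -1]
    planted_drop = np.where(
        retained, c[np.arange(n_items), np.maximum(first_correct - 1, 0)] - c[:, -1], np.nan
    )

    alpha, drop_center, correct_center = config.recall_link()
    logodds = (
        alpha
        + config.drop_memory_coupling * (generative_drop - drop_center)
        + config.accuracy_memory_coupling * (correct.sum(axis=1) - correct_center)
    )
    recalled = (rng.random(n_items) < expit(logodds)).astype(int)

    item_rt = rng.normal(0.0, config.rt_item_sd, size=n_items)
    rt = config.rt_delay_s + np.exp(
        np.log(config.rt_base_s)
        + item_rt[:, None]
        - config.rt_round_slope * np.arange(n_rounds)[None, :]
        + rng.normal(0.0, config.rt_noise_sd, size=(n_items, n_rounds))
    )

    rec = {
        "subject": subject,
        "item": np.arange(n_items),
        "first_correct_round": first_correct,
        "retained": retained,
        "generative_drop": generative_drop,
        "planted_drop": planted_drop,
        "recalled_s3": recalled,
    }
    for r in range(n_rounds):
        rec[f"latent_r{r + 1}"] = c[:, r]
        rec[f"correct_r{r + 1}"] = correct[:, r]
        rec[f"rt_r{r + 1}"] = rt[:, r]
    df = pd.DataFrame(rec)
    df["configuration"] = df[[f"correct_r{r + 1}" for r in range(n_rounds)]].astype(str).agg(
        "".join, axis=1
    )
    return df


def simulate_behavior(config: SimulationConfig) -> GroundTruth:
    """Generate the Session 2/3 behavioral ground truth only (no EEG).

    Cheap path for behavioral analyses and for design-count checks at the
    full 40-subject scale, where materializing all EEG epochs at once would
    be wasteful.
    """
    frames = [
        _simulate_items(config, s, _subject_rng(config, _S2_STREAM, s))
        for s in range(config.n_subjects)
    ]
    return GroundTruth(
        topography=config.topography(),
        signal_window=config.signal_window,
        items=pd.concat(frames, ignore_index=True),
        recall_link=config.recall_link(),
    )


def simulate_session2(config: SimulationConfig) -> tuple[EpochSet, GroundTruth]:
    """Simulate Session 2 study + retrieval EEG epochs for all subjects.

    Retrieval epochs scale the planted pattern by the item's latent
    competition level that round (centered at 0.5, so latent 1 matches the
    Session 1 high-competition mean and latent 0 the low-competition mean).
    Study epochs use the item's round-1 latent level for every round, i.e.
    no round-dependent signal, making the study control null by design.
    """
    chol = config.noise.channel_cholesky(config.n_channels)
    pattern = _signal_pattern(config)
    times = config.times

    data_blocks, meta_blocks, item_frames = [], [], []
    for subject in range(config.n_subjects):
        rng = _subject_rng(config, _S2_STREAM, subject)
        items = _simulate_items(config, subject, rng)
        item_frames.append(items)

        metas, amps = [], []
        for r in range(1, config.n_rounds + 1):
            for trial_type in ("study", "retrieval"):
                order = rng.permutation(config.n_items_s2)
                level = items[f"latent_r{1 if trial_type == 'study' else r}"].to_numpy()[order]
                metas.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "item": items["item"].to_numpy()[order],
                            "round": r,
                            "trial_type": trial_type,
                        }
                    )
                )
                amps.append((level - 0.5) * config.effect_size)
        meta = pd.concat(metas, ignore_index=True)
        amp = np.concatenate(amps)
        noise = _correlated_noise(
            rng, len(meta), config.n_channels, times.size, chol, config.noise
        )
        data_blocks.append(noise + amp[:, None, None] * pattern[None, :, :])
        meta_blocks.append(meta)

    items_all = pd.concat(item_frames, ignore_index=True)
    meta_all = pd.concat(meta_blocks, ignore_index=True)
    meta_all = meta_all.merge(
        items_all[["subject", "item", "recalled_s3"]], on=["subject", "item"], how="left"
    )
    epochs = EpochSet(
        data=np.concatenate(data_blocks, axis=0),
        times=times,
        sfreq=config.sampling_rate,
        metadata=meta_all,
    )
    truth = GroundTruth(
        topography=config.topography(),
        signal_window=config.signal_window,
        items=items_all,
        recall_link=config.recall_link(),
    )
    return epochs, truth
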