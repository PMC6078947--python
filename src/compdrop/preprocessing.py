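"""Deterministic signal conditioning: filtering, re-referencing, epoching,
baseline correction and theta-band power extraction.

The voltage chain is band-pass (2-200 Hz) with a 60 Hz line-noise notch,
whole-scalp average re-reference, epoching on stimulus onsets, and
per-epoch baseline subtraction. The theta chain band-passes 4-8 Hz and
takes the analytic-signal (Hilbert) envelope, squared by default, with no
baseline correction.

Filter realizations are zero-phase: the broadband band-pass is a
linear-phase FIR (Hamming window) applied forward-backward, the notch a
second-order IIR (quality factor 30) applied forward-backward, and the
theta band-pass a 4th-order Butterworth applied forward-backward. All
operations are deterministic.

Artifact handling on real recordings (visual inspection, blink-component
removal) is out of scope; :func:`reject_epochs_by_amplitude` provides a
simple peak-to-peak rejection hook for recorded data. Synthetic data are
artifact-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._exceptions import ConfigurationError
from .containers import EpochSet

__all__ = [
    "FilterSpec",
    "bandpass_notch",
    "rereference_average",
    "epoch_and_baseline",
    "theta_power",
    "reject_epochs_by_amplitude",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch specification for the broadband voltage chain."""

    band_lo: float = 2.0
    band_hi: float = 200.0
    notch: float = 60.0
    fir_taps_per_lo_cycle: float = 3.3  # FIR length = this / band_lo seconds
    notch_q: float = 30.0

    def validate(self, sfreq: float) -> None:
        nyq = sfreq / 2.0
        if not 0 < self.band_lo < self.band_hi:
            raise ConfigurationError("need 0 < band_lo < band_hi")
        if self.band_hi >= nyq:
            raise ConfigurationError(
                f"band_hi {self.band_hi} Hz exceeds Nyquist {nyq} Hz at fs={sfreq}"
            )
        if not self.band_lo < self.notch < self.band_hi:
            raise ConfigurationError("notch frequency must lie inside the pass band")

    def n_taps(self, sfreq: float) -> int:
        n = int(round(self.fir_taps_per_lo_cycle * sfreq / self.band_lo))
        return n + 1 - n % 2  # odd length keeps the FIR type-I / zero-delay symmetric


def bandpass_notch(data: np.ndarray, sfreq: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase band-pass + notch along the last axis.

    Accepts any array whose last axis is time (continuous multichannel
    recordings or epochs). Attenuation at the notch frequency exceeds 20 dB
    and the band edges are -6 dB points of the FIR design.
    """
    spec = spec or FilterSpec()
    spec.validate(sfreq)
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ConfigurationError("input contains non-finite samples")
    taps = sps.firwin(
        spec.n_taps(sfreq),
        [spec.band_lo, spec.band_hi],
        pass_zero=False,
        fs=sfreq,
        window="hamming",
    )
    n = data.shape[-1]
    if n <= len(taps):
        raise ConfigurationError(
            f"signal of {n} samples is shorter than the {len(taps)}-tap band-pass FIR; "
            "filter continuous data before epoching"
        )
    out = sps.filtfilt(taps, [1.0], data, axis=-1, padlen=min(3 * len(taps), n - 1))
    b, a = sps.iirnotch(spec.notch, spec.notch_q, fs=sfreq)
    out = sps.filtfilt(b, a, out, axis=-1)
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Whole-scalp average reference: subtract the channel mean per timepoint."""
    if epochs.n_channels < 2:
        raise ConfigurationError("average re-reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(
        data=data,
        times=epochs.times,
        sfreq=epochs.sfreq,
        metadata=epochs.metadata.copy(),
        channel_names=list(epochs.channel_names),
    )


def epoch_and_baseline(
    data: np.ndarray,
    sfreq: float,
    onsets: np.ndarray,
    span_ms: tuple[float, float] = (-100.0, 1000.0),
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
    metadata: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut a continuous (channels x samples) recording into onset-locked epochs.

    ``onsets`` are sample indices of stimulus onset. Epochs whose span falls
    outside the recording are dropped (count logged); the matching metadata
    rows are dropped with them. When ``baseline_ms`` is given, the per-epoch,
    per-channel mean over that window (which must lie inside the epoch span)
    is subtracted.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("continuous data must be (channels, samples)")
    onsets = np.asarray(onsets, dtype=int)
    t0, t1 = span_ms
    start_off = int(round(t0 * sfreq / 1000.0))
    n_samp = int(round((t1 - t0) * sfreq / 1000.0))
    times = t0 + np.arange(n_samp) * 1000.0 / sfreq

    keep = (onsets + start_off >= 0) & (onsets + start_off + n_samp <= data.shape[1])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("epoch_and_baseline: dropped %d epochs outside the recording", n_dropped)
    kept = onsets[keep]
    epochs = np.stack([data[:, o + start_off : o + start_off + n_samp] for o in kept], axis=0) if len(
        kept
    ) else np.empty((0, data.shape[0], n_samp))

    if baseline_ms is not None:
        b0, b1 = baseline_ms
        if b1 <= b0:
            raise ConfigurationError("baseline window must be a non-empty (start, end) pair")
        sel = (times >= b0) & (times < b1)
        if not sel.any():
            raise ConfigurationError("baseline window contains no samples within the epoch span")
        epochs = epochs - epochs[:, :, sel].mean(axis=2, keepdims=True)

    if metadata is None:
        metadata = pd.DataFrame({"onset_sample": kept})
    else:
        if len(metadata) != len(onsets):
            raise ConfigurationError("metadata must have one row per onset")
        metadata = metadata.iloc[np.flatnonzero(keep)].reset_index(drop=True)
    return EpochSet(data=epochs, times=times, sfreq=sfreq, metadata=metadata)


def theta_power(
    epochs: EpochSet,
    band: tuple[float, float] = (4.0, 8.0),
    order: int = 4,
    output: str = "power",
) -> EpochSet:
    """Theta-band (4-8 Hz inclusive) Hilbert envelope per channel.

    ``output='power'`` (default) squares the analytic-signal magnitude;
    ``output='magnitude'`` returns the envelope itself. No baseline
    correction is applied. Raises if the epoch is shorter than the filter
    warm-up (about three cycles of the band's low edge).
    """
    if output not in ("power", "magnitude"):
        raise ConfigurationError("output must be 'power' or 'magnitude'")
    lo, hi = band
    if not 0 < lo < hi < epochs.sfreq / 2:
        raise ConfigurationError("theta band must satisfy 0 < lo < hi < Nyquist")
    min_samples = int(3 * epochs.sfreq / lo)
    if epochs.n_times < min_samples:
        raise ConfigurationError(
            f"epoch too short for theta extraction: {epochs.n_times} < {min_samples} samples"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=epochs.sfreq, output="sos")
    filtered = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    envelope = np.abs(sps.hilbert(filtered, axis=-1))
    out = envelope**2 if output == "power" else envelope
    return EpochSet(
        data=out,
        times=epochs.times,
        sfreq=epochs.sfreq,
        metadata=epochs.metadata.copy(),
        channel_names=list(epochs.channel_names),
    )


def reject_epochs_by_amplitude(epochs: EpochSet, peak_to_peak: float) -> EpochSet:
    """Drop epochs whose any-channel peak-to-peak amplitude exceeds a threshold.

    A stand-in hook for artifact screening of recorded data; counts are
    logged. Synthetic data normally pass untouched.
    """
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    keep = (ptp <= peak_to_peak).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("amplitude rejection: dropped %d of %d epochs", n_dropped, epochs.n_trials)
    return epochs.select(keep)
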