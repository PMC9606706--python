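"""Sensor-space preprocessing chain for epoched EEG.

The chain is band-pass filtering (0.5-100 Hz linear-phase FIR, Kaiser window
beta = 7.2, order 462), hard-threshold trial rejection at -200/+800 uV,
average re-referencing, and deterministic trial-count equalization. All
steps are seedless and order-stable. Filtering is single-pass linear-phase
FIR with group-delay compensation (centred convolution), so the designed
magnitude response applies exactly and evoked latencies are not shifted;
the first/last ``order/2`` samples of an epoch are edge-contaminated.

Channel interpolation and ICA-based ocular artifact removal have no synthetic
counterpart here (the generator produces neither dead channels nor eye
movements); this module is where they would slot into the chain.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, firwin

from .simulate import SensorEpochs

__all__ = [
    "bandpass_filter",
    "reject_trials",
    "average_reference",
    "equalize_trials",
    "baseline_correct",
    "preprocess_chain",
]

BANDPASS_ORDER = 462
KAISER_BETA = 7.2
REJECT_LO = -200e-6
REJECT_HI = 800e-6


class LengthError(ValueError):
    """Epoch too short for the requested filter."""


def _fir_bandpass(fs: float, low: float, high: float) -> np.ndarray:
    return firwin(
        BANDPASS_ORDER + 1,
        [low, high],
        pass_zero=False,
        window=("kaiser", KAISER_BETA),
        fs=fs,
    )


def _filter_time_axis(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # odd-length symmetric FIR + centred convolution == delay-compensated
    return fftconvolve(data, taps.reshape((1,) * (data.ndim - 1) + (-1,)), mode="same", axes=-1)


def bandpass_filter(epochs: SensorEpochs, low: float = 0.5, high: float = 100.0) -> SensorEpochs:
    """Zero-delay band-pass (Kaiser FIR, beta 7.2, order 462)."""
    if epochs.fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    if epochs.data.shape[-1] < 3 * BANDPASS_ORDER:
        raise LengthError("epoch shorter than three filter orders")
    taps = _fir_bandpass(epochs.fs, low, high)
    return SensorEpochs(
        data=_filter_time_axis(epochs.data, taps),
        fs=epochs.fs,
        epoch_window=epochs.epoch_window,
        channel_labels=epochs.channel_labels,
    )


def reject_trials(
    epochs: SensorEpochs, lo: float = REJECT_LO, hi: float = REJECT_HI
) -> tuple[SensorEpochs, np.ndarray]:
    """Drop any trial containing a sample outside [lo, hi] volts.

    Returns the surviving epochs and the boolean keep-mask over input trials.
    """
    if lo >= hi:
        raise ValueError("lower threshold must be below the upper threshold")
    bad = np.any((epochs.data < lo) | (epochs.data > hi), axis=(1, 2))
    keep = ~bad
    return (
        SensorEpochs(
            data=epochs.data[keep],
            fs=epochs.fs,
            epoch_window=epochs.epoch_window,
            channel_labels=epochs.channel_labels,
        ),
        keep,
    )


def average_reference(epochs: SensorEpochs) -> SensorEpochs:
    """Subtract the instantaneous mean over channels from every channel."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference needs at least two channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return SensorEpochs(
        data=data,
        fs=epochs.fs,
        epoch_window=epochs.epoch_window,
        channel_labels=epochs.channel_labels,
    )


def equalize_selection(n_available: int, target: int) -> np.ndarray:
    """Evenly spaced trial indices: round(k*N/target), duplicates pushed forward.

    Keeps the selected trials spread across the whole recording, the
    deterministic formalization of pseudo-selection.
    """
    if target > n_available:
        raise ValueError("target exceeds available trial count")
    if target < 1:
        raise ValueError("target must be >= 1")
    idx = np.round(np.arange(target) * n_available / target).astype(int)
    idx = np.minimum(idx, n_available - 1)
    for k in range(1, target):  # resolve duplicates forward
        if idx[k] <= idx[k - 1]:
            idx[k] = idx[k - 1] + 1
    if idx[-1] >= n_available:
        raise ValueError("cannot resolve duplicates within the available trials")
    return idx


def equalize_trials(
    epochs_list: list[SensorEpochs], target: int | None = None
) -> list[SensorEpochs]:
    """Subsample every epochs object to a common (minimum) trial count."""
    counts = [e.n_trials for e in epochs_list]
    if any(c < 1 for c in counts):
        raise ValueError("all inputs need at least one trial")
    tgt = min(counts) if target is None else target
    out = []
    for e in epochs_list:
        idx = equalize_selection(e.n_trials, tgt)
        out.append(
            SensorEpochs(
                data=e.data[idx],
                fs=e.fs,
                epoch_window=e.epoch_window,
                channel_labels=e.channel_labels,
            )
        )
    return out


def baseline_correct(
    values: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Subtract the mean over the baseline window along the last (time) axis."""
    mask = (times >= window[0]) & (times <= window[1])
    if not np.any(mask):
        raise ValueError("baseline window contains no samples")
    return values - values[..., mask].mean(axis=-1, keepdims=True)


def preprocess_chain(epochs: SensorEpochs) -> tuple[SensorEpochs, np.ndarray]:
    """filter -> reject -> average-reference; returns epochs and keep-mask."""
    filtered = bandpass_filter(epochs)
    kept, mask = reject_trials(filtered)
    return average_reference(kept), mask
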