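"""Vehicular signal conditioning: resampling, scaling, epoch alignment.

Telemetry recorded at 10 Hz (velocity, acceleration, lateral and
longitudinal acceleration) is brought onto the EEG clock by polyphase
rational resampling (x256 up, /10 down, zero-phase anti-aliasing FIR cut at
the 5 Hz input Nyquist), min-max scaled to [0, 1], and reduced to one value
per EEG epoch so the rows of the vehicular feature matrix refer to exactly
the same 2 s windows as the EEG feature matrices.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .simulate import EEG_SFREQ, VEH_SFREQ


def resample_to_eeg_rate(
    x: np.ndarray, up: int = EEG_SFREQ, down: int = VEH_SFREQ
) -> np.ndarray:
    """Polyphase resampling from 10 Hz to 256 Hz along the last axis.

    Output length is ceil(n * up / down).  The anti-aliasing FIR is the
    Kaiser-windowed design of :func:`scipy.signal.resample_poly`, applied
    zero-phase, with cutoff at the input Nyquist (5 Hz); edges are padded by
    linear extension so constant signals pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples to resample")
    # centring makes the DC level exact (polyphase branch gains are only
    # approximately equal); "line" padding keeps edges well-behaved
    mean = x.mean(axis=-1, keepdims=True)
    return sps.resample_poly(x - mean, up, down, axis=-1, padtype="line") + mean


def minmax_normalize(
    matrix: np.ndarray, ranges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (x - min) / (max - min) scaling to [0, 1].

    When ``ranges`` (a (2, n_cols) array of training min/max) is supplied it
    is applied as-is and the output is clipped to [0, 1], so test data never
    leak into the scaling.  Returns the scaled matrix and the ranges used.
    """
    matrix = np.asarray(matrix, dtype=float)
    if ranges is None:
        lo = matrix.min(axis=0)
        hi = matrix.max(axis=0)
        degenerate = np.flatnonzero(hi - lo == 0)
        if degenerate.size:
            raise ValueError(f"constant column(s) {degenerate.tolist()} with no supplied range")
        ranges = np.vstack([lo, hi])
        return (matrix - lo) / (hi - lo), ranges
    ranges = np.asarray(ranges, dtype=float)
    lo, hi = ranges[0], ranges[1]
    scaled = (matrix - lo) / (hi - lo)
    return np.clip(scaled, 0.0, 1.0), ranges


def epoch_align(
    signal_256hz: np.ndarray, start_times_s: np.ndarray,
    sfreq: int = EEG_SFREQ, length_s: float = 2.0,
) -> np.ndarray:
    """Per-epoch mean of each channel over the 2 s epoch windows.

    ``signal_256hz`` is (n_channels, n_samples); the returned matrix is
    (n_epochs, n_channels) with rows aligned to ``start_times_s`` (typically
    the kept-epoch onsets of the EEG :class:`~miwl.eeg.EpochSet`).
    """
    x = np.atleast_2d(np.asarray(signal_256hz, dtype=float))
    win = int(round(length_s * sfreq))
    starts = np.round(np.asarray(start_times_s) * sfreq).astype(int)
    if starts.size and starts.max() + win > x.shape[1]:
        raise ValueError("epoch grid extends beyond the vehicular signal")
    out = np.empty((starts.size, x.shape[0]))
    for i, s in enumerate(starts):
        out[i] = x[:, s:s + win].mean(axis=1)
    return out


def align_session_vehicular(
    vehicular_10hz: np.ndarray, start_times_s: np.ndarray
) -> np.ndarray:
    """Resample raw 10 Hz telemetry to 256 Hz and reduce to per-epoch means."""
    return epoch_align(resample_to_eeg_rate(vehicular_10hz), start_times_s)
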