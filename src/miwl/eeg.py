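"""EEG preprocessing and spectral feature extraction.

Raw 15-channel EEG at 256 Hz is band-pass filtered (1-30 Hz, fourth-order
zero-phase Butterworth), corrected for eye blinks by channel-wise regression
on the Fpz reference, segmented into 2 s epochs advanced every 0.125 s,
screened by three artifact criteria (amplitude, trend, sample-to-sample
step), and reduced to Hann-windowed periodograms at 0.5 Hz resolution.
Band features are anchored to the individual alpha frequency (IAF): theta
[IAF-6, IAF-2], alpha [IAF-2, IAF+2], beta [IAF+2, IAF+18] Hz.

Two feature representations are produced per kept epoch:

* ``band_features_45`` - mean band power for 3 rhythms x 15 channels, with a
  fixed channel-major feature-ID layout (theta@Fpz = 1 ... beta@O2 = 45);
* ``roi_psd_matrix_187`` - the raw 0.5 Hz PSD bins over an 11-channel region
  of interest and 17 bins from IAF-6 to IAF+2, of which 99 columns
  (frontal-theta and parietal-alpha) are eligible for workload-index
  selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import CHANNELS, EEG_SFREQ

#: Channel order defining spectral feature IDs 1..45 (channel-major,
#: rhythm-minor: theta@Fpz=1, alpha@Fpz=2, beta@Fpz=3, theta@Fz=4, ...).
FEATURE_CHANNEL_ORDER = CHANNELS
RHYTHMS = ("theta", "alpha", "beta")

#: Region-of-interest channels for the workload index: Fpz is excluded from
#: the frontal set because it is consumed by blink correction; 5 frontal x 9
#: theta bins = 45 and 6 parietal x 9 alpha bins = 54 eligible columns.
FRONTAL_ROI = ("Fz", "AF3", "AF4", "F3", "F4")
PARIETAL_ROI = ("Pz", "POz", "P3", "P4", "P5", "P6")
ROI_CHANNELS = FRONTAL_ROI + PARIETAL_ROI

#: Posterior channels used for resting-state IAF estimation.
IAF_CHANNELS = ("Pz", "POz", "Oz", "P3", "P4", "P5", "P6", "O1", "O2")


def feature_names_45() -> list[str]:
    return [f"{r}@{ch}" for ch in FEATURE_CHANNEL_ORDER for r in RHYTHMS]


@dataclass
class EpochSet:
    """2 s epochs on the 0.125 s grid with per-epoch artifact bookkeeping."""

    epochs: np.ndarray           # (n_epochs, n_channels, n_samples)
    start_times_s: np.ndarray
    channel_names: tuple
    keep_mask: np.ndarray = None
    rejection_reasons: list = None
    sfreq: int = EEG_SFREQ

    def __post_init__(self):
        n = self.epochs.shape[0]
        if self.keep_mask is None:
            self.keep_mask = np.ones(n, dtype=bool)
        if self.rejection_reasons is None:
            self.rejection_reasons = [set() for _ in range(n)]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def rejected_fraction(self) -> float:
        return float(1.0 - self.keep_mask.mean())

    def kept(self) -> "EpochSet":
        m = self.keep_mask
        return EpochSet(
            epochs=self.epochs[m],
            start_times_s=self.start_times_s[m],
            channel_names=self.channel_names,
            keep_mask=np.ones(int(m.sum()), dtype=bool),
            rejection_reasons=[set() for _ in range(int(m.sum()))],
            sfreq=self.sfreq,
        )


@dataclass
class PSDSet:
    """Per-epoch, per-channel power spectral density (uV^2/Hz) at 0.5 Hz bins."""

    psd: np.ndarray       # (n_epochs, n_channels, n_freqs)
    freqs_hz: np.ndarray
    channel_names: tuple
    start_times_s: np.ndarray = None


@dataclass
class IAFEstimate:
    """Individual alpha frequency and the band edges derived from it."""

    iaf_hz: float

    def __post_init__(self):
        if not 8.0 <= self.iaf_hz <= 12.0:
            raise ValueError("IAF must lie in [8, 12] Hz")

    @property
    def theta_band(self) -> tuple[float, float]:
        return (self.iaf_hz - 6.0, self.iaf_hz - 2.0)

    @property
    def alpha_band(self) -> tuple[float, float]:
        return (self.iaf_hz - 2.0, self.iaf_hz + 2.0)

    @property
    def beta_band(self) -> tuple[float, float]:
        return (self.iaf_hz + 2.0, self.iaf_hz + 18.0)


@dataclass
class SpectralFeatureMatrix:
    """Per-epoch spectral features: the 45-band matrix and the 187-bin ROI matrix."""

    band45: np.ndarray          # (n_epochs, 45)
    roi187: np.ndarray          # (n_epochs, 187)
    eligible99: np.ndarray      # boolean mask over the 187 columns, sums to 99
    iaf: IAFEstimate = None
    start_times_s: np.ndarray = None


def bandpass_filter(
    x: np.ndarray, low_hz: float = 1.0, high_hz: float = 30.0, order: int = 4,
    sfreq: float = EEG_SFREQ,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, applied per channel."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if high_hz >= sfreq / 2:
        raise ValueError("high cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=sfreq, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def detect_blink_intervals(
    reference: np.ndarray, sfreq: float = EEG_SFREQ,
    threshold_uv: float = 40.0, pad_s: float = 0.1,
) -> list[tuple[int, int]]:
    """Half-open sample intervals where the low-passed reference exceeds threshold."""
    sos = sps.butter(4, 6.0, btype="low", fs=sfreq, output="sos")
    ref_lp = sps.sosfiltfilt(sos, reference)
    above = np.abs(ref_lp - np.median(ref_lp)) > threshold_uv
    if not above.any():
        return []
    pad = int(round(pad_s * sfreq))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        s, e = max(0, s - pad), min(reference.size, e + pad)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def remove_blinks(
    eeg: np.ndarray, channel_names, reference_channel: str = "Fpz",
    sfreq: float = EEG_SFREQ, threshold_uv: float = 40.0,
) -> np.ndarray:
    """Regress the blink reference out of each channel inside detected blink intervals.

    Blink intervals are found on the low-pass-filtered reference channel by an
    amplitude criterion; within each interval every channel has its
    least-squares projection on the (low-passed) reference subtracted.
    Samples outside intervals are untouched and none are dropped.
    """
    names = list(channel_names)
    if reference_channel not in names:
        raise ValueError(f"reference channel {reference_channel!r} not present")
    ref = eeg[names.index(reference_channel)]
    intervals = detect_blink_intervals(ref, sfreq=sfreq, threshold_uv=threshold_uv)
    if not intervals:
        return eeg.copy()
    sos = sps.butter(4, 6.0, btype="low", fs=sfreq, output="sos")
    ref_lp = sps.sosfiltfilt(sos, ref)
    out = eeg.copy()
    for s, e in intervals:
        seg = ref_lp[s:e] - ref_lp[s:e].mean()
        denom = float(seg @ seg)
        if denom == 0.0:
            continue
        for ci in range(out.shape[0]):
            beta = float(out[ci, s:e] @ seg) / denom
            out[ci, s:e] -= beta * seg
    return out


def segment_epochs(
    x: np.ndarray, channel_names=CHANNELS, sfreq: int = EEG_SFREQ,
    length_s: float = 2.0, shift_s: float = 0.125,
) -> EpochSet:
    """Cut a (channels, samples) signal into overlapping half-open epochs.

    Epoch k covers [k*shift, k*shift + length) seconds; the count is
    floor((T - length)/shift) + 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    win = int(round(length_s * sfreq))
    step = int(round(shift_s * sfreq))
    if x.shape[1] < win:
        raise ValueError("signal shorter than one epoch")
    n_ep = (x.shape[1] - win) // step + 1
    idx = np.arange(win)[None, :] + step * np.arange(n_ep)[:, None]
    epochs = x.T[idx].transpose(0, 2, 1)  # (n_ep, n_ch, win)
    starts = step * np.arange(n_ep) / sfreq
    return EpochSet(
        epochs=epochs, start_times_s=starts, channel_names=tuple(channel_names),
        sfreq=sfreq,
    )


def reject_artifacts(
    epochs: EpochSet, amplitude_uv: float = 100.0,
    trend_uv_per_s: float = 10.0, step_uv: float = 25.0,
) -> EpochSet:
    """Flag epochs violating any of the three artifact criteria.

    (i) any sample beyond +-``amplitude_uv``; (ii) absolute slope of the
    least-squares line over the epoch above ``trend_uv_per_s``; (iii) any
    absolute sample-to-sample difference above ``step_uv``.  Violation on any
    channel rejects the whole epoch; reasons are recorded per epoch.
    """
    x = epochs.epochs  # (n_ep, n_ch, n_s)
    n_s = x.shape[2]
    t = np.arange(n_s) / epochs.sfreq
    tc = t - t.mean()
    denom = float(tc @ tc)
    slopes = (x * tc).sum(axis=2) / denom                     # (n_ep, n_ch) uV/s
    amp_bad = np.abs(x).max(axis=(1, 2)) > amplitude_uv
    trend_bad = np.abs(slopes).max(axis=1) > trend_uv_per_s
    step_bad = np.abs(np.diff(x, axis=2)).max(axis=(1, 2)) > step_uv
    keep = ~(amp_bad | trend_bad | step_bad)
    reasons = []
    for a, tr, st in zip(amp_bad, trend_bad, step_bad):
        r = set()
        if a:
            r.add("threshold")
        if tr:
            r.add("trend")
        if st:
            r.add("step")
        reasons.append(r)
    return EpochSet(
        epochs=epochs.epochs, start_times_s=epochs.start_times_s,
        channel_names=epochs.channel_names, keep_mask=keep,
        rejection_reasons=reasons, sfreq=epochs.sfreq,
    )


def compute_psd(epochs: EpochSet, kept_only: bool = True) -> PSDSet:
    """Hann-windowed periodogram per kept epoch per channel (0.5 Hz bins)."""
    src = epochs.kept() if kept_only else epochs
    freqs, psd = sps.periodogram(
        src.epochs, fs=src.sfreq, window="hann", detrend=False, scaling="density",
        axis=-1,
    )
    return PSDSet(
        psd=psd, freqs_hz=freqs, channel_names=src.channel_names,
        start_times_s=src.start_times_s,
    )


def estimate_iaf(resting_psd: PSDSet, channels=IAF_CHANNELS) -> IAFEstimate:
    """IAF = peak of the epoch- and channel-averaged resting PSD in [8, 12] Hz."""
    names = list(resting_psd.channel_names)
    missing = [c for c in channels if c not in names]
    if missing:
        raise ValueError(f"missing IAF channels: {missing}")
    sel = [names.index(c) for c in channels]
    mean_psd = resting_psd.psd[:, sel, :].mean(axis=(0, 1))
    band = (resting_psd.freqs_hz >= 8.0) & (resting_psd.freqs_hz <= 12.0)
    sub = mean_psd[band]
    peak = sub.max()
    if peak <= 0 or np.count_nonzero(sub == peak) > 1:
        ties = resting_psd.freqs_hz[band][sub == peak]
        raise ValueError(f"no unique alpha peak in [8, 12] Hz (tied at {ties} Hz)")
    return IAFEstimate(float(resting_psd.freqs_hz[band][int(np.argmax(sub))]))


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    # inclusive on both edges at the 0.5 Hz grid
    return (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)


def band_features_45(psd: PSDSet, iaf: IAFEstimate) -> np.ndarray:
    """Mean band power per rhythm per channel, columns ordered by feature ID."""
    names = list(psd.channel_names)
    missing = [c for c in FEATURE_CHANNEL_ORDER if c not in names]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    bands = {"theta": iaf.theta_band, "alpha": iaf.alpha_band, "beta": iaf.beta_band}
    cols = []
    for ch in FEATURE_CHANNEL_ORDER:
        ci = names.index(ch)
        for rhythm in RHYTHMS:
            mask = _band_bins(psd.freqs_hz, bands[rhythm])
            cols.append(psd.psd[:, ci, mask].mean(axis=1))
    return np.column_stack(cols)


def roi_psd_matrix_187(psd: PSDSet, iaf: IAFEstimate) -> tuple[np.ndarray, np.ndarray]:
    """ROI PSD matrix (11 channels x 17 bins, channel-major) and eligibility mask.

    Bins run from IAF-6 to IAF+2 Hz inclusive at 0.5 Hz.  Eligible columns are
    frontal channels x 9 theta bins [IAF-6, IAF-2] (45 columns) and parietal
    channels x 9 alpha bins [IAF-2, IAF+2] (54 columns); the IAF-2 bin is the
    shared band edge, eligible on both channel groups.
    """
    names = list(psd.channel_names)
    missing = [c for c in ROI_CHANNELS if c not in names]
    if missing:
        raise ValueError(f"missing ROI channels: {missing}")
    bin_freqs = iaf.iaf_hz - 6.0 + 0.5 * np.arange(17)
    bin_idx = np.searchsorted(psd.freqs_hz, bin_freqs - 1e-9)
    if not np.allclose(psd.freqs_hz[bin_idx], bin_freqs):
        raise ValueError("PSD grid does not contain the ROI bins")
    blocks, elig = [], []
    theta_bins = bin_freqs <= iaf.iaf_hz - 2.0 + 1e-9   # first 9 bins
    alpha_bins = bin_freqs >= iaf.iaf_hz - 2.0 - 1e-9   # last 9 bins
    for ch in ROI_CHANNELS:
        ci = names.index(ch)
        blocks.append(psd.psd[:, ci, :][:, bin_idx])
        elig.append(theta_bins if ch in FRONTAL_ROI else alpha_bins)
    roi = np.concatenate(blocks, axis=1)
    eligible = np.concatenate(elig)
    assert roi.shape[1] == 187 and int(eligible.sum()) == 99
    return roi, eligible


def roi_column_names(iaf: IAFEstimate) -> list[str]:
    bin_freqs = iaf.iaf_hz - 6.0 + 0.5 * np.arange(17)
    return [f"{ch}@{f:.1f}Hz" for ch in ROI_CHANNELS for f in bin_freqs]


def preprocess(
    eeg: np.ndarray, channel_names=CHANNELS, resting_eeg: np.ndarray | None = None,
    sfreq: int = EEG_SFREQ, iaf: IAFEstimate | None = None,
) -> SpectralFeatureMatrix:
    """Full chain: filter, blink-correct, epoch, reject, PSD, band features.

    The IAF is taken from ``iaf`` if given, otherwise estimated from
    ``resting_eeg`` (closed-eyes recording); one of the two is required.
    """
    filtered = bandpass_filter(eeg, sfreq=sfreq)
    cleaned = remove_blinks(filtered, channel_names, sfreq=sfreq)
    epochs = reject_artifacts(segment_epochs(cleaned, channel_names, sfreq=sfreq))
    psd = compute_psd(epochs)
    if iaf is None:
        if resting_eeg is None:
            raise ValueError("either a resting recording or an IAF estimate is required")
        rest_psd = compute_psd(segment_epochs(
            bandpass_filter(resting_eeg, sfreq=sfreq), channel_names, sfreq=sfreq))
        iaf = estimate_iaf(rest_psd)
    band45 = band_features_45(psd, iaf)
    roi187, eligible = roi_psd_matrix_187(psd, iaf)
    return SpectralFeatureMatrix(
        band45=band45, roi187=roi187, eligible99=eligible, iaf=iaf,
        start_times_s=psd.start_times_s,
    )
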