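"""EEG preprocessing chain.

Order used by the pipeline: band-pass filter (0.5-50 Hz), PCA artifact
removal, bilateral-mastoid re-referencing, channel selection down to the
8-channel montage, fixed-width epoching.  Each step is a pure function
on :class:`~vims_eeg.recording.EEGRecording`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.stats import kurtosis

from vims_eeg.recording import EEGRecording, Epoch, EpochSet, check_channel_subset

__all__ = [
    "DEFAULT_MONTAGE", "bandpass_filter", "select_channels",
    "rereference_mastoids", "pca_artifact_removal", "segment_windows",
    "n_windows", "preprocess_recording",
]

#: The 8-channel scalp montage used for classification.
DEFAULT_MONTAGE = ("FP1", "FP2", "C3", "C4", "P3", "P4", "O1", "O2")


def bandpass_filter(rec: EEGRecording, low_hz: float = 0.5,
                    high_hz: float = 50.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    ``order`` is the one-pass filter order; `sosfiltfilt` squares the
    magnitude response and cancels the phase, so the effective
    attenuation is doubled and time-locked features are preserved.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(out, rec.fs, list(rec.channel_names), rec.start_time_s)


def select_channels(rec: EEGRecording, names) -> EEGRecording:
    """Return exactly the requested channels in the requested order."""
    names = list(names)
    check_channel_subset(names, rec.channel_names)
    idx = [rec.channel_index(n) for n in names]
    return EEGRecording(rec.data[idx].copy(), rec.fs, names, rec.start_time_s)


def rereference_mastoids(rec: EEGRecording, ref_names=("M1", "M2"),
                         fallback: str | None = None) -> EEGRecording:
    """Subtract the mean of the two mastoid channels; drop the mastoids.

    If a mastoid is absent the call fails unless ``fallback='average'``
    is passed explicitly, in which case the common average reference is
    used instead (a silent fallback would change results invisibly).
    """
    missing = [n for n in ref_names if n not in rec.channel_names]
    if missing:
        if fallback == "average":
            ref = rec.data.mean(axis=0)
            return EEGRecording(rec.data - ref, rec.fs,
                                list(rec.channel_names), rec.start_time_s)
        raise KeyError(
            f"mastoid channel(s) {missing} missing; pass fallback='average' "
            "to re-reference to the common average instead")
    ref = np.mean([rec.channel(n) for n in ref_names], axis=0)
    keep = [n for n in rec.channel_names if n not in ref_names]
    idx = [rec.channel_index(n) for n in keep]
    return EEGRecording(rec.data[idx] - ref, rec.fs, keep, rec.start_time_s)


def pca_artifact_removal(rec: EEGRecording, var_threshold: float = 0.35,
                         kurt_threshold: float = 8.0
                         ) -> tuple[EEGRecording, list[int]]:
    """Remove high-variance, high-kurtosis principal components.

    The channel covariance is eigen-decomposed; a component is flagged
    as artifact when its variance share exceeds ``var_threshold`` AND
    the excess kurtosis of its time course exceeds ``kurt_threshold`` —
    targeting large non-Gaussian transients (blinks, cable movement)
    while leaving oscillatory rhythms intact.  Returns the cleaned
    recording and the indices (variance-ordered) of removed components.
    """
    if rec.n_channels < 2:
        raise ValueError("PCA artifact removal needs at least 2 channels")
    x = rec.data
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    total_var = float(np.sum(xc * xc))
    if total_var == 0:
        return rec.copy(), []
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    shares = evals / evals.sum()
    sources = evecs.T @ xc
    removed = [i for i in range(len(evals))
               if shares[i] > var_threshold
               and kurtosis(sources[i]) > kurt_threshold]
    if not removed:
        return EEGRecording(xc + mean, rec.fs, list(rec.channel_names),
                            rec.start_time_s), []
    keep = np.ones(len(evals), dtype=bool)
    keep[removed] = False
    clean = evecs[:, keep] @ sources[keep] + mean
    return EEGRecording(clean, rec.fs, list(rec.channel_names),
                        rec.start_time_s), removed


def n_windows(duration_s: float, window_s: float) -> int:
    """Number of non-overlapping windows; trailing partial discarded."""
    return int(np.floor(duration_s / window_s + 1e-9))


def segment_windows(rec: EEGRecording, window_s: float,
                    subject_id: int = -1, video_id: int = -1,
                    label: int | None = None) -> EpochSet:
    """Cut a recording into contiguous, non-overlapping epochs.

    Windows are half-open intervals [t, t + window_s) from time 0; the
    trailing partial window is discarded.  A window longer than the
    recording yields an empty set with a warning.
    """
    ns = window_s * rec.fs
    if abs(ns - round(ns)) > 1e-6 or ns <= 0:
        raise ValueError(
            f"window_s * fs must be a positive integer, got {window_s} * {rec.fs}")
    ns = int(round(ns))
    count = rec.n_samples // ns
    if count == 0:
        warnings.warn(f"window of {window_s} s longer than recording "
                      f"({rec.duration_s:.1f} s); returning empty epoch set")
    epochs = [Epoch(rec.data[:, k * ns:(k + 1) * ns].copy(), rec.fs,
                    list(rec.channel_names), label=label,
                    origin=(subject_id, video_id,
                            rec.start_time_s + k * window_s))
              for k in range(count)]
    return EpochSet(epochs)


def preprocess_recording(rec: EEGRecording, low_hz: float = 0.5,
                         high_hz: float = 50.0,
                         channels=DEFAULT_MONTAGE,
                         reference: str = "mastoids",
                         var_threshold: float = 0.35,
                         kurt_threshold: float = 8.0) -> EEGRecording:
    """Full chain: band-pass, PCA artifact removal, re-reference, select."""
    rec = bandpass_filter(rec, low_hz, high_hz)
    rec, _ = pca_artifact_removal(rec, var_threshold, kurt_threshold)
    if reference == "mastoids":
        rec = rereference_mastoids(rec)
    elif reference == "average":
        rec = EEGRecording(rec.data - rec.data.mean(axis=0), rec.fs,
                           list(rec.channel_names), rec.start_time_s)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return select_channels(rec, channels)
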