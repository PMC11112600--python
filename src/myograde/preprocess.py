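"""Filtering, windowing, min–max normalization and SNR computation.

The pipeline is: 10–450 Hz zero-phase band-pass on every channel, sliding
windows of 200 samples with step 100, then per-subject per-channel min–max
normalization to [0, 1] with the training bounds stored for reuse on unseen
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording, SegmentSet, ValidationError

__all__ = [
    "bandpass_filter",
    "segment_windows",
    "compute_bounds",
    "normalize",
    "compute_snr",
    "SnrResult",
    "n_windows",
]


def bandpass_filter(rec: Recording, low_hz: float = 10.0, high_hz: float = 450.0,
                    order: int = 4, apply_to_piezo: bool = True) -> Recording:
    """Zero-phase Butterworth band-pass applied to all 4 channels.

    A forward–backward (filtfilt) pass preserves the temporal alignment
    between the sEMG and strain channels.  ``apply_to_piezo=False`` leaves
    the two strain channels untouched.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    out = rec.channels.copy()
    rows = range(4) if apply_to_piezo else (0, 2)
    for i in rows:
        out[i] = sps.sosfiltfilt(sos, rec.channels[i])
    return rec.with_channels(out)


def n_windows(length: int, window: int = 200, step: int = 100) -> int:
    """Number of complete sliding windows: floor((L - window)/step) + 1."""
    if length < window:
        raise ValueError(
            f"signal of length {length} is shorter than the minimum window "
            f"length {window}")
    return (length - window) // step + 1


def segment_windows(rec: Recording, window: int = 200, step: int = 100) -> SegmentSet:
    """Slice a recording into overlapping windows; incomplete tails are dropped."""
    L = rec.n_samples
    n = n_windows(L, window, step)
    data = np.empty((n, 4, window))
    starts = np.arange(n) * step
    for i, s in enumerate(starts):
        data[i] = rec.channels[:, s:s + window]
    labels = None
    if rec.coarse_grade is not None:
        labels = np.full(n, rec.coarse_grade, dtype=np.int64)
    return SegmentSet(
        data=data, labels=labels,
        subject_ids=np.array([rec.subject_id] * n, dtype=object),
        starts=starts)


def compute_bounds(recordings) -> dict[str, np.ndarray]:
    """Per-subject per-channel (min, max) over each subject's full signal.

    Bounds are computed on the (already filtered) signal, matching the order
    of the pipeline: filter first, then normalize.
    """
    bounds: dict[str, np.ndarray] = {}
    for rec in recordings:
        b = np.stack([rec.channels.min(axis=1), rec.channels.max(axis=1)], axis=1)
        if rec.subject_id in bounds:
            prev = bounds[rec.subject_id]
            b = np.stack([np.minimum(prev[:, 0], b[:, 0]),
                          np.maximum(prev[:, 1], b[:, 1])], axis=1)
        bounds[rec.subject_id] = b
    return bounds


def normalize(segs: SegmentSet, bounds: dict[str, np.ndarray] | None = None,
              training: bool = True) -> SegmentSet:
    """Min–max map each channel to [0, 1]: s = (r - min R)/(max R - min R).

    With ``bounds=None`` the per-subject per-channel extrema of the segment
    data itself are used (training mode).  With stored bounds, out-of-range
    values from unseen data are clipped to [0, 1].  A degenerate (constant)
    channel raises in training mode and maps to zeros with a warning in
    inference mode.
    """
    if segs.subject_ids is None:
        raise ValidationError("normalize requires per-segment subject provenance")
    own_bounds = bounds is None
    if own_bounds:
        bounds = {}
        for subj in np.unique(segs.subject_ids.astype(str)):
            mask = segs.subject_ids.astype(str) == subj
            block = segs.data[mask]  # (m, 4, win)
            bounds[subj] = np.stack(
                [block.min(axis=(0, 2)), block.max(axis=(0, 2))], axis=1)
    out = np.empty_like(segs.data)
    for subj in np.unique(segs.subject_ids.astype(str)):
        mask = segs.subject_ids.astype(str) == subj
        if subj not in bounds:
            raise ValidationError(f"no stored normalization bounds for {subj!r}")
        b = bounds[subj]
        lo, hi = b[:, 0], b[:, 1]
        span = hi - lo
        degenerate = span <= 0
        if degenerate.any():
            if training:
                raise ValidationError(
                    f"channel(s) {np.where(degenerate)[0].tolist()} of subject "
                    f"{subj!r} are constant (max == min); cannot normalize "
                    "training data")
            warnings.warn(
                f"constant channel(s) {np.where(degenerate)[0].tolist()} for "
                f"subject {subj!r}: mapping to zeros (detached sensor?)",
                stacklevel=2)
            span = np.where(degenerate, 1.0, span)
        scaled = (segs.data[mask] - lo[None, :, None]) / span[None, :, None]
        if degenerate.any():
            scaled[:, degenerate, :] = 0.0
        out[mask] = scaled
    if not own_bounds:
        out = np.clip(out, 0.0, 1.0)
    return SegmentSet(data=out, labels=segs.labels, subject_ids=segs.subject_ids,
                      starts=segs.starts, bounds=dict(bounds), normalized=True)


@dataclass(frozen=True)
class SnrResult:
    """RMS amplitudes during activity (v_s) and rest (v_n) and their ratio in dB."""

    v_s: float
    v_n: float
    snr_db: float


def compute_snr(signal: np.ndarray, activity_mask: np.ndarray) -> SnrResult:
    """SNR = 20 log10(V_s / V_n) with V_s, V_n the RMS ("effective") voltage
    amplitudes over the active and rest samples respectively."""
    signal = np.asarray(signal, dtype=np.float64)
    mask = np.asarray(activity_mask, dtype=bool)
    if signal.shape != mask.shape:
        raise ValueError("signal and activity_mask must have the same shape")
    if mask.all() or not mask.any():
        raise ValueError("activity_mask must mark at least one active and one "
                         "rest sample")
    v_s = float(np.sqrt(np.mean(signal[mask] ** 2)))
    v_n = float(np.sqrt(np.mean(signal[~mask] ** 2)))
    if v_n == 0.0:
        raise ValueError("rest segment is silent (V_n = 0); SNR undefined")
    return SnrResult(v_s=v_s, v_n=v_n, snr_db=20.0 * np.log10(v_s / v_n))
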