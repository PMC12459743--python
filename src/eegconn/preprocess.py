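"""Deterministic signal conditioning: filtering, referencing, epoching, rejection.

The chain mirrors standard EEG practice for this kind of paradigm: broadband
0.5-40 Hz band-pass (two-pass recursive filter, 48 dB/octave, plus 50 Hz
notch), downsampling to 256 Hz with anti-alias filtering, common average
reference, segmentation into stimulus-locked epochs (-2000..2000 ms),
amplitude-based epoch rejection (> 200 uV peak-to-peak within 200 ms, or a
flatline below 0.5 uV span within 100 ms), and narrowband theta (4-7 Hz) /
alpha (8-12 Hz) extraction with zero-phase Hamming-windowed sinc FIR filters.
Everything here is a pure function of its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .core import ContinuousSignal, EpochedSignal

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0)}


def _apply_along_time(obj, func, new_fs=None):
    """Apply ``func`` on the last axis of a Continuous/EpochedSignal's data."""
    data = func(obj.data)
    fs = new_fs if new_fs is not None else obj.fs_hz
    if isinstance(obj, EpochedSignal):
        return EpochedSignal(
            data=data, fs_hz=fs, t0_ms=obj.t0_ms,
            channel_names=list(obj.channel_names),
            trial_indices=obj.trial_indices.copy(),
        )
    return ContinuousSignal(data=data, fs_hz=fs, channel_names=list(obj.channel_names))


def downsample(signal, target_fs_hz: float):
    """Polyphase resampling to ``target_fs_hz`` (anti-alias filter included)."""
    if target_fs_hz > signal.fs_hz:
        raise ValueError(
            f"target fs {target_fs_hz} Hz above original {signal.fs_hz} Hz; upsampling refused"
        )
    if target_fs_hz == signal.fs_hz:
        return _apply_along_time(signal, lambda d: d.copy())
    frac = Fraction(target_fs_hz / signal.fs_hz).limit_denominator(1000)
    return _apply_along_time(
        signal,
        lambda d: sps.resample_poly(d, frac.numerator, frac.denominator, axis=-1),
        new_fs=signal.fs_hz * frac.numerator / frac.denominator,
    )


def broadband_filter(signal, low_hz: float = 0.5, high_hz: float = 40.0,
                     notch_hz: float | None = 50.0):
    """Two-pass 4th-order band-pass (48 dB/octave) plus optional notch."""
    nyq = signal.fs_hz / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, {nyq}) Hz")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=signal.fs_hz, output="sos")

    def _run(d):
        out = sps.sosfiltfilt(sos, d, axis=-1)
        if notch_hz is not None and notch_hz < nyq:
            b, a = sps.iirnotch(notch_hz, Q=30.0, fs=signal.fs_hz)
            out = sps.filtfilt(b, a, out, axis=-1)
        return out

    return _apply_along_time(signal, _run)


def _fir_taps(low_hz, high_hz, fs_hz, n_samples):
    """Hamming window-method order from a 25%-of-band-edge transition width.

    The tap count is capped so the forward-backward pass stays valid on short
    epochs (pad length must not exceed the signal length).
    """
    trans = 0.25 * low_hz
    ntaps = int(np.ceil(3.3 * fs_hz / trans))
    max_taps = max((n_samples - 1) // 3, 9)
    ntaps = min(ntaps, max_taps)
    if ntaps % 2 == 0:
        ntaps -= 1
    return ntaps


def narrowband_extract(signal, band):
    """Zero-phase band extraction with a Hamming-windowed sinc FIR filter.

    ``band`` is a name from :data:`BANDS` or a (low, high) Hz pair.  The
    filter is linear phase and applied forward-backward, so the output has
    exactly zero phase shift; out-of-band attenuation is doubled by the two
    passes.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    nyq = signal.fs_hz / 2.0
    if lo <= 0 or hi >= nyq:
        raise ValueError(f"band ({lo}, {hi}) overlaps DC or Nyquist ({nyq} Hz)")
    ntaps = _fir_taps(lo, hi, signal.fs_hz, signal.data.shape[-1])
    taps = sps.firwin(ntaps, [lo, hi], pass_zero=False, window="hamming", fs=signal.fs_hz)

    def _run(d):
        padlen = min(3 * ntaps, d.shape[-1] - 1)
        return sps.filtfilt(taps, [1.0], d, axis=-1, padlen=padlen)

    return _apply_along_time(signal, _run)


def common_average_reference(epochs, excluded_channels: list[str] | None = None):
    """Subtract the mean of the retained channels from every channel.

    After referencing the mean over retained channels is zero at every
    sample.  Excluded (noisy) channels still get the reference subtracted but
    do not contribute to it.
    """
    excluded = set(excluded_channels or [])
    keep = [i for i, name in enumerate(epochs.channel_names) if name not in excluded]
    if len(keep) < 2:
        raise ValueError("common average reference needs at least 2 retained channels")
    return _apply_along_time(
        epochs, lambda d: d - d.take(keep, axis=-2).mean(axis=-2, keepdims=True)
    )


def epoch_segments(
    continuous: ContinuousSignal,
    event_samples,
    window_ms: tuple[float, float] = (-2000.0, 2000.0),
    trial_indices=None,
) -> tuple[EpochedSignal, list[int]]:
    """Cut stimulus-locked epochs over the half-open window [start, end).

    Events whose window extends past either edge of the recording are dropped
    and returned in the second element.
    """
    event_samples = np.asarray(event_samples, dtype=int)
    if trial_indices is None:
        trial_indices = np.arange(1, len(event_samples) + 1)
    trial_indices = np.asarray(trial_indices, dtype=int)
    i0 = int(round(window_ms[0] * continuous.fs_hz / 1000.0))
    i1 = int(round(window_ms[1] * continuous.fs_hz / 1000.0))
    n = continuous.n_samples
    segs, kept, dropped = [], [], []
    for ev, ti in zip(event_samples, trial_indices):
        if ev + i0 < 0 or ev + i1 > n:
            dropped.append(int(ti))
            continue
        segs.append(continuous.data[:, ev + i0 : ev + i1])
        kept.append(int(ti))
    if not segs:
        warnings.warn("no event had full window support; returning empty epochs")
        data = np.empty((0, continuous.n_channels, i1 - i0))
    else:
        data = np.stack(segs)
    epochs = EpochedSignal(
        data=data, fs_hz=continuous.fs_hz, t0_ms=window_ms[0],
        channel_names=list(continuous.channel_names),
        trial_indices=np.asarray(kept, dtype=int),
    )
    return epochs, dropped


def _sliding_ptp(data: np.ndarray, win: int) -> np.ndarray:
    """Peak-to-peak over every complete sliding window (step 1 sample)."""
    hi = maximum_filter1d(data, size=win, axis=-1, mode="nearest")
    lo = minimum_filter1d(data, size=win, axis=-1, mode="nearest")
    ptp = hi - lo
    # indices whose centered window lies fully inside the signal
    left = win // 2
    right = data.shape[-1] - (win - 1 - left)
    return ptp[..., left:right]


def reject_epochs(
    epochs: EpochedSignal,
    max_diff_uv: float = 200.0,
    max_diff_window_ms: float = 200.0,
    flat_uv: float = 0.5,
    flat_window_ms: float = 100.0,
) -> tuple[EpochedSignal, np.ndarray, pd.DataFrame]:
    """Amplitude-based trial rejection; returns (kept, keep-mask, report).

    A trial is rejected when any channel shows a sliding-window peak-to-peak
    above ``max_diff_uv`` within ``max_diff_window_ms`` ("max-diff"), or a
    peak-to-peak below ``flat_uv`` within ``flat_window_ms`` ("flatline" —
    the span reading of the minimum-amplitude rule, since a literal signed
    minimum would reject every zero-crossing signal).  The report lists
    trial index, reason, channel and window start in ms.
    """
    w_max = int(round(max_diff_window_ms * epochs.fs_hz / 1000.0))
    w_flat = int(round(flat_window_ms * epochs.fs_hz / 1000.0))
    if max(w_max, w_flat) > epochs.n_samples:
        raise ValueError("rejection window longer than epoch")

    ptp_max = _sliding_ptp(epochs.data, w_max)
    ptp_flat = _sliding_ptp(epochs.data, w_flat)
    mask = np.ones(epochs.n_trials, dtype=bool)
    rows = []
    for t in range(epochs.n_trials):
        viol_max = np.argwhere(ptp_max[t] > max_diff_uv)
        viol_flat = np.argwhere(ptp_flat[t] < flat_uv)
        if viol_max.size:
            ch, pos = viol_max[0]
            reason, win = "max-diff", w_max
        elif viol_flat.size:
            ch, pos = viol_flat[0]
            reason, win = "flatline", w_flat
        else:
            continue
        mask[t] = False
        rows.append(
            {
                "trial": int(epochs.trial_indices[t]),
                "reason": reason,
                "channel": epochs.channel_names[int(ch)],
                "window_start_ms": float(epochs.t0_ms + pos * 1000.0 / epochs.fs_hz),
            }
        )
    kept = EpochedSignal(
        data=epochs.data[mask].copy(),
        fs_hz=epochs.fs_hz,
        t0_ms=epochs.t0_ms,
        channel_names=list(epochs.channel_names),
        trial_indices=epochs.trial_indices[mask].copy(),
    )
    report = pd.DataFrame(rows, columns=["trial", "reason", "channel", "window_start_ms"])
    return kept, mask, report
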