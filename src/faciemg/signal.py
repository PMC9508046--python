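"""Envelope amplitude extraction from raw sEMG traces.

Processing chain per trace: full-wave rectification -> 100 ms running-average
smoothing -> selection of the 500 ms epoch with the largest mean envelope ->
95th percentile of the smoothed rectified samples inside that epoch. The
result is one scalar amplitude (uV) per channel x pose x repetition.

The epoch may instead be supplied externally (the manually-selected path);
the automatic selection reproduces the "window containing the maximum
amplitudes" criterion by exhaustive search over all start offsets.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import EMGTrace, MeasurementSession

__all__ = [
    "rectify",
    "smooth_running_average",
    "select_epoch",
    "amplitude_95",
    "process_trace",
    "process_session",
    "AMPLITUDE_COLUMNS",
]

AMPLITUDE_COLUMNS = (
    "measurement_id",
    "muscle",
    "side",
    "pose",
    "repetition",
    "amplitude_uv",
    "epoch_start_s",
)


def _window_samples(window_ms: float, fs: float) -> int:
    if window_ms <= 0:
        raise ValueError("window_ms must be strictly positive")
    return max(1, int(round(window_ms * fs / 1000.0)))


def rectify(trace: EMGTrace) -> EMGTrace:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return trace.replace(samples=np.abs(trace.samples))


def smooth_running_average(trace: EMGTrace, window_ms: float = 100.0) -> EMGTrace:
    """Centered running average with truncated windows at the edges.

    Edge samples are averaged over the window samples that actually exist
    (no zero padding), so a constant trace maps to itself.
    """
    w = _window_samples(window_ms, trace.sampling_rate_hz)
    n = len(trace.samples)
    if w > n:
        raise ValueError(f"smoothing window ({w} samples) longer than trace ({n} samples)")
    kernel = np.ones(w)
    sums = np.convolve(trace.samples, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return trace.replace(samples=sums / counts)


def select_epoch(trace: EMGTrace, epoch_ms: float = 500.0) -> int:
    """Start offset (samples) of the epoch maximizing the window mean.

    Expects a rectified, smoothed trace. All valid start offsets are scanned;
    ties are broken toward the earliest start.
    """
    w = _window_samples(epoch_ms, trace.sampling_rate_hz)
    n = len(trace.samples)
    if w > n:
        raise ValueError(f"epoch ({w} samples) longer than trace ({n} samples)")
    means = sliding_window_view(trace.samples, w).mean(axis=1)
    return int(np.argmax(means))


def amplitude_95(samples: Iterable[float]) -> float:
    """95th percentile (linear interpolation) of a nonnegative sample series."""
    x = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, dtype=float)
    if x.size == 0:
        raise ValueError("amplitude_95 requires a nonempty sample series")
    if np.any(x < 0):
        raise ValueError("amplitude_95 expects rectified (nonnegative) samples")
    return float(np.percentile(x, 95))


def process_trace(
    trace: EMGTrace,
    *,
    window_ms: float = 100.0,
    epoch_ms: float = 500.0,
    manual_epoch_start_s: float | None = None,
) -> tuple[float, float]:
    """Full chain on one trace; returns (amplitude_uv, epoch_start_s)."""
    fs = trace.sampling_rate_hz
    env = smooth_running_average(rectify(trace), window_ms)
    w = _window_samples(epoch_ms, fs)
    if manual_epoch_start_s is None:
        start = select_epoch(env, epoch_ms)
    else:
        start = int(round(manual_epoch_start_s * fs))
        if start < 0 or start + w > len(env.samples):
            raise ValueError(
                f"manual epoch offset {manual_epoch_start_s} s out of range for trace "
                f"{trace.measurement_id}/{trace.muscle}/{trace.side}/{trace.pose}"
                f"/rep{trace.repetition}"
            )
    amp = amplitude_95(env.samples[start : start + w])
    return amp, start / fs


def process_session(
    session: MeasurementSession,
    manual_epochs: Mapping[tuple[str, str, str, int], float] | None = None,
    *,
    window_ms: float = 100.0,
    epoch_ms: float = 500.0,
) -> pd.DataFrame:
    """One amplitude record per trace of a session.

    ``manual_epochs`` maps (muscle, side, pose, repetition) to an epoch start
    offset in seconds for traces whose epoch was selected by hand; all other
    traces use automatic selection. Missing traces simply yield no record.
    """
    manual_epochs = manual_epochs or {}
    rows = []
    for tr in session.traces:
        key = (tr.muscle, tr.side, tr.pose, tr.repetition)
        amp, start_s = process_trace(
            tr,
            window_ms=window_ms,
            epoch_ms=epoch_ms,
            manual_epoch_start_s=manual_epochs.get(key),
        )
        rows.append(
            {
                "measurement_id": tr.measurement_id,
                "muscle": tr.muscle,
                "side": tr.side,
                "pose": tr.pose,
                "repetition": tr.repetition,
                "amplitude_uv": amp,
                "epoch_start_s": start_s,
            }
        )
    return pd.DataFrame(rows, columns=list(AMPLITUDE_COLUMNS))


def process_cohort(sessions: Iterable[MeasurementSession], **kwargs) -> pd.DataFrame:
    """Concatenated amplitude records for a list of sessions."""
    frames = [process_session(s, **kwargs) for s in sessions]
    if not frames:
        return pd.DataFrame(columns=list(AMPLITUDE_COLUMNS))
    return pd.concat(frames, ignore_index=True)
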