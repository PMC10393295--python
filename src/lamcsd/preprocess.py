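"""LFP preprocessing: filtering, channel selection, trial averaging and
interpolation onto the common analysis grid."""

from __future__ import annotations

import numpy as np
import scipy.signal
from scipy.interpolate import RegularGridInterpolator

from .core import GridPattern, InvalidArgumentError, LaminarRecording

#: Common analysis grid (depth x time) used for pattern comparison.
GRID_M = 30
GRID_K = 100
ANALYSIS_WINDOW_MS = (0.0, 100.0)
BASELINE_WINDOW_MS = (-250.0, 0.0)


def lowpass_filter(
    rec: LaminarRecording, cutoff: float = 500.0, order: int = 5
) -> LaminarRecording:
    """Zero-phase low-pass Butterworth filter applied per channel.

    Forward-backward filtering doubles the effective order and squares the
    magnitude response (amplitude 0.5 at the cutoff).  Edges are padded with
    odd reflection over 3x the filter order.
    """
    if cutoff >= rec.fs / 2:
        raise InvalidArgumentError(
            f"cutoff {cutoff} Hz is not below Nyquist ({rec.fs / 2} Hz)"
        )
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.lfp, axis=1, padtype="odd", padlen=3 * order)
    return rec.with_lfp(filtered)


def select_channels(rec: LaminarRecording, target_pitch: float = 40.0) -> LaminarRecording:
    """Spatially downsample to ``target_pitch`` µm, keeping the deepest channel.

    The native pitch must divide the target pitch (e.g. 20 µm -> 40 µm keeps
    every other electrode).
    """
    if rec.n_channels < 2:
        return rec
    pitches = np.diff(rec.depths)
    native = float(np.abs(pitches[0]))
    if not np.allclose(np.abs(pitches), native):
        raise InvalidArgumentError("channel pitch is not uniform")
    step_f = target_pitch / native
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise InvalidArgumentError(
            f"native pitch {native} µm does not divide target pitch {target_pitch} µm"
        )
    if step == 1:
        return rec
    # start from the deepest channel and walk up
    deepest_last = rec.depths[-1] > rec.depths[0]
    idx = (
        np.arange(rec.n_channels - 1, -1, -step)[::-1]
        if deepest_last
        else np.arange(0, rec.n_channels, step)
    )
    return LaminarRecording(
        lfp=rec.lfp[idx],
        depths=rec.depths[idx],
        fs=rec.fs,
        trial_onsets=rec.trial_onsets,
        area=rec.area,
    )


def trial_average(
    rec: LaminarRecording, window_ms: tuple[float, float] = (-250.0, 250.0)
) -> GridPattern:
    """Mean across trials, time re-referenced to stimulus onset (ms)."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise InvalidArgumentError("window must satisfy t0 < t1")
    i0 = int(round(t0 / 1e3 * rec.fs))
    n_win = int(round((t1 - t0) / 1e3 * rec.fs))
    n_samples = rec.lfp.shape[1]
    bad = []
    segs = []
    for trial, onset in enumerate(rec.trial_onsets):
        s = int(round(onset * rec.fs)) + i0
        if s < 0 or s + n_win > n_samples:
            bad.append(trial)
            continue
        segs.append(rec.lfp[:, s : s + n_win])
    if bad:
        raise InvalidArgumentError(f"window exceeds recording bounds for trials {bad}")
    avg = np.mean(segs, axis=0)
    time_axis = (i0 + np.arange(n_win)) / rec.fs * 1e3
    return GridPattern(values=avg, depth_axis=rec.depths, time_axis=time_axis, units="uV")


def baseline_subtract(
    pattern: GridPattern, baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> GridPattern:
    """Subtract each channel's mean over the (pre-stimulus) baseline window."""
    t0, t1 = baseline_window_ms
    mask = (pattern.time_axis >= t0) & (pattern.time_axis < t1)
    if not mask.any():
        raise InvalidArgumentError(
            f"baseline window [{t0}, {t1}) ms contains no samples"
        )
    baseline = pattern.values[:, mask].mean(axis=1, keepdims=True)
    return GridPattern(
        values=pattern.values - baseline,
        depth_axis=pattern.depth_axis.copy(),
        time_axis=pattern.time_axis.copy(),
        units=pattern.units,
    )


def crop_window(pattern: GridPattern, window_ms: tuple[float, float]) -> GridPattern:
    """Restrict a pattern to a time window (inclusive bounds)."""
    t0, t1 = window_ms
    mask = (pattern.time_axis >= t0) & (pattern.time_axis <= t1)
    if mask.sum() < 2:
        raise InvalidArgumentError("window leaves fewer than two time samples")
    return GridPattern(
        values=pattern.values[:, mask],
        depth_axis=pattern.depth_axis.copy(),
        time_axis=pattern.time_axis[mask],
        units=pattern.units,
    )


def interpolate_grid(pattern: GridPattern, M: int = GRID_M, K: int = GRID_K) -> GridPattern:
    """Bilinear interpolation onto an M x K uniform grid spanning the input axes."""
    if M < 2 or K < 2:
        raise InvalidArgumentError("M and K must both be >= 2")
    if pattern.values.shape[0] < 2 or pattern.values.shape[1] < 2:
        raise InvalidArgumentError("input pattern must be at least 2 x 2")
    dax = pattern.depth_axis
    tax = pattern.time_axis
    flip_d = dax[0] > dax[-1]
    flip_t = tax[0] > tax[-1]
    vals = pattern.values
    if flip_d:
        dax, vals = dax[::-1], vals[::-1]
    if flip_t:
        tax, vals = tax[::-1], vals[:, ::-1]
    interp = RegularGridInterpolator((dax, tax), vals, method="linear")
    new_d = np.linspace(dax[0], dax[-1], M)
    new_t = np.linspace(tax[0], tax[-1], K)
    DD, TT = np.meshgrid(new_d, new_t, indexing="ij")
    out = interp(np.stack([DD.ravel(), TT.ravel()], axis=1)).reshape(M, K)
    return GridPattern(values=out, depth_axis=new_d, time_axis=new_t, units=pattern.units)
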