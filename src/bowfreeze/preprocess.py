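"""Zero-phase low-pass filtering and rate harmonisation.

Marker trajectories are smoothed with a bidirectional (zero-phase) 5th-order
Butterworth filter, cut-off 20 Hz, and captures acquired at 120 Hz are then
decimated to the common 60 Hz analysis rate.  Filtering runs independently on
each contiguous block of non-missing samples; blocks too short for the filter
warm-up are passed through untouched and logged.  The missing mask is never
altered and gaps are never interpolated.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .io import TrialRecording

log = logging.getLogger(__name__)


def _contiguous_blocks(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a 1-D boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], valid, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def lowpass_filter(
    trial: TrialRecording, cutoff_hz: float = 20.0, order: int = 5
) -> TrialRecording:
    """Bidirectional Butterworth low-pass on every coordinate channel.

    Forward-backward application squares the magnitude response and cancels
    phase, so band-limited content is delayed by zero samples.  Each
    contiguous valid block of each marker is filtered separately; blocks
    shorter than the filtfilt warm-up (3x the filter's tap count) are left
    as-is.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not below the Nyquist frequency.
    """
    nyquist = trial.rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trial.rate_hz, output="sos")
    # filtfilt pad length for sos filters: 3 * (2 * n_sections + 1)
    min_len = 3 * (2 * sos.shape[0] + 1) + 1
    out = trial.copy()
    skipped = 0
    for j in range(out.positions.shape[1]):
        valid = ~out.missing[:, j]
        for start, stop in _contiguous_blocks(valid):
            if stop - start < min_len:
                skipped += 1
                continue
            out.positions[start:stop, j, :] = signal.sosfiltfilt(
                sos, out.positions[start:stop, j, :], axis=0
            )
    if skipped:
        log.warning("lowpass_filter: %d short blocks left unfiltered", skipped)
    log.info("lowpass_filter: cutoff=%g Hz order=%d rate=%g Hz", cutoff_hz, order, trial.rate_hz)
    return out


def decimate_to(trial: TrialRecording, target_hz: float = 60.0) -> TrialRecording:
    """Downsample by sample picking to ``target_hz``.

    The rate must be an integer multiple of the target.  No additional
    anti-alias filter is applied here: the 20 Hz low-pass that precedes
    decimation in the standard pipeline already bounds content below the
    30 Hz post-decimation Nyquist.
    """
    ratio = trial.rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"rate {trial.rate_hz} Hz is not an integer multiple of {target_hz} Hz"
        )
    step = int(round(ratio))
    if step == 1:
        return trial.copy()
    out = trial.copy()
    out.positions = out.positions[::step]
    out.missing = out.missing[::step]
    out.rate_hz = float(target_hz)
    log.info("decimate_to: %g -> %g Hz (kept every %d-th sample)", trial.rate_hz, target_hz, step)
    return out


def preprocess(
    trial: TrialRecording,
    cutoff_hz: float = 20.0,
    order: int = 5,
    target_hz: float = 60.0,
) -> TrialRecording:
    """Standard preprocessing: low-pass filter, then decimate to 60 Hz."""
    return decimate_to(lowpass_filter(trial, cutoff_hz, order), target_hz)
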