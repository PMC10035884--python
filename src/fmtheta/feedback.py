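"""Online closed-loop feedback computation.

Theta power is estimated over sliding 1-s windows (2048 samples at
2048 Hz) hopping by 256 samples (875-ms overlap), i.e. 8 estimates per
second with 1 s of history. Each window's Hann-tapered periodogram is
averaged over the 4-7 Hz bins and expressed in dB relative to an
adaptive threshold: the pre-training resting theta power in session 1,
the mean of the previous session's block powers afterwards. Windows
containing a sample beyond +/-75 uV are gated — the display holds the
last artifact-free level until the artifact subsides.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import (
    EEGRecord,
    FeedbackConfig,
    FeedbackFrame,
    Goal,
    ThresholdSource,
    ThresholdState,
)

__all__ = [
    "DB_FLOOR",
    "stream_theta_power",
    "artifact_gate",
    "to_db",
    "block_achievement",
    "update_threshold",
    "run_feedback",
]

DB_FLOOR = -60.0


def _window_band_power(
    windows: np.ndarray, fs: float, band_lo: float, band_hi: float
) -> np.ndarray:
    """Band-mean Hann periodogram PSD per window (rows), matching the
    scaling of scipy's density periodogram without detrending."""
    from scipy.signal import get_window

    nper = windows.shape[1]
    taper = get_window("hann", nper)  # periodic Hann, as in spectral analysis
    scale = 1.0 / (fs * (taper**2).sum())
    spec = np.fft.rfft(windows * taper, axis=1)
    psd = (spec.real**2 + spec.imag**2) * scale
    psd[:, 1:] *= 2.0
    if nper % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    in_band = (freqs >= band_lo) & (freqs <= band_hi)
    return psd[:, in_band].mean(axis=1)


def stream_theta_power(record: EEGRecord, cfg: FeedbackConfig | None = None) -> list[FeedbackFrame]:
    """Sliding-window theta power stream: one frame per hop, frame rate
    fs / (window - overlap). Returns frames with power only (db is filled
    by :func:`to_db`)."""
    cfg = cfg or FeedbackConfig()
    if record.fs != cfg.fs:
        raise ValueError(f"record fs {record.fs} != config fs {cfg.fs}")
    x = record.segment.samples
    if x.shape[0] < cfg.window_samples:
        warnings.warn("record shorter than one window: empty frame stream", stacklevel=2)
        return []
    windows = sliding_window_view(x, cfg.window_samples)[:: cfg.hop_samples]
    powers = _window_band_power(windows, cfg.fs, cfg.band_lo, cfg.band_hi)
    hop = cfg.hop_samples
    win = cfg.window_samples
    return [
        FeedbackFrame(t_s=(i * hop + win) / cfg.fs, theta_power=float(p))
        for i, p in enumerate(powers)
    ]


def to_db(power: float, threshold: ThresholdState, floor_db: float = DB_FLOOR) -> float:
    """10*log10(power / threshold); zero/tiny power clamps at the floor."""
    if threshold.value <= 0:
        raise ValueError("threshold must be positive")
    if power <= threshold.value * 10 ** (floor_db / 10):
        return floor_db
    return float(10.0 * np.log10(power / threshold.value))


def artifact_gate(
    frames: list[FeedbackFrame],
    record: EEGRecord,
    cfg: FeedbackConfig | None = None,
    threshold: Optional[ThresholdState] = None,
) -> list[FeedbackFrame]:
    """Hold-last gating: a frame is gated iff any sample in its window
    exceeds +/- artifact_limit_uV; gated frames carry the last non-gated
    power/db. If the stream starts gated, held frames show the threshold
    level (0 dB) — a neutral start-of-stream convention.
    Frame count is conserved and non-gated frames are unchanged.
    """
    cfg = cfg or FeedbackConfig()
    x = np.abs(record.segment.samples)
    out: list[FeedbackFrame] = []
    hold_power = threshold.value if threshold is not None else float("nan")
    hold_db = 0.0
    seen_clean = False
    hop, win = cfg.hop_samples, cfg.window_samples
    # cumulative count of super-threshold samples for O(1) window queries
    bad = np.concatenate([[0], np.cumsum(x > cfg.artifact_limit_uV)])
    for i, f in enumerate(frames):
        lo = i * hop
        hi = lo + win
        gated = bad[hi] > bad[lo]
        if gated:
            if not seen_clean and threshold is None:
                hold_power = f.theta_power  # no threshold known: hold live power, 0 dB
            out.append(
                FeedbackFrame(t_s=f.t_s, theta_power=hold_power, db=hold_db,
                              gated=True, achieved=f.achieved)
            )
        else:
            seen_clean = True
            hold_power, hold_db = f.theta_power, f.db
            out.append(
                FeedbackFrame(t_s=f.t_s, theta_power=f.theta_power, db=f.db,
                              gated=False, achieved=f.achieved)
            )
    return out


def block_achievement(frames: Sequence[FeedbackFrame], goal: Goal) -> float:
    """Percentage of non-gated frames on the goal-consistent side of the
    threshold (Up: db > 0, Down: db < 0). Frames exactly at 0 dB count
    as not achieved for either goal."""
    goal = Goal(goal)
    live = [f for f in frames if not f.gated]
    if not live:
        raise ValueError("all frames gated: achievement undefined")
    if goal is Goal.UP:
        n_ok = sum(1 for f in live if f.db > 0)
    else:
        n_ok = sum(1 for f in live if f.db < 0)
    return 100.0 * n_ok / len(live)


def update_threshold(
    session_index: int,
    resting_theta: Optional[float] = None,
    previous_session_block_means: Optional[Sequence[float]] = None,
) -> ThresholdState:
    """Session 1: pre-training resting theta power; later sessions: the
    arithmetic mean of the previous session's six block mean powers."""
    if session_index < 1:
        raise ValueError("session_index is 1-based")
    if session_index == 1:
        if resting_theta is None:
            raise ValueError("session 1 requires resting_theta")
        return ThresholdState(
            value=float(resting_theta),
            session_index=1,
            source=ThresholdSource.RESTING_BASELINE,
        )
    if not previous_session_block_means:
        raise ValueError("sessions > 1 require previous_session_block_means")
    return ThresholdState(
        value=float(np.mean(previous_session_block_means)),
        session_index=session_index,
        source=ThresholdSource.PREVIOUS_SESSION_MEAN,
    )


def run_feedback(
    record: EEGRecord,
    threshold: ThresholdState,
    goal: Goal,
    cfg: FeedbackConfig | None = None,
) -> list[FeedbackFrame]:
    """Full online chain: stream power, convert to dB against the
    threshold, gate on artifacts, mark goal achievement per frame."""
    cfg = cfg or FeedbackConfig()
    frames = stream_theta_power(record, cfg)
    for f in frames:
        f.db = to_db(f.theta_power, threshold)
    frames = artifact_gate(frames, record, cfg, threshold=threshold)
    goal = Goal(goal)
    for f in frames:
        if not f.gated:
            f.achieved = f.db > 0 if goal is Goal.UP else f.db < 0
    return frames
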