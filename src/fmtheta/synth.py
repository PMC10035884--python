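"""Synthetic virtual subjects: EEG with goal-responsive theta, artifact
transients, and a virtual Go-NoGo shooter.

The EEG model is additive: a 1/f^a background, a narrowband (4-7 Hz)
theta component whose band power tracks the subject's modulation goal
and session/block trends, a 10-Hz alpha tone, and raised-cosine artifact
pulses large enough to trip the +/-75 uV online gate. Theta gains act
multiplicatively on band power; session/block trends act in dB, so the
downstream dB-scale analysis sees linear trends by construction.

The shooter fires at an enemy target if a lognormal latency draw falls
within the target exposure time (TET); the overall hit rate follows a
two-point logistic psychometric pinned through (tet50, 0.5) and
(tet90, 0.9). Friendly targets draw a commission error with fixed
probability.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._seeds import child_rng, child_seed
from .offline import welch_band_power
from .protocol import NFSession
from .types import (
    BehavioralTrial,
    EEGRecord,
    Goal,
    Identity,
    OutcomeKind,
    SignalSegment,
    SubjectParams,
    TargetSchedule,
)

__all__ = [
    "generate_background",
    "add_band_oscillation",
    "band_limited_noise",
    "inject_artifacts",
    "simulate_nf_session",
    "simulate_shooter",
    "psychometric_slope",
    "psychometric_hit_rate",
    "simulate_cohort_outcomes",
]


def generate_background(
    duration_s: float,
    fs: float,
    spectral_exponent: float = 1.0,
    scale: float = 2.0,
    seed: int = 0,
) -> SignalSegment:
    """Zero-mean 1/f^a background noise with RMS amplitude `scale` (uV).

    White Gaussian noise is shaped in the frequency domain by
    f^(-a/2) (power follows 1/f^a), giving a fixed spectral slope that a
    log-log periodogram regression recovers.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if not 0 <= spectral_exponent <= 3:
        raise ValueError("spectral_exponent must lie in [0, 3]")
    n = int(round(duration_s * fs))
    rng = child_rng(seed, "background")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spectral_exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    rms = np.sqrt((x**2).mean())
    if rms > 0 and scale > 0:
        x *= scale / rms
    elif scale == 0:
        x = np.zeros(n)
    return SignalSegment(samples=x, fs=fs)


def add_band_oscillation(
    segment: SignalSegment,
    f_hz: float,
    amplitude: float,
    envelope: float | np.ndarray = 1.0,
    phase: float = 0.0,
) -> SignalSegment:
    """Return input + amplitude * envelope * sin(2 pi f t + phase).

    The input segment is unchanged; a pure sinusoid of amplitude a has
    band-integrated power a^2/2, the closed form used in tests.
    """
    if not 0 < f_hz < segment.fs / 2:
        raise ValueError(f"f_hz must lie in (0, Nyquist={segment.fs / 2})")
    n = segment.n_samples
    env = np.asarray(envelope, dtype=float)
    if env.ndim == 0:
        env = np.full(n, float(env))
    elif env.shape[0] != n:
        raise ValueError("envelope length must equal segment length")
    t = np.arange(n) / segment.fs
    return SignalSegment(
        samples=segment.samples + amplitude * env * np.sin(2 * np.pi * f_hz * t + phase),
        fs=segment.fs,
    )


def band_limited_noise(
    duration_s: float,
    fs: float,
    band: tuple[float, float] = (4.0, 7.0),
    seed: int = 0,
) -> SignalSegment:
    """Narrowband Gaussian noise confined to `band`, normalized so its
    measured band-mean Welch PSD equals 1 uV^2/Hz (multiply by
    sqrt(target) to set an exact band power)."""
    n = int(round(duration_s * fs))
    rng = child_rng(seed, "band-noise")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    x = np.fft.irfft(spec * mask, n=n)
    measured = welch_band_power(x, fs, band=band, statistic="mean").power
    if measured > 0:
        x /= np.sqrt(measured)
    return SignalSegment(samples=x, fs=fs)


def _raised_cosine_pulse(n: int) -> np.ndarray:
    """Unit-peak raised-cosine (Hann-shaped) pulse, band-limited with a
    deterministic maximum at the centre sample."""
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def inject_artifacts(
    segment: SignalSegment,
    onsets_s: Sequence[float],
    peak_uV: float = 150.0,
    dur_s: float = 0.25,
    seed: int = 0,
) -> tuple[SignalSegment, list[tuple[int, int]]]:
    """Add raised-cosine artifact pulses; returns the new segment and the
    injected (start, stop) sample intervals in ascending order.
    Overlapping requested intervals are merged with a warning. Alternating
    pulse polarity is drawn from the seed."""
    if peak_uV <= 75.0:
        raise ValueError("peak_uV must exceed the 75 uV online gate to be detectable")
    fs = segment.fs
    n = segment.n_samples
    dur = int(round(dur_s * fs))
    raw = sorted(int(round(o * fs)) for o in onsets_s)
    intervals: list[tuple[int, int]] = []
    for start in raw:
        stop = start + dur
        if start < 0 or stop > n:
            raise ValueError("artifact interval outside segment")
        if intervals and start < intervals[-1][1]:
            warnings.warn("overlapping artifact intervals merged", stacklevel=2)
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], stop))
        else:
            intervals.append((start, stop))
    x = segment.samples.copy()
    rng = child_rng(seed, "artifacts")
    for start, stop in intervals:
        pulse = _raised_cosine_pulse(stop - start) * peak_uV
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x[start:stop] += sign * pulse
    return SignalSegment(samples=x, fs=fs), intervals


def simulate_resting_state(
    params: SubjectParams,
    duration_s: float = 60.0,
    fs: float = 2048.0,
    seed: int = 0,
    background_rms_uV: float = 2.0,
) -> EEGRecord:
    """Artifact-free eyes-open rest: 1/f background plus theta at the
    subject's baseline band power and the alpha tone. Used to define the
    session-1 modulation threshold."""
    background = generate_background(
        duration_s, fs, spectral_exponent=1.0, scale=background_rms_uV,
        seed=child_seed(seed, "rest-bg", params.subject_id),
    )
    carrier = band_limited_noise(
        duration_s, fs, band=(4.0, 7.0),
        seed=child_seed(seed, "rest-theta", params.subject_id),
    ).samples
    x = background.samples + np.sqrt(params.baseline_theta_power) * carrier
    if params.alpha_power > 0:
        rng = child_rng(seed, "rest-alpha", params.subject_id)
        x = add_band_oscillation(
            SignalSegment(x, fs), 10.0, np.sqrt(2 * params.alpha_power),
            phase=rng.uniform(0, 2 * np.pi),
        ).samples
    return EEGRecord(segment=SignalSegment(x, fs), events=[], channel_label="FCz")


def _theta_target_power(params: SubjectParams, goal: Goal, session: int, block: int) -> float:
    trend_db = params.session_trend * (session - 1) + params.block_trend * (block - 1)
    return params.baseline_theta_power * params.goal_gain(goal) * 10 ** (trend_db / 10)


def simulate_nf_session(
    params: SubjectParams,
    session: NFSession,
    seed: int = 0,
    fs: float = 2048.0,
    background_rms_uV: float = 2.0,
    theta_mode: str = "narrowband",
) -> EEGRecord:
    """Synthesize one neurofeedback training session as a continuous
    FCz-like record with rest/modulation events.

    Theta band power is baseline during the 10-s rests and
    baseline * goal_gain * 10^((session_trend*(s-1) + block_trend*(b-1))/10)
    during each 30-s modulation interval. theta_mode='narrowband' uses
    4-7 Hz filtered noise (realistic spectra); 'tone' uses a 6-Hz
    sinusoid whose band power admits a closed form. Artifact pulses
    arrive as a Poisson process at params.artifact_rate per minute.
    Events: 'rest' and 'mod/Up' / 'mod/Down' at interval starts.
    """
    dur_s = session.duration_s
    n = int(round(dur_s * fs))
    s = session.session_index

    background = generate_background(
        dur_s, fs, spectral_exponent=1.0, scale=background_rms_uV,
        seed=child_seed(seed, "bg", params.subject_id, s),
    )

    # per-sample amplitude envelope carrying the goal/trend power profile
    amp_env = np.full(n, np.sqrt(params.baseline_theta_power))
    events: list[tuple[int, int, str]] = []
    for iv in session.intervals():
        lo = int(round(iv.start_s * fs))
        hi = int(round(iv.end_s * fs))
        if iv.kind == "modulation":
            target = _theta_target_power(params, iv.goal, s, iv.block_index)
            amp_env[lo:hi] = np.sqrt(target)
            code = f"mod/{iv.goal.value}"
        else:
            code = "rest"
        events.append((lo, hi - lo, code))

    if theta_mode == "narrowband":
        carrier = band_limited_noise(
            dur_s, fs, band=(4.0, 7.0), seed=child_seed(seed, "theta", params.subject_id, s)
        ).samples
    elif theta_mode == "tone":
        rng = child_rng(seed, "theta-phase", params.subject_id, s)
        t = np.arange(n) / fs
        # 6-Hz tone with band-mean PSD 1 over the 4-bin 4-7 Hz band (1-s windows)
        carrier = np.sqrt(2.0 * 4.0) * np.sin(2 * np.pi * 6.0 * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    x = background.samples + amp_env * carrier

    if params.alpha_power > 0:
        rng = child_rng(seed, "alpha-phase", params.subject_id, s)
        seg = add_band_oscillation(
            SignalSegment(x, fs), 10.0, np.sqrt(2 * params.alpha_power),
            phase=rng.uniform(0, 2 * np.pi),
        )
        x = seg.samples

    segment = SignalSegment(x, fs)
    if params.artifact_rate > 0:
        rng = child_rng(seed, "artifact-times", params.subject_id, s)
        n_art = rng.poisson(params.artifact_rate * dur_s / 60.0)
        if n_art > 0:
            onsets = np.sort(rng.uniform(0, dur_s - 0.3, size=n_art))
            # drop onsets closer than the pulse width to avoid merge warnings
            keep = np.concatenate([[True], np.diff(onsets) > 0.3])
            segment, _ = inject_artifacts(
                segment, onsets[keep], peak_uV=150.0, dur_s=0.25,
                seed=child_seed(seed, "artifact-shape", params.subject_id, s),
            )
    return EEGRecord(segment=segment, events=events, channel_label="FCz")


def psychometric_slope(tet50_ms: float, tet90_ms: float) -> float:
    """Logistic slope (1/ms) through (tet50, 0.5) and (tet90, 0.9)."""
    return float(np.log(9.0) / (tet90_ms - tet50_ms))


def psychometric_hit_rate(tet_ms: np.ndarray | float, tet50_ms: float, tet90_ms: float) -> np.ndarray:
    """Hit probability at exposure time tet under the subject's logistic
    psychometric function."""
    k = psychometric_slope(tet50_ms, tet90_ms)
    return sps.logistic.cdf(np.asarray(tet_ms, dtype=float), loc=tet50_ms, scale=1.0 / k)


def simulate_shooter(
    params: SubjectParams, schedule: TargetSchedule, seed: int = 0
) -> list[BehavioralTrial]:
    """Simulate Go-NoGo responses to a target schedule.

    Enemy targets: shot latency L ~ lognormal(median rt_median_ms,
    log-SD rt_spread); a shot fires iff L <= TET (else omission). The
    fired shot hits with conditional probability p(TET)/P(L <= TET)
    (clipped at 1), so the overall hit rate equals the logistic
    psychometric through (tet50, 0.5) and (tet90, 0.9). Friendly
    targets: a commission error fires with probability commission_prob,
    with latency drawn conditional on landing within the exposure.
    """
    rng = child_rng(seed, "shooter", params.subject_id)
    sigma = params.rt_spread
    med = params.rt_median_ms
    events = schedule.events
    # vectorized per-unique-TET probabilities (scipy calls are costly per trial)
    tets = np.unique([ev.tet_ms for ev in events])
    p_hit_of = dict(zip(tets, psychometric_hit_rate(tets, params.tet50_ms, params.tet90_ms)))
    p_fire_of = dict(zip(tets, sps.lognorm.cdf(tets, s=sigma, scale=med)))
    trials: list[BehavioralTrial] = []
    for ev in events:
        if ev.identity is Identity.ENEMY:
            latency = float(med * np.exp(sigma * rng.standard_normal()))
            if latency > ev.tet_ms:
                trials.append(
                    BehavioralTrial(target=ev, shot_times_ms=[], hit=False,
                                    outcome=OutcomeKind.OMISSION, rt_ms=None)
                )
                continue
            p_hit = float(p_hit_of[ev.tet_ms])
            p_fire = float(p_fire_of[ev.tet_ms])
            q = min(1.0, p_hit / p_fire) if p_fire > 0 else 0.0
            hit = bool(rng.random() < q)
            trials.append(
                BehavioralTrial(
                    target=ev, shot_times_ms=[latency], hit=hit,
                    outcome=OutcomeKind.HIT if hit else OutcomeKind.MISS, rt_ms=latency,
                )
            )
        else:
            if rng.random() < params.commission_prob:
                p_fire = float(p_fire_of[ev.tet_ms])
                if p_fire > 0:
                    latency = float(sps.lognorm.ppf(rng.random() * p_fire, s=sigma, scale=med))
                else:
                    latency = 0.9 * ev.tet_ms
                p_hit = float(p_hit_of[ev.tet_ms])
                hit = bool(rng.random() < p_hit)
                trials.append(
                    BehavioralTrial(target=ev, shot_times_ms=[latency], hit=hit,
                                    outcome=OutcomeKind.COMMISSION, rt_ms=latency)
                )
            else:
                trials.append(
                    BehavioralTrial(target=ev, shot_times_ms=[], hit=False,
                                    outcome=OutcomeKind.CORRECT_WITHHOLD, rt_ms=None)
                )
    return trials


def simulate_cohort_outcomes(
    subjects: Sequence[SubjectParams],
    n_sessions: int = 5,
    n_blocks: int = 6,
    intercept_sd_db: float = 2.5,
    slope_sd_db: float = 0.10,
    residual_sd_db: float = 1.35,
    modulation_effect_db: float = 0.10,
    seed: int = 0,
):
    """Block-level Fmtheta outcome table drawn directly from each
    subject's trend model, bypassing waveform synthesis.

    y(subject, session, block, modulation) =
        u_i + (session_trend_i + v_i) * (session - 1)
        + block_trend_i * (block - 1) + m * modulation + e,
    with u_i ~ N(0, intercept_sd^2) between-subject offsets,
    v_i ~ N(0, slope_sd^2) individual slope variability, and
    e ~ N(0, residual_sd^2) block-level noise (all in dB relative to
    the session threshold). modulation_effect_db is the up-minus-down
    fixed effect for ALT subjects (applied as +/- half around the block
    mean); the default is small, matching the observed near-null
    up/down separation in realized theta.

    Returns a pandas DataFrame with columns
    subject, group, session, block, modulation, y.
    """
    import pandas as pd

    from .protocol import assign_block_goals

    rows = []
    for idx, p in enumerate(subjects):
        rng = child_rng(seed, "cohort", p.subject_id)
        u = rng.normal(0.0, intercept_sd_db)
        v = rng.normal(0.0, slope_sd_db)
        half_sep = modulation_effect_db / 2.0
        for s in range(1, n_sessions + 1):
            goals = assign_block_goals(p.group, child_seed(seed, "goals", p.subject_id, s))
            for b in range(1, n_blocks + 1):
                goal = goals[b - 1]
                mod = 1 if goal is Goal.UP else 0
                mu = (
                    u
                    + (p.session_trend + v) * (s - 1)
                    + p.block_trend * (b - 1)
                    + (half_sep if mod == 1 else -half_sep) * (1 if p.group.value == "ALT" else 0)
                )
                y = mu + rng.normal(0.0, residual_sd_db)
                rows.append(
                    dict(subject=p.subject_id, group=p.group.value, session=s,
                         block=b, modulation=mod, y=y)
                )
    return pd.DataFrame(rows)
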