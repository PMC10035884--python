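"""Shared domain types for the neurofeedback simulation pipeline.

Units are stated on each field: EEG samples are microvolts (uV), band
power is uV^2 expressed as the mean over power-spectral-density bins in
the band, times are seconds or milliseconds as named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Group",
    "Goal",
    "Identity",
    "Condition",
    "OutcomeKind",
    "SignalSegment",
    "EEGRecord",
    "SubjectParams",
    "FeedbackConfig",
    "FeedbackFrame",
    "ThresholdState",
    "ThresholdSource",
    "TargetEvent",
    "TargetSchedule",
    "BehavioralTrial",
    "ThresholdResult",
    "Epoch",
    "RejectionCriteria",
    "BandPower",
]


class Group(str, Enum):
    """Training arm: up-modulation only (INC) or alternating up/down (ALT)."""

    INC = "INC"
    ALT = "ALT"


class Goal(str, Enum):
    """Modulation goal of a neurofeedback block."""

    UP = "Up"
    DOWN = "Down"


class Identity(str, Enum):
    ENEMY = "enemy"
    FRIENDLY = "friendly"


class Condition(str, Enum):
    """Shooting-task time-stress condition (FTP = familiarization block)."""

    LOW = "Low"
    HIGH = "High"
    FTP = "FTP"


class OutcomeKind(str, Enum):
    HIT = "hit"
    MISS = "miss"
    OMISSION = "omission"
    COMMISSION = "commission"
    CORRECT_WITHHOLD = "correct_withhold"


@dataclass
class SignalSegment:
    """A single-channel sampled signal in uV at a fixed rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "SignalSegment":
        return SignalSegment(self.samples.copy(), self.fs)


@dataclass
class EEGRecord:
    """Signal plus typed event list: (onset sample, duration samples, code)."""

    segment: SignalSegment
    events: list[tuple[int, int, str]] = field(default_factory=list)
    channel_label: str = "FCz"

    def __post_init__(self) -> None:
        n = self.segment.n_samples
        for onset, dur, code in self.events:
            if not (0 <= onset < n):
                raise ValueError(f"event {code!r} onset {onset} outside [0, {n})")
            if dur < 0:
                raise ValueError(f"event {code!r} has negative duration {dur}")

    @property
    def fs(self) -> float:
        return self.segment.fs

    def events_with_code(self, code: str) -> list[tuple[int, int, str]]:
        return [e for e in self.events if e[2] == code]


@dataclass
class SubjectParams:
    """Generative parameters of one virtual subject.

    baseline_theta_power is the band-mean theta PSD (uV^2/Hz over 4-7 Hz)
    during rest; up_gain/down_gain multiply that power during modulation;
    session_trend/block_trend are additive dB changes per session/block.
    tet50_ms < tet90_ms because the hit rate increases with target
    exposure time; rt_spread is the log-space SD of the lognormal shot
    latency.
    """

    subject_id: str
    group: Group
    baseline_theta_power: float = 10.0
    up_gain: float = 2.0
    down_gain: float = 0.5
    session_trend: float = 0.0
    block_trend: float = 0.0
    alpha_power: float = 8.0
    artifact_rate: float = 2.0
    tet50_ms: float = 750.0
    tet90_ms: float = 1100.0
    commission_prob: float = 0.25
    rt_median_ms: float = 450.0
    rt_spread: float = 0.25

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.up_gain < 0 or self.down_gain < 0:
            raise ValueError("gains must be >= 0")
        if not 0 <= self.commission_prob <= 1:
            raise ValueError("commission_prob must be in [0, 1]")
        if self.tet50_ms >= self.tet90_ms:
            raise ValueError("tet50_ms must be < tet90_ms (hit rate increases with TET)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.baseline_theta_power <= 0:
            raise ValueError("baseline_theta_power must be > 0")

    def goal_gain(self, goal: Goal) -> float:
        return self.up_gain if Goal(goal) is Goal.UP else self.down_gain


@dataclass
class FeedbackConfig:
    """Online feedback estimator settings (1-s window, 875-ms overlap
    at 2048 Hz gives 8 power estimates per second)."""

    fs: float = 2048.0
    window_samples: int = 2048
    overlap_samples: int = 1792
    band_lo: float = 4.0
    band_hi: float = 7.0
    artifact_limit_uV: float = 75.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_samples < self.window_samples:
            raise ValueError("need 0 <= overlap_samples < window_samples")
        if not 0 < self.band_lo < self.band_hi < self.fs / 2:
            raise ValueError("need 0 < band_lo < band_hi < fs/2")

    @property
    def hop_samples(self) -> int:
        return self.window_samples - self.overlap_samples

    @property
    def frames_per_second(self) -> float:
        return self.fs / self.hop_samples


@dataclass
class FeedbackFrame:
    """One online theta-power estimate (window ending at t_s)."""

    t_s: float
    theta_power: float
    db: float = float("nan")
    gated: bool = False
    achieved: bool = False


class ThresholdSource(str, Enum):
    RESTING_BASELINE = "resting_baseline"
    PREVIOUS_SESSION_MEAN = "previous_session_mean"


@dataclass
class ThresholdState:
    """Session modulation threshold (uV^2 band-mean theta power)."""

    value: float
    session_index: int
    source: ThresholdSource

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("threshold value must be positive")


@dataclass
class TargetEvent:
    index: int
    lane: str            # left | center | right
    distance: str        # near | mid | far
    identity: Identity
    onset_ms: float      # from block start
    tet_ms: float        # target exposure time

    def __post_init__(self) -> None:
        self.identity = Identity(self.identity)
        if self.tet_ms <= 0:
            raise ValueError("tet_ms must be positive")


@dataclass
class TargetSchedule:
    condition: Condition
    blocks: list[list[TargetEvent]]

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        for block in self.blocks:
            onsets = [e.onset_ms for e in block]
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise ValueError("onsets must be strictly increasing within a block")

    @property
    def events(self) -> list[TargetEvent]:
        return [e for block in self.blocks for e in block]

    @property
    def n_events(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass
class BehavioralTrial:
    """Scored response to one target (rt_ms is None iff no shot fired)."""

    target: TargetEvent
    shot_times_ms: list[float]
    hit: bool
    outcome: OutcomeKind
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.outcome = OutcomeKind(self.outcome)
        if (self.rt_ms is None) != (len(self.shot_times_ms) == 0):
            raise ValueError("rt_ms must be absent iff no shot was fired")


@dataclass
class ThresholdResult:
    """Psychometric thresholds from the method of limits."""

    tet50_ms: float
    tet90_ms: float
    slope: float  # logistic slope, 1/ms

    def __post_init__(self) -> None:
        if not self.tet50_ms < self.tet90_ms:
            raise ValueError("tet50_ms must be < tet90_ms")


@dataclass
class Epoch:
    samples: np.ndarray
    fs: float
    t0_s: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class RejectionCriteria:
    """Four-criterion automatic epoch rejection thresholds."""

    amp_limit_uV: float = 100.0
    jointprob_sd: float = 5.0
    slope_limit_uV_per_epoch: float = 75.0
    slope_r2_limit: float = 0.3
    kurtosis_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "amp_limit_uV",
            "jointprob_sd",
            "slope_limit_uV_per_epoch",
            "slope_r2_limit",
            "kurtosis_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BandPower:
    power: float
    band: tuple[float, float]
    db_rel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("power must be >= 0")
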