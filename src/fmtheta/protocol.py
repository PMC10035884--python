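"""Neurofeedback protocol structure.

A training session is six blocks of six trials; every trial is a 10-s
rest period followed by a 30-s active modulation period, so each block
contains 180 s of active modulation and each session 1080 s. The INC arm
up-modulates in every block; the ALT arm receives three up- and three
down-modulation blocks in randomized order with no more than two equal
goals in a row. The full study is an orientation session, five combined
NF + shooting sessions and one final shooting-only session.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

from ._seeds import child_rng
from .types import Goal, Group, ThresholdState

__all__ = [
    "REST_S",
    "MODULATION_S",
    "TRIALS_PER_BLOCK",
    "BLOCKS_PER_SESSION",
    "NF_SESSIONS",
    "SH_SESSIONS",
    "NFBlock",
    "NFSession",
    "StudyPlan",
    "Interval",
    "assign_block_goals",
    "valid_alt_sequences",
    "build_session_timeline",
    "build_study_plan",
]

REST_S = 10.0
MODULATION_S = 30.0
TRIALS_PER_BLOCK = 6
BLOCKS_PER_SESSION = 6
NF_SESSIONS = 5
SH_SESSIONS = 6


@dataclass
class Interval:
    """One contiguous timeline interval of a session."""

    start_s: float
    end_s: float
    kind: str               # "rest" | "modulation"
    block_index: int        # 1-based
    trial_index: int        # 1-based within block
    goal: Goal

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class NFBlock:
    block_index: int
    goal: Goal
    n_trials: int = TRIALS_PER_BLOCK
    rest_s: float = REST_S
    modulation_s: float = MODULATION_S

    @property
    def active_s(self) -> float:
        return self.n_trials * self.modulation_s

    @property
    def rest_total_s(self) -> float:
        return self.n_trials * self.rest_s

    @property
    def duration_s(self) -> float:
        return self.active_s + self.rest_total_s


@dataclass
class NFSession:
    session_index: int
    blocks: list[NFBlock]
    threshold: Optional[ThresholdState] = None

    def __post_init__(self) -> None:
        if len(self.blocks) != BLOCKS_PER_SESSION:
            raise ValueError(f"a session has exactly {BLOCKS_PER_SESSION} blocks")

    @property
    def goals(self) -> list[Goal]:
        return [b.goal for b in self.blocks]

    @property
    def active_s(self) -> float:
        return sum(b.active_s for b in self.blocks)

    @property
    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    def intervals(self) -> Iterator[Interval]:
        """Contiguous, disjoint rest/modulation intervals in session time."""
        t = 0.0
        for block in self.blocks:
            for trial in range(1, block.n_trials + 1):
                yield Interval(t, t + block.rest_s, "rest", block.block_index, trial, block.goal)
                t += block.rest_s
                yield Interval(
                    t, t + block.modulation_s, "modulation", block.block_index, trial, block.goal
                )
                t += block.modulation_s


@dataclass
class StudyPlan:
    """Seven-session study timeline with per-subject NF goal sequences.

    Session 1 runs the shooting task before NF training (pre-test);
    sessions 2-5 run NF before shooting; session 6 is shooting only.
    """

    groups: dict[str, Group]
    nf_sessions: dict[str, list[NFSession]]
    sh_before_nf_session: int = 1
    n_sh_sessions: int = SH_SESSIONS

    @property
    def subject_ids(self) -> list[str]:
        return list(self.groups)

    def group_size(self, group: Group) -> int:
        return sum(1 for g in self.groups.values() if g is Group(group))


def _max_run(goals: list[Goal]) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(goals))


def valid_alt_sequences() -> list[tuple[Goal, ...]]:
    """All arrangements of 3 Up / 3 Down goals with no run of 3 or more.

    Brute-force enumeration over the C(6,3) = 20 arrangements; 14 satisfy
    the run-length constraint.
    """
    out = []
    for positions in itertools.combinations(range(BLOCKS_PER_SESSION), 3):
        goals = [Goal.DOWN] * BLOCKS_PER_SESSION
        for p in positions:
            goals[p] = Goal.UP
        if _max_run(goals) <= 2:
            out.append(tuple(goals))
    return out


def assign_block_goals(group: Group, seed: int) -> list[Goal]:
    """Goal sequence for one session of one subject.

    INC: all six blocks up-modulate. ALT: rejection sampling from uniform
    permutations of 3 Up / 3 Down until no more than two consecutive
    blocks share a goal — uniform over the 14 valid sequences.
    """
    group = Group(group)
    if group is Group.INC:
        return [Goal.UP] * BLOCKS_PER_SESSION
    rng = child_rng(seed, "block-goals")
    goals = [Goal.UP] * 3 + [Goal.DOWN] * 3
    while True:
        perm = [goals[i] for i in rng.permutation(BLOCKS_PER_SESSION)]
        if _max_run(perm) <= 2:
            return perm


def build_session_timeline(
    session_index: int,
    goals: list[Goal],
    threshold: Optional[ThresholdState] = None,
) -> NFSession:
    """Assemble one NF session from a six-goal sequence."""
    if len(goals) != BLOCKS_PER_SESSION:
        raise ValueError(f"expected {BLOCKS_PER_SESSION} goals, got {len(goals)}")
    blocks = [NFBlock(block_index=i + 1, goal=Goal(g)) for i, g in enumerate(goals)]
    return NFSession(session_index=session_index, blocks=blocks, threshold=threshold)


def build_study_plan(
    n_inc: int = 12,
    n_alt: int = 18,
    master_seed: int = 0,
) -> StudyPlan:
    """Build the full study: per-subject NF sessions with independent goal
    randomization per subject-session, deterministic in the master seed."""
    if n_inc < 1 or n_alt < 1:
        raise ValueError("group sizes must be >= 1")
    groups: dict[str, Group] = {}
    for i in range(n_inc):
        groups[f"INC{i + 1:02d}"] = Group.INC
    for i in range(n_alt):
        groups[f"ALT{i + 1:02d}"] = Group.ALT

    nf_sessions: dict[str, list[NFSession]] = {}
    for sid, grp in groups.items():
        sessions = []
        for s in range(1, NF_SESSIONS + 1):
            seed = child_rng(master_seed, "goals", sid, s).integers(2**31)
            goals = assign_block_goals(grp, int(seed))
            sessions.append(build_session_timeline(s, goals))
        nf_sessions[sid] = sessions
    return StudyPlan(groups=groups, nf_sessions=nf_sessions)
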