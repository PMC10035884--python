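"""Go-NoGo shooting task: schedules, psychophysics, scoring, metrics.

The main task presents 360 pop-up targets per time-stress condition —
40 at each of 9 range locations (3 lanes x 3 distances), 324 enemy and
36 friendly (a .90/.10 Go/No-Go ratio), split into 4 blocks of 90
trials. Inter-target intervals are 1000 +/- 500 ms over a discrete
Gaussian lattice in 100-ms steps; target exposure times (TETs) are
individualized around the subject's 50th (High stress) or 90th (Low
stress) percentile hit-rate thresholds, obtained by the psychophysical
method of limits (10 trials at each of 11 TETs in alternating
ascending/descending series).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._seeds import child_rng, child_seed
from .types import (
    BehavioralTrial,
    Condition,
    Identity,
    OutcomeKind,
    SubjectParams,
    TargetEvent,
    TargetSchedule,
    ThresholdResult,
)

__all__ = [
    "LANES",
    "DISTANCES",
    "generate_target_schedule",
    "generate_ftp_schedule",
    "default_iptp_levels",
    "run_method_of_limits_series",
    "method_of_limits",
    "score_events",
    "compute_behavioral_metrics",
    "BehavioralMetrics",
]

LANES = ("left", "center", "right")
DISTANCES = ("near", "mid", "far")

N_MAIN_TARGETS = 360
N_PER_CELL = 40
N_ENEMY = 324
N_FRIENDLY = 36
N_BLOCKS = 4

ITI_MAIN_LATTICE_MS = np.arange(500, 1501, 100)
ITI_MAIN_SIGMA_MS = 250.0
ITI_FTP_LATTICE_MS = np.arange(1000, 3001, 100)
ITI_FTP_SIGMA_MS = 500.0
FTP_TET_VALUES_MS = np.arange(400, 1501, 100)
TET_SIGMA_MS = 100.0
TET_CLIP_MS = (400.0, 1500.0)


def _discrete_gaussian(rng: np.random.Generator, lattice: np.ndarray,
                       center: float, sigma: float, size: int) -> np.ndarray:
    """Draws from a Gaussian truncated to and discretized on a lattice."""
    w = np.exp(-0.5 * ((lattice - center) / sigma) ** 2)
    w /= w.sum()
    return rng.choice(lattice, size=size, p=w)


def _assemble_blocks(
    rng: np.random.Generator,
    lanes: np.ndarray,
    dists: np.ndarray,
    identities: np.ndarray,
    tets: np.ndarray,
    itis: np.ndarray,
    n_blocks: int,
    condition: Condition,
) -> TargetSchedule:
    n = lanes.shape[0]
    per_block = n // n_blocks
    blocks: list[list[TargetEvent]] = []
    idx = 0
    for _b in range(n_blocks):
        onset = 0.0
        block: list[TargetEvent] = []
        for _ in range(per_block):
            onset += itis[idx]
            block.append(
                TargetEvent(
                    index=idx, lane=str(lanes[idx]), distance=str(dists[idx]),
                    identity=Identity(identities[idx]), onset_ms=float(onset),
                    tet_ms=float(tets[idx]),
                )
            )
            onset += tets[idx]
            idx += 1
        blocks.append(block)
    return TargetSchedule(condition=condition, blocks=blocks)


def generate_target_schedule(
    condition: Condition,
    tet50_ms: float,
    tet90_ms: float,
    seed: int = 0,
) -> TargetSchedule:
    """Main-task schedule for one time-stress condition.

    360 events, exactly 40 per lane-by-distance cell, exactly 324 enemy
    and 36 friendly, in a pseudorandom order; ITIs on the 500-1500 ms
    100-ms lattice (discrete Gaussian, sigma 250 ms); TETs a discrete
    Gaussian (sigma 100 ms, 10-ms grid) centered on tet50 (High stress)
    or tet90 (Low stress), clipped to 400-1500 ms; split into 4 x 90.
    """
    condition = Condition(condition)
    if condition not in (Condition.LOW, Condition.HIGH):
        raise ValueError("main-task condition must be Low or High")
    if tet50_ms <= 0 or tet90_ms <= 0:
        raise ValueError("TETs must be positive")
    rng = child_rng(seed, "schedule", condition.value)

    cells = [(lane, dist) for lane in LANES for dist in DISTANCES]
    lanes = np.array([lane for lane, _ in cells for _ in range(N_PER_CELL)])
    dists = np.array([dist for _, dist in cells for _ in range(N_PER_CELL)])
    identities = np.array(
        [Identity.ENEMY.value] * N_ENEMY + [Identity.FRIENDLY.value] * N_FRIENDLY
    )
    order = rng.permutation(N_MAIN_TARGETS)
    lanes, dists = lanes[order], dists[order]
    identities = identities[rng.permutation(N_MAIN_TARGETS)]

    center = tet50_ms if condition is Condition.HIGH else tet90_ms
    tets = rng.normal(center, TET_SIGMA_MS, size=N_MAIN_TARGETS)
    tets = np.clip(np.round(tets / 10) * 10, *TET_CLIP_MS)
    itis = _discrete_gaussian(rng, ITI_MAIN_LATTICE_MS, 1000.0, ITI_MAIN_SIGMA_MS,
                              N_MAIN_TARGETS)
    return _assemble_blocks(rng, lanes, dists, identities, tets, itis, N_BLOCKS, condition)


def generate_ftp_schedule(seed: int = 0) -> TargetSchedule:
    """Familiarization block: 100 all-enemy targets, ITIs 2000 +/- 1000 ms
    on a 100-ms discrete-Gaussian lattice, TETs spread near-uniformly
    over the twelve 100-ms bins from 400 to 1500 ms in random order."""
    rng = child_rng(seed, "ftp")
    n = 100
    reps = int(np.ceil(n / FTP_TET_VALUES_MS.size))
    tets = np.tile(FTP_TET_VALUES_MS, reps)
    tets = tets[rng.permutation(tets.size)][:n]
    itis = _discrete_gaussian(rng, ITI_FTP_LATTICE_MS, 2000.0, ITI_FTP_SIGMA_MS, n)
    lanes = np.array(LANES)[rng.integers(0, 3, size=n)]
    dists = np.array(DISTANCES)[rng.integers(0, 3, size=n)]
    identities = np.array([Identity.ENEMY.value] * n)
    return _assemble_blocks(rng, lanes, dists, identities, tets, itis, 1, Condition.FTP)


def default_iptp_levels(lo_ms: float = 400.0, hi_ms: float = 1400.0, n: int = 11) -> np.ndarray:
    """Default 11 TET levels for the individual performance thresholding
    procedure (100-ms steps from 400 to 1400 ms)."""
    return np.linspace(lo_ms, hi_ms, n)


def run_method_of_limits_series(
    params: SubjectParams,
    levels_ms: Optional[np.ndarray] = None,
    trials_per_level: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the thresholding procedure on a virtual subject:
    trials_per_level presentations at each of the 11 TET levels in
    alternating ascending/descending series. Returns a long table with
    columns (series, tet_ms, hit)."""
    from .synth import simulate_shooter  # local import avoids cycle

    levels = np.asarray(default_iptp_levels() if levels_ms is None else levels_ms, dtype=float)
    rows = []
    for series in range(trials_per_level):
        order = levels if series % 2 == 0 else levels[::-1]
        events = []
        onset = 0.0
        for i, tet in enumerate(order):
            onset += 1000.0
            events.append(
                TargetEvent(index=i, lane="center", distance="mid",
                            identity=Identity.ENEMY, onset_ms=onset, tet_ms=float(tet))
            )
            onset += tet
        schedule = TargetSchedule(condition=Condition.FTP, blocks=[events])
        trials = simulate_shooter(params, schedule, seed=child_seed(seed, "iptp", series))
        for tr in trials:
            rows.append(dict(series=series, tet_ms=tr.target.tet_ms, hit=tr.hit))
    return pd.DataFrame(rows)


def method_of_limits(responses: pd.DataFrame) -> ThresholdResult:
    """Fit a two-parameter logistic hit-rate curve by maximum likelihood
    to pooled ascending/descending series and invert it at 0.5 and 0.9.

    `responses` needs columns tet_ms and hit (boolean); rows from all
    series are pooled. Degenerate data (all hits or all misses) admit no
    threshold and raise ValueError.
    """
    if not {"tet_ms", "hit"}.issubset(responses.columns):
        raise ValueError("responses needs columns 'tet_ms' and 'hit'")
    grouped = responses.groupby("tet_ms")["hit"].agg(["sum", "count"])
    if len(grouped) < 2:
        raise ValueError("need at least 2 TET levels")
    k_hits = grouped["sum"].to_numpy(dtype=float)
    n_trials = grouped["count"].to_numpy(dtype=float)
    tet = grouped.index.to_numpy(dtype=float)
    if k_hits.sum() == 0 or k_hits.sum() == n_trials.sum():
        raise ValueError("degenerate data: all hits or all misses, no threshold")

    def nll(theta: np.ndarray) -> float:
        t50, log_k = theta
        p = expit(np.exp(log_k) * (tet - t50))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(k_hits * np.log(p) + (n_trials - k_hits) * np.log(1 - p)).sum())

    span = tet.max() - tet.min()
    p_emp = np.clip(k_hits / n_trials, 0.01, 0.99)
    t50_init = float(np.interp(0.5, p_emp, tet)) if np.all(np.diff(p_emp) >= 0) else float(
        tet.mean()
    )
    x0 = np.array([t50_init, np.log(np.log(9.0) / (span / 2))])
    res = minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(tet.min() - span, tet.max() + span), (np.log(1e-4), np.log(1.0))],
    )
    t50, log_k = res.x
    k = float(np.exp(log_k))
    t90 = float(t50 + logit(0.9) / k)
    return ThresholdResult(tet50_ms=float(t50), tet90_ms=t90, slope=k)


def score_events(trials: Sequence[BehavioralTrial]) -> int:
    """Scoreboard total: enemy shot fired +1 and hit +1; friendly
    withheld +1; friendly fired -1 and hit -1; enemy omission -1; enemy
    missed -1."""
    score = 0
    for tr in trials:
        fired = len(tr.shot_times_ms) > 0
        if tr.target.identity is Identity.ENEMY:
            if fired:
                score += 1            # shot fired at enemy
                score += 1 if tr.hit else -1   # hit, or failed execution
            else:
                score -= 1            # omission
        else:
            if fired:
                score -= 1            # commission
                if tr.hit:
                    score -= 1        # compounded commission
            else:
                score += 1            # correct withhold
    return score


class BehavioralMetrics(dict):
    """Per-condition behavioral summary (commission_pct, hit_pct, mean_rt_ms)."""


def compute_behavioral_metrics(trials: Sequence[BehavioralTrial]) -> BehavioralMetrics:
    """Commission % = friendly targets fired upon / friendly targets;
    hit % = enemy targets hit (any shot) / enemy targets; RT = time of
    the hitting shot for hits, first shot for misses, nothing for
    omissions. Metrics are order-invariant; an empty target class yields
    a missing metric with a warning."""
    friendly = [t for t in trials if t.target.identity is Identity.FRIENDLY]
    enemy = [t for t in trials if t.target.identity is Identity.ENEMY]
    out = BehavioralMetrics(commission_pct=None, hit_pct=None, mean_rt_ms=None)
    if friendly:
        out["commission_pct"] = 100.0 * sum(
            1 for t in friendly if t.shot_times_ms
        ) / len(friendly)
    else:
        warnings.warn("no friendly targets: commission_pct missing", stacklevel=2)
    if enemy:
        out["hit_pct"] = 100.0 * sum(1 for t in enemy if t.hit) / len(enemy)
        rts = [t.rt_ms for t in enemy if t.rt_ms is not None]
        out["mean_rt_ms"] = float(np.mean(rts)) if rts else None
    else:
        warnings.warn("no enemy targets: hit_pct missing", stacklevel=2)
    return out
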