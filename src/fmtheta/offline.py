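"""Offline EEG stage: filtering/downsampling, epoching, four-criterion
artifact rejection, Welch band power, dB conversion and retention
accounting.

The rejection stage mirrors standard automatic epoch screening: an
absolute amplitude limit, a joint-probability criterion on the pooled
amplitude distribution, an abnormal-trend (slope + R^2) criterion, and a
kurtosis criterion, the latter two z-scored across epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from scipy import signal, stats

from .types import BandPower, EEGRecord, Epoch, RejectionCriteria, SignalSegment

__all__ = [
    "preprocess_record",
    "epoch_records",
    "subdivide_epoch",
    "reject_epochs",
    "RejectionReport",
    "welch_band_power",
    "trial_band_power",
    "band_power_db",
    "retention_stats",
]


def preprocess_record(
    record: EEGRecord, highpass_hz: float = 1.0, target_fs: float = 512.0
) -> EEGRecord:
    """Zero-phase FIR highpass then anti-aliased integer decimation.

    Event onsets/durations are remapped to the new sampling rate.
    """
    fs = record.fs
    factor = fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {fs} not an integer multiple of target_fs {target_fs}")
    factor = int(round(factor))

    x = record.segment.samples
    if highpass_hz > 0:
        # zero-phase (forward-backward) 4th-order Butterworth highpass
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    if factor > 1:
        x = signal.decimate(x, factor, ftype="fir", zero_phase=True)

    events = [(onset // factor, dur // factor, code) for onset, dur, code in record.events]
    return EEGRecord(
        segment=SignalSegment(x, target_fs),
        events=events,
        channel_label=record.channel_label,
    )


def epoch_records(
    record: EEGRecord, event_code: str, t_min_s: float, t_max_s: float
) -> tuple[list[Epoch], int]:
    """One epoch per matching event over the half-open sample window
    [onset + t_min*fs, onset + t_max*fs). Events whose window falls
    outside the record are dropped and counted; returns (epochs, n_dropped).
    """
    fs = record.fs
    x = record.segment.samples
    n = x.shape[0]
    lo_off = int(round(t_min_s * fs))
    hi_off = int(round(t_max_s * fs))
    epochs: list[Epoch] = []
    dropped = 0
    matches = record.events_with_code(event_code)
    if not matches:
        warnings.warn(f"no events with code {event_code!r}", stacklevel=2)
    for onset, _dur, code in matches:
        lo, hi = onset + lo_off, onset + hi_off
        if lo < 0 or hi > n:
            dropped += 1
            continue
        epochs.append(Epoch(samples=x[lo:hi].copy(), fs=fs, t0_s=t_min_s, label=code))
    return epochs, dropped


def subdivide_epoch(epoch: Epoch, win_s: float = 1.0) -> list[Epoch]:
    """Cut an epoch into non-overlapping sub-epochs of win_s seconds."""
    step = int(round(win_s * epoch.fs))
    n = epoch.samples.shape[0] // step
    return [
        Epoch(
            samples=epoch.samples[i * step : (i + 1) * step].copy(),
            fs=epoch.fs,
            t0_s=epoch.t0_s + i * win_s,
            label=epoch.label,
        )
        for i in range(n)
    ]


@dataclass
class RejectionReport:
    keep_mask: np.ndarray
    counts: dict[str, int]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


def _slope_r2(y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope in uV per epoch length, and fit R^2."""
    n = y.shape[0]
    t = np.linspace(0.0, 1.0, n)  # epoch-length units: slope = rise over epoch
    tc = t - t.mean()
    yc = y - y.mean()
    denom = (tc**2).sum()
    slope = float((tc * yc).sum() / denom)
    ss_res = ((yc - slope * tc) ** 2).sum()
    ss_tot = (yc**2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, float(r2)


def reject_epochs(
    epochs: list[Epoch], criteria: RejectionCriteria | None = None
) -> RejectionReport:
    """Flag epochs by four criteria; keep_mask marks epochs passing all.

    (a) amplitude: any |sample| > amp_limit_uV;
    (b) joint probability: mean negative log-likelihood of the epoch's
        samples under a Gaussian fit to the pooled amplitude distribution,
        z-scored across epochs, > jointprob_sd;
    (c) abnormal trend: |least-squares slope| > slope limit (uV over the
        epoch) AND fit R^2 > slope_r2_limit (conjunctive);
    (d) kurtosis: sample kurtosis z-scored across epochs > kurtosis_sd.
    Criteria (b) and (d) need the across-epoch distribution; with fewer
    than 8 epochs, or zero variance, they are skipped with a warning.
    """
    criteria = criteria or RejectionCriteria()
    n = len(epochs)
    if n == 0:
        return RejectionReport(np.zeros(0, dtype=bool), {k: 0 for k in "abcd"})
    data = np.stack([e.samples for e in epochs])

    flag_a = np.abs(data).max(axis=1) > criteria.amp_limit_uV

    slopes_r2 = np.array([_slope_r2(row) for row in data])
    flag_c = (np.abs(slopes_r2[:, 0]) > criteria.slope_limit_uV_per_epoch) & (
        slopes_r2[:, 1] > criteria.slope_r2_limit
    )

    flag_b = np.zeros(n, dtype=bool)
    flag_d = np.zeros(n, dtype=bool)
    if n >= 8:
        pooled_mu = data.mean()
        pooled_sd = data.std()
        if pooled_sd > 0:
            nll = 0.5 * np.log(2 * np.pi * pooled_sd**2) + (
                (data - pooled_mu) ** 2 / (2 * pooled_sd**2)
            ).mean(axis=1)
            nll_sd = nll.std()
            if nll_sd > 0:
                flag_b = (nll - nll.mean()) / nll_sd > criteria.jointprob_sd
            kurt = stats.kurtosis(data, axis=1)
            kurt_sd = kurt.std()
            if kurt_sd > 0:
                flag_d = (kurt - kurt.mean()) / kurt_sd > criteria.kurtosis_sd
        else:
            warnings.warn("zero variance: joint-probability and kurtosis criteria skipped",
                          stacklevel=2)
    else:
        warnings.warn("fewer than 8 epochs: distribution-based criteria skipped",
                      stacklevel=2)

    keep = ~(flag_a | flag_b | flag_c | flag_d)
    counts = {
        "amplitude": int(flag_a.sum()),
        "jointprob": int(flag_b.sum()),
        "trend": int(flag_c.sum()),
        "kurtosis": int(flag_d.sum()),
    }
    return RejectionReport(keep_mask=keep, counts=counts)


def welch_band_power(
    samples: np.ndarray,
    fs: float,
    win_s: float = 1.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (4.0, 7.0),
    statistic: str = "mean",
) -> BandPower:
    """Welch PSD (Hann taper, density scaling, no detrending) reduced over
    the band: statistic='mean' averages PSD bins in [lo, hi] inclusive
    (uV^2/Hz), statistic='integral' integrates them (uV^2).
    """
    samples = np.asarray(samples, dtype=float)
    nperseg = int(round(win_s * fs))
    if samples.shape[0] < nperseg:
        raise ValueError(f"need at least {nperseg} samples, got {samples.shape[0]}")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        samples, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density",
    )
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError(f"no PSD bins inside band {band}")
    if statistic == "mean":
        power = float(psd[in_band].mean())
    elif statistic == "integral":
        df = float(freqs[1] - freqs[0])
        power = float(psd[in_band].sum() * df)  # rectangular sum: exact Parseval
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return BandPower(power=power, band=(lo, hi))


def trial_band_power(
    epoch: Epoch,
    baseline_span_s: float = 3.0,
    criteria: RejectionCriteria | None = None,
    band: tuple[float, float] = (4.0, 7.0),
    win_s: float = 1.0,
) -> tuple[Optional[BandPower], RejectionReport]:
    """Artifact-screened band power of one trial epoch.

    The epoch (baseline + task, e.g. -3 to 30 s) is cut into 1-s
    sub-epochs, screened by the four rejection criteria, and band power
    is averaged over the surviving windows separately for the baseline
    span (the first `baseline_span_s` seconds) and the task span. The
    returned BandPower carries the task power with db_rel against the
    baseline; None if either span lost all its windows.
    """
    subs = subdivide_epoch(epoch, win_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = reject_epochs(subs, criteria)
    base_p, task_p = [], []
    for sub, keep in zip(subs, report.keep_mask):
        if not keep:
            continue
        p = welch_band_power(sub.samples, sub.fs, win_s=win_s, band=band).power
        if sub.t0_s < epoch.t0_s + baseline_span_s:
            base_p.append(p)
        else:
            task_p.append(p)
    if not base_p or not task_p:
        return None, report
    task = float(np.mean(task_p))
    ref = float(np.mean(base_p))
    bp = BandPower(power=task, band=band)
    bp.db_rel = band_power_db(task, ref) if ref > 0 else None
    return bp, report


def band_power_db(task_power: float, reference_power: float) -> float:
    """10*log10(task/reference) relative band power in dB.

    The reference is the pre-trial baseline period mean power (NF: -3 to
    0 s; shooting: -1 to 0 s).
    """
    if reference_power <= 0:
        raise ValueError("reference power must be positive")
    if task_power < 0:
        raise ValueError("task power must be >= 0")
    if task_power == 0:
        return -60.0
    return 10.0 * np.log10(task_power / reference_power)


def retention_stats(kept_units: int, total_units: int) -> tuple[int, int, float]:
    """Data-retention summary: (kept, total, 100*kept/total) with the
    percentage rounded half-up to 2 decimals."""
    if total_units <= 0:
        raise ValueError("total_units must be positive")
    if not 0 <= kept_units <= total_units:
        raise ValueError("need 0 <= kept_units <= total_units")
    pct = Decimal(100 * kept_units) / Decimal(total_units)
    pct = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return kept_units, total_units, pct
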