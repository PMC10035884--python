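# Methods

`fmtheta` is an in-silico replica of a two-arm frontal-midline theta
(Fmθ) neurofeedback training study with a Go-NoGo shooting task as the
behavioral outcome. Every stage of the real protocol — the closed-loop
feedback computation, the session structure, the task, the offline EEG
analysis and the multilevel statistics — is implemented and exercised
on synthetic subjects whose generative structure matches what the
analysis stage assumes. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic cohort does
and does not establish about real data.

## Study design

Thirty virtual subjects (12 INC, 18 ALT) complete five neurofeedback
training sessions and six shooting-task test sessions. A training
session is six blocks of six trials; each trial is a 10-s rest followed
by a 30-s active modulation period, giving 180 s of modulation per
block, 1080 s per session and 5400 s across the five sessions. INC
subjects up-modulate in every block; ALT subjects receive three up- and
three down-modulation blocks per session, randomized under the
constraint that no more than two consecutive blocks share a goal. Of
the C(6,3) = 20 arrangements of three Up/three Down, exactly 14 satisfy
the constraint; `protocol.assign_block_goals` samples them uniformly by
rejection from random permutations, independently per subject-session.
In session 1 the shooting task precedes training (pre-test); sessions
2–5 train before testing; session 6 is test-only.

## Online feedback engine

Theta power is estimated on sliding 1-s windows (2048 samples at
2048 Hz) hopping by 256 samples — an 875-ms overlap, hence exactly
fs / (window − overlap) = 8 estimates per second with 1 s of history. A
60-s record yields (60·2048 − 2048)/256 + 1 = 473 frames. Each window
is Hann-tapered, converted to a one-sided power spectral density and
averaged over the bins with 4 ≤ f ≤ 7 Hz (band-mean, units μV²/Hz).
The streaming estimator's frame mean equals an offline Welch estimate
with the same window and overlap to machine precision (no detrending in
either path); this equivalence is pinned by test.

The displayed value is 10·log10(power / threshold) dB. The session-1
threshold is the subject's resting theta power from a 60-s eyes-open
baseline; each later session uses the arithmetic mean of the previous
session's six block mean powers. Zero power is clamped at −60 dB.
Windows containing any sample beyond ±75 μV are gated: the display
holds the last artifact-free power/dB until the first fully clean
window. A stream that starts gated holds 0 dB (the threshold level) — a
neutral convention for a case the protocol leaves open. Block
achievement is the percentage of non-gated frames strictly on the goal
side of 0 dB; frames at exactly 0 dB count for neither goal, so
up- and down-achievement sum to 100% in the absence of ties.

## Synthetic EEG

A session record is the sum of

* a 1/f^a background (default a = 1, RMS 2 μV), built by shaping white
  Gaussian noise in the frequency domain;
* a narrowband 4–7 Hz theta component whose band-mean power follows the
  trial envelope: baseline θ₀ (default 10 μV²/Hz) during rests and
  θ₀ · gain(goal) · 10^((session_trend·(s−1) + block_trend·(b−1))/10)
  during modulation. Gains act multiplicatively on power (default up
  2.0, down 0.5, i.e. ±3 dB); trends act additively in dB, so the
  dB-scale analysis sees linear trends by construction. The narrowband
  carrier is normalized against a measured Welch estimate so its band
  power is exact for each realization; a pure-tone mode (6 Hz) is kept
  for closed-form checks (band-integrated power a²/2);
* a 10-Hz alpha tone (default 8 μV² band power) as an out-of-band
  bystander;
* raised-cosine artifact pulses (peak 150 μV, 250 ms) at a Poisson rate
  (default 2/min), detectable by the ±75 μV online rule by
  construction.

The 2-μV background keeps its theta-band content below ~1% of the
baseline theta power, so the measured modulation/rest band-power ratio
recovers the generative gain within the 5% calibration tolerance. All
generators are pure functions of their arguments and a seed; substreams
derive from counter-based seed splitting per (subject, session, role),
so regenerating any one piece never perturbs another.

## Virtual shooter and psychophysics

Enemy targets: shot latency is lognormal (median 450 ms, log-SD 0.25);
a shot fires iff the latency is within the target exposure time (TET),
otherwise the trial is an omission. The fired shot hits with
conditional probability p(TET)/P(latency ≤ TET) clipped at 1, where
p(·) is the logistic psychometric through (tet50, 0.5) and (tet90, 0.9)
(defaults 750/1100 ms) — so the overall hit rate equals the
psychometric exactly wherever the clip is inactive. Friendly targets
fire (a commission error) with fixed probability. The simulator fires
at most one shot per trial; the scoring and metrics layer accepts
multi-shot records (hit if any shot hit; RT is the hitting shot's time
for hits, the first shot's time for misses).

The method of limits presents 10 trials at each of 11 TETs (default
400–1400 ms in 100-ms steps) in alternating ascending/descending
series, pools them, and fits the two-parameter logistic by maximum
likelihood (L-BFGS-B on the binomial deviance; slope bounded in
[1e-4, 1] per ms, which keeps perfect step data finite while leaving
the 50% point inside the empirical step). Thresholds are the 0.5 and
0.9 inverses. Recovery is within 10% at the protocol's trial counts.

Main-task schedules contain 360 targets per time-stress condition — 40
at each of 3 lanes × 3 distances, exactly 324 enemy and 36 friendly
(the .90/.10 Go/No-Go ratio held exactly rather than by Bernoulli
draws, which stabilizes commission denominators) — in four blocks of
90. Inter-target intervals are a discrete Gaussian on the 500–1500 ms
lattice in 100-ms steps (σ = 250 ms, half the half-range); the
familiarization block uses the same rule on 1000–3000 ms (σ = 500 ms)
with 100 all-enemy targets and TETs spread near-uniformly over the
twelve 100-ms bins from 400–1500 ms. Per-event TETs in the main task
are normal around tet50 (High stress) or tet90 (Low stress) with
σ = 100 ms, rounded to a 10-ms grid and clipped to 400–1500 ms — a
documented stand-in, since only the centering of the individualized
distributions is specified by the protocol.

## Offline analysis

Records are highpass-filtered at 1 Hz with a zero-phase 4th-order
Butterworth (forward–backward), then decimated 2048 → 512 Hz with an
anti-aliasing FIR; events are remapped to the new rate. Training
epochs span −3 to 30 s around modulation onset (half-open sample
windows, 0-based; out-of-range events are dropped and counted) and are
cut into 33 non-overlapping 1-s sub-epochs for artifact screening.
Four rejection criteria flag a sub-epoch: (a) any |sample| > 100 μV;
(b) mean negative log-likelihood under a Gaussian fit to the pooled
amplitude distribution more than 5 SD above the across-epoch mean;
(c) |least-squares slope| > 75 μV across the epoch AND fit R² > 0.3
(conjunctive — both numbers must be exceeded); (d) sample kurtosis more
than 5 SD above the across-epoch mean. Distribution-based criteria
(b, d) need at least 8 epochs and nonzero variance, else they are
skipped with a warning. On clean Gaussian epochs the false-positive
rate stays below 5%.

Band power uses Welch with 1-s Hann windows at 50% overlap, no
detrending; the band statistic is the mean PSD over 4–7 Hz bins
(matching the online engine) or the band integral (rectangular bin
sum, which preserves a sinusoid's a²/2 exactly). Task power is
expressed as 10·log10(task/baseline) dB against the pre-trial baseline
(−3–0 s for training, −1–0 s for the shooting task). Retention
percentages are kept/total rounded half-up to two decimals.

## Multilevel statistics

Block- or condition-level outcomes nest within subjects. Models follow
a four-step ladder — intercepts-only; + level-1 predictors (Block and
Modulation for training, Condition for the task); + Session and its
interactions with the level-1 terms; full model adding Group and the
cross-level interactions with a random Session slope — estimated by
REML through statsmodels' linear mixed models. Coding: Group INC = 0 /
ALT = 1, Modulation Down = 0 / Up = 1, Condition Low = 0 / High = 1;
Session and Block enter uncentered at their 1-based values. Reported
per model: fixed effects with Wald-z p-values; variance components;
ICC = τ₀/(τ₀ + σ²); the design effect 1 + (n − 1)·ICC with n defaulting
to the observations per subject (30 for the training table, 12 for the
task tables); AIC/BIC computed from the REML log-likelihood with
k = fixed + variance parameters (the mixed-model results object does
not expose them directly); a fixed-effects pseudo-R² =
var(Xβ̂)/var(y); and simple slopes b_focal + b_interaction·g with
delta-method standard errors. Singular random-slope fits fall back to
a random intercept with the slope variance floored at zero and the
convergence flag cleared; boundary fits cascade through several
optimizers because a zero-variance solution can make a single
optimizer's inner solve singular.

Assumption screens mirror standard practice: subject-mean outliers
beyond 2 SD, outcome skewness/kurtosis flagged outside ±3, VIF per
fixed-effect column, and marginal-residual summaries for QQ and
homoscedasticity plots. A subject is a responder if the univariate
regression of theta on session OR on modulation code is significant at
α = 0.05 two-sided; under pure noise the union of the two screens
flags ≲10% of subjects.

## Synthetic cohort and what it shows

The statistics stage runs on a block-level outcome table drawn
directly from each subject's trend model (`simulate_cohort_outcomes`),
not on 2048-Hz waveforms: y = u_i + (trend_i + v_i)(s−1) +
block_trend_i(b−1) ± m/2 + e. Defaults encode the qualitative training
pattern: ALT session trend +0.32 dB/session with a +0.06 dB/block
block trend, INC flat; up-vs-down modulation effect m = 0.10 dB
(small, matching the near-null realized separation); between-subject
intercept SD 2.5 dB and residual SD 1.35 dB, which put the
intercepts-only ICC near 0.78 for a strongly clustered repeated
measure; individual slope SD 0.10 dB/session, about a third of the
group contrast, so the group-level pattern rather than individual
heterogeneity dominates at the 30-subject scale — the regime in which
the Group × Session effect is detectable at the 2-SE level in ≥80% of
replicates. Shooting-task practice trends lower the psychometric
thresholds (faster for INC than ALT), commission probability and
median RT linearly across sessions, reproducing the direction of the
behavioral session effects.

Behavioral clustering comes from per-subject parameter draws around
the config centers (deterministic in the master seed): tet50 SD 75 ms
and psychometric width SD 50 ms; commission probability SD 0.05;
median RT SD 30 ms plus a per-session day-state RT shift (SD 40 ms —
without it, session-mean RTs over ~300 trials are unrealistically
stable and the RT ICC saturates); and a one-off thresholding
estimation error (SD 60 ms) carried by each subject's schedule for the
whole study. The last term is what leaves a small but nonzero accuracy
ICC: individualized exposure times are designed to equalize hit rates
across subjects, so only threshold miscalibration survives as
between-subject accuracy variance. The spreads were set from the
between/within decomposition implied by the intended total SDs and
ICCs of each outcome and then fixed. At the full 30-subject scale the
simulated intercepts-only ICCs fall near 0.8 (training theta), 0.77
(task theta), 0.30 (commission), ~0.01–0.1 (accuracy) and 0.39 (RT) —
strong clustering for the EEG measures, weak for accuracy, in the same
order and regime the analysis stage expects.

The waveform lane (full EEG → online engine → offline analysis) runs
by default for one subject per group over two sessions inside
`run_study`; simulating all 30 subjects' five 1440-s sessions at
2048 Hz is supported but costs tens of minutes, and the block-level
generator is the appropriate scale for the statistical stage. Passing
tests on this cohort shows that the pipeline recovers the structure it
assumes — calibrated band powers, psychometric thresholds, variance
components, cross-level interactions — not that real EEG satisfies
those assumptions: real recordings have nonstationary spectra,
correlated artifacts, imperfect compliance and drifting electrode
impedances that the generator deliberately omits (single channel, no
volume conduction, no ocular/cardiac physiology).

## Numerical conventions

Half-open epoch windows, 0-based sample indexing; periodic Hann
tapers; no detrending anywhere in the spectral path; dB floor −60;
ties at 0 dB count as not achieved; retention rounded half-up;
rejection z-scores use population SD; EDF export is 16-bit with 1-s
records and the physical range written exactly as printed in the
header so round-trips are quantization-exact. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`
spawn-key splitting.
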