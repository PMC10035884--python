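"""Go-NoGo shooting task: thresholding, schedules, scoring.

Runs the psychophysical method of limits on a virtual shooter to find
its 50% and 90% hit-rate exposure times, generates High- and Low-stress
target schedules from those thresholds, simulates the task and prints
the behavioral metrics the study analyzes.
"""

from fmtheta import shooting, synth
from fmtheta.types import SubjectParams

params = SubjectParams(subject_id="S01", group="INC", down_gain=1.0,
                       tet50_ms=750.0, tet90_ms=1100.0, commission_prob=0.3)

# method of limits: 10 trials at each of 11 exposure times
responses = shooting.run_method_of_limits_series(params, seed=1)
thresh = shooting.method_of_limits(responses)
print(f"recovered thresholds: TET50 {thresh.tet50_ms:.0f} ms, "
      f"TET90 {thresh.tet90_ms:.0f} ms (true 750 / 1100)")

for condition in ("High", "Low"):
    schedule = shooting.generate_target_schedule(
        condition, thresh.tet50_ms, thresh.tet90_ms, seed=7)
    trials = synth.simulate_shooter(params, schedule, seed=11)
    m = shooting.compute_behavioral_metrics(trials)
    score = shooting.score_events(trials)
    print(f"{condition:>4} stress: hit {m['hit_pct']:.1f}%, "
          f"commission {m['commission_pct']:.1f}%, "
          f"RT {m['mean_rt_ms']:.0f} ms, score {score}")

# High stress exposes targets near TET50 (hit rate ~50%), Low stress
# near TET90 (~90%); commission errors fire at the rare friendly targets.
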