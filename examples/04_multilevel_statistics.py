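"""Multilevel trend analysis of a synthetic cohort.

Generates the block-level theta outcome table for a 12 INC + 18 ALT
cohort in which only the ALT arm trends upward across sessions, fits
the four-step model ladder, and reports ICC, design effect and the
Group x Session simple slopes.
"""

from fmtheta import stats, synth
from fmtheta.types import SubjectParams

subjects = [SubjectParams(subject_id=f"INC{i:02d}", group="INC", down_gain=1.0)
            for i in range(12)]
subjects += [SubjectParams(subject_id=f"ALT{i:02d}", group="ALT",
                           session_trend=0.32, block_trend=0.06)
             for i in range(18)]
table = synth.simulate_cohort_outcomes(subjects, seed=42)
print(f"long table: {len(table)} rows "
      f"({table.subject.nunique()} subjects x 5 sessions x 6 blocks)")

ladder = stats.model_ladder(table, "y", ["block", "modulation"])
null = ladder["intercepts_only"]
print(f"intercepts-only: ICC {null.icc:.2f}, "
      f"design effect {stats.design_effect(null.icc, 30):.2f}, "
      f"AIC {null.aic:.1f}")

# targeted cross-level interaction model for the training-effect test
spec = stats.ModelSpec(
    outcome="y",
    fixed=("block", "modulation", "session", "group", "group:session"),
    random_session_slope=True,
)
res = stats.fit_mlm(table, spec)
b, se = res.params["group:session"], res.bse["group:session"]
print(f"Group x Session: b = {b:.3f} (SE {se:.3f}), "
      f"p = {res.pvalues['group:session']:.4f}")

for s in stats.simple_slopes(res):
    grp = "ALT" if s.moderator_level == 1 else "INC"
    print(f"  session slope, {grp}: b = {s.slope:+.3f} (SE {s.se:.3f}), p = {s.p:.3f}")

responders = stats.classify_responders(table)
print(f"responders (session or modulation predicts theta): "
      f"{int(responders.sum())}/{len(responders)}")

# A design effect far above 2 confirms the clustered structure; the
# positive Group x Session coefficient with an ALT-only positive simple
# slope is the cohort's generative training pattern recovered by REML.
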