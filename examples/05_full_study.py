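"""The whole study in one call.

run_study simulates the full design — study plan, neurofeedback outcome
table, six shooting-task sessions in both time-stress conditions, a
raw-EEG waveform lane through the online and offline stages, and the
multilevel model ladder for all five outcomes — deterministically from
one master seed, writing plain CSV/JSON outputs.
"""

import json

import pandas as pd

from fmtheta import pipeline

outputs = pipeline.run_study(dict(
    master_seed=42,
    out_dir="scratch/full_study",
    n_inc=4, n_alt=6,          # reduced cohort keeps this demo quick
    n_sh_sessions=3,
    waveform_subjects_per_group=1,
    waveform_sessions=2,
))

nf = pd.read_csv(outputs.nf_table)
sh = pd.read_csv(outputs.sh_table)
print(f"NF table: {len(nf)} rows; SH table: {len(sh)} rows")

reports = json.loads(outputs.model_reports.read_text())
for outcome, ladder in reports.items():
    icc = ladder["intercepts_only"]["icc"]
    deff = ladder["intercepts_only"]["design_effect"]
    print(f"{outcome:>16}: ICC {icc:.2f}, design effect {deff:.2f}")

if outputs.retention_report:
    print("waveform-lane retention:", outputs.retention_report.read_text().strip())
print("outputs in", outputs.out_dir)

# Re-running with the same master seed reproduces every table byte for
# byte; the per-outcome ICCs show which measures are strongly clustered
# within subjects.
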