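"""Simulate a small two-group EEG/ECG cohort and write it to disk.

Each subject gets an EDF recording (scalp channels + ECG), a BIDS-style
events table for the cue -> emotional face task, and a ground-truth JSON
with the injected component amplitudes and true R-peak train.
"""

import json
import tempfile
from pathlib import Path

from heplpp import SimConfig, simulate_cohort

config = SimConfig(
    n_per_group=2,          # 2 MDD-like + 2 HC-like subjects
    n_trials=12,            # 4 per emotion condition
    channels=("F3", "Fz", "F4", "FC1", "FC2", "Cz", "C4", "CP4", "CP6"),
)

outdir = Path(tempfile.mkdtemp()) / "cohort"
manifest_path = simulate_cohort(config, seed=7, outdir=outdir)
manifest = json.loads(manifest_path.read_text())

print(f"cohort written to {outdir}")
print(f"config hash: {manifest['config_hash'][:16]}...  (identical config+seed -> identical bytes)")
for sub in manifest["subjects"]:
    truth = json.loads((outdir / sub["truth"]).read_text())
    print(
        f"  {sub['subject_id']}: group={sub['group']}  "
        f"heart rate {truth['hr_mean_bpm']:.1f} bpm, "
        f"true HEP amplitude {truth['hep_amp_uv']:.2f} uV"
    )
print(
    "\nThe HC-like group carries a ~2 uV heartbeat-evoked potential on the "
    "frontocentral channels;\nthe MDD-like group's is attenuated (~0.8 uV), "
    "which downstream cluster tests should recover."
)
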