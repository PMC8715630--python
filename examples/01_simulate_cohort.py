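"""Generate a small synthetic cohort and inspect its ground truth.

Each patient carries a latent impairment z in [0, 1] that drives both the
clinical scores (monotone links + noise) and the movement quality of every
generated task recording.
"""

import numpy as np

from robokin import SimConfig, simulate_cohort

cfg = SimConfig(n_patients=10, sessions_per_patient=2, seed=42, n_reaches=8)
recordings, score_rows, truth = simulate_cohort(cfg)

print(f"{len(recordings)} recordings, {len(score_rows)} session score rows")
first = score_rows[0]
z = truth.z[(first.patient_id, first.session_label)]
print(f"{first.patient_id}/{first.session_label}: impairment z = {z:.2f}")
print(f"  observed scores: {first.scores.as_dict()}")
print(f"  noise-free:      {truth.noise_free_scores[(first.patient_id, first.session_label)]}")

# more impaired patients fragment their reaches into more submovements
counts = {}
for (pid, sess, device, task, seg), subs in truth.submovements.items():
    if task == "reach8":
        counts.setdefault((pid, sess), []).append(len(subs))
zs = [truth.z[k] for k in counts]
means = [np.mean(v) for v in counts.values()]
r = np.corrcoef(zs, means)[0, 1]
print(f"corr(z, mean submovements per reach) = {r:.2f}  (positive: impairment fragments movement)")
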