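"""Estimate lumbar moment from wearable channels, with and without insoles.

Generates a small cohort (4 participants x 12 tasks), trains
gradient-boosted regressors under leave-one-participant-out cross-validation
for the trunk-IMU-only and trunk+insole conditions, and compares how well
each condition's held-out PEAK moment predictions track the lab truth.
"""

import numpy as np
from scipy import stats

import liftrisk as lr
from liftrisk import estimate

profiles = lr.sample_participants(4, seed=5)
tasks = lr.build_task_grid(n_masses=3, n_heights=4)
trials, _ = lr.generate_dataset(profiles, tasks, seed=5)

predictions = {
    cond: estimate.lopo_cross_validate(trials, cond, seed=5)
    for cond in estimate.CONDITIONS
}
lookup = lr.build_lookup(trials, profiles, predictions)

print("held-out peak lumbar moment accuracy, per participant:")
for pid, g in lookup.groupby("participant_id"):
    r_trunk = stats.pearsonr(g.peak_lumbar_trunk, g.peak_lumbar_lab).statistic
    r_tf = stats.pearsonr(g.peak_lumbar_trunkforce, g.peak_lumbar_lab).statistic
    mae_trunk = np.mean(np.abs(g.peak_lumbar_trunk - g.peak_lumbar_lab))
    mae_tf = np.mean(np.abs(g.peak_lumbar_trunkforce - g.peak_lumbar_lab))
    print(
        f"  P{pid}: trunk r = {r_trunk:.3f} (MAE {mae_trunk:5.1f} Nm)   "
        f"trunk+force r = {r_tf:.3f} (MAE {mae_tf:5.1f} Nm)"
    )

print("\nTrunk channels never see box mass, so the trunk-only model predicts")
print("the same moment for a 5 kg and a 23 kg lift from the same shelf;")
print("the under-foot force channels carry the missing weight information.")
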