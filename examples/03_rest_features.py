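"""Resting-state spectral features of fast vs slow voxels.

Computes the four features — slope below 0.2 Hz, aperiodic exponent, ALFF,
fALFF — from two synthetic resting runs and compares the fast and slow HRF
classes with Wilcoxon rank-sum tests.
"""

import numpy as np

from hemospec import SyntheticConfig, build_feature_table, compare_groups, generate_subject

config = SyntheticConfig(n_per_class=60, seed=13, n_task_runs=1, n_bh_runs=1)
subject = generate_subject(config)
table = build_feature_table(subject.rest_runs)
labels = subject.truth.label.to_numpy()

print(f"{'feature':<22}{'fast mean':>12}{'slow mean':>12}{'rank-sum p':>14}")
for feat in ("slope", "aperiodic_exponent", "alff", "falff"):
    fast = table.loc[labels == "fast", feat].mean()
    slow = table.loc[labels == "slow", feat].mean()
    _, p = compare_groups(table, labels, feat)
    print(f"{feat:<22}{fast:>12.4f}{slow:>12.4f}{p:>14.2e}")

print(
    "\nFast voxels decay less steeply (shallower slope, smaller exponent) and"
    "\ncarry less low-frequency power (lower ALFF). fALFF — the low-band to"
    "\nwide-band ratio — is closer to 1 for the flatter fast spectra."
)
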