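"""Map breath-hold vascular latency and compare hemodynamic classes.

Builds the breath-hold regressor (boxcar over the holds convolved with a
sign-reversed canonical response), forms the global reference from voxels
correlating above r=0.25, and finds each voxel's latency as the lag of
maximum cross-correlation on a 100 ms grid.
"""

from hemospec import SyntheticConfig, generate_subject, make_bh_regressor
from hemospec.breathhold import latency_map

config = SyntheticConfig(n_per_class=40, seed=5)
subject = generate_subject(config)

regressor = make_bh_regressor(config.bh_schedule, config.tr)
table = latency_map(subject.bh_runs[0], regressor)
table["label"] = subject.truth.label.to_numpy()
table["latency_true"] = subject.truth.vascular_latency_true.to_numpy()

print(f"included voxels (r > 0.25 with regressor): {(table.r > 0.25).mean():.0%}")
print("\ngroup-mean latency (s), estimated vs generative:")
print(table.groupby("label")[["latency_s", "latency_true"]].mean().round(2))
print(
    "\nLatency is relative to the global reference (its mean sits near zero);"
    "\nwith latency coupled to class, the ordering LGN < fast < slow appears."
)
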