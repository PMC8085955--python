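"""Generate a synthetic technician session log with ground-truth labels.

The generator emulates a multi-herbarium digitization project: each
technician accumulates experience on barcoding, imaging and skeletal
databasing, and their session rates follow the task's experience curve
plus multiplicative noise.  Anomalies (setbacks, swapped fields, extreme
outliers, unreliable reporters) are injected at configurable rates and
every entry carries a label saying what it is.
"""

from digilabor import GeneratorConfig, generate_sessions

config = GeneratorConfig(n_technicians=40, seed=11)
sessions, labels = generate_sessions(config)

print(f"{len(sessions)} session reports from {config.n_technicians} technicians")
print("\nFirst three rows:")
print(sessions.head(3).to_string(index=False))
print("\nGround-truth label counts:")
print(labels["label"].value_counts().to_string())
print(
    "\nEach count is the number of injected entries of that kind; the "
    "cleaning stage should recover exactly these partitions."
)
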