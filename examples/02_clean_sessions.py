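"""Apply the five-stage cleaning procedure and audit what it removes.

Stages run in order: manually flagged reporters, atypical-workflow
entries, swapped-field entry errors (rate so low the inverse ratio is a
typical rate), non-whitelisted setback descriptions, then 5-SD numeric
outliers.  The audit reports how many entries and labor hours each
category removes — on real projects this cleaning can discard a third of
reported hours.
"""

from digilabor import GeneratorConfig, clean_sessions, generate_sessions
from digilabor.pipeline import PipelineConfig, _cleaning_config_with_labels

sessions, labels = generate_sessions(GeneratorConfig(n_technicians=40, seed=11))

# ground-truth labels stand in for the human investigation that flags
# unreliable reporters and atypical workflows on real data
config = _cleaning_config_with_labels(PipelineConfig(), labels, sessions)
outcome = clean_sessions(sessions, config)

print("Cleaning audit (entries and labor hours per category):")
print(outcome.audit.to_string(index=False))

removed = outcome.audit.loc[outcome.audit["category"] != "kept", "hours"].sum()
total = sessions["minutes"].sum() / 60
print(
    f"\nCleaning removed {removed:.0f} of {total:.0f} reported hours "
    f"({removed / total:.0%}); the kept partition feeds the rate analysis."
)
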