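"""Fit experience-dependent rate curves from cleaned session reports.

Each technician's cumulative hours on each task are accumulated over
their date-sorted sessions; session rates (specimens/minute) are pooled
into shared two-hour experience bins below a 64-hour threshold, and the
per-bin mean rates are fit by least squares — a line for the improving
tasks, a concave quadratic for barcoding.
"""

from digilabor import CANONICAL_MODELS, GeneratorConfig, clean_sessions, generate_sessions
from digilabor.experience import bin_by_experience, cumulative_task_hours, fit_all_tasks
from digilabor.pipeline import PipelineConfig, _cleaning_config_with_labels

sessions, labels = generate_sessions(GeneratorConfig(seed=11))
outcome = clean_sessions(
    sessions, _cleaning_config_with_labels(PipelineConfig(), labels, sessions)
)

records = cumulative_task_hours(outcome.kept)
bins = bin_by_experience(records)
models = fit_all_tasks(bins)

print("Experience bins per task:")
print(bins.groupby("task")["n_entries"].agg(["count", "sum"]).to_string())
print("\nFitted curves (specimens/minute vs cumulative hours x):")
for task, model in models.items():
    c = model.coefficients
    poly = " + ".join(f"{v:.5f}*x^{p}" if p else f"{v:.5f}" for p, v in enumerate(c))
    ref = CANONICAL_MODELS[task].coefficients
    print(f"  {task:20s} {poly}   (generating curve intercept {ref[0]:.5f})")
print(
    "\nPositive slopes mean technicians speed up with practice; the "
    "negative quadratic term means barcoding peaks and then declines."
)
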