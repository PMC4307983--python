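"""Quantifying transient bimodality in a single-cell time course.

Generates a synthetic mixed-sugar experiment (0.1% glucose + 0.1%
galactose, robot cadence) and runs the quantification pipeline: per-event
normalization, Gaussian-mixture modality calls, subpopulation tracking and
the timing metrics.  The printed numbers are compared with the generator's
analytic ground truth.
"""

from galswitch import PipelineConfig, SyntheticConfig, generate_experiment, run_pipeline

cfg = SyntheticConfig(seed=42, events_per_sample=2000)
exp = generate_experiment(cfg)
report = run_pipeline(PipelineConfig(events=exp.events, seed=42))
m = report.metrics.iloc[0]

print(f"glucose depletion (truth):   {exp.truth['t_depletion']:.2f} h")
print(f"delta_a  estimate / truth:   {m['delta_a_h']:.2f} / {exp.truth['delta_a_true']:.2f} h")
print(f"delta_g  estimate / truth:   {m['delta_g_h']:.2f} / {exp.truth['delta_g_true']:.2f} h")
print(f"F_ON-mid estimate / truth:   {m['f_on_mid']:.3f} / {exp.truth['f_on_mid_true']:.3f}")
print(f"response time (F_ON = 0.5):  {m['response_time_h']:.2f} h")
print()
print("delta_a is when the early-activated cohort reaches half-max")
print("expression; delta_g is how long the two subpopulations coexist —")
print("it tracks the time glucose needs to fall to the bifurcation point.")
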