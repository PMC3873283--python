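"""A small in-silico multi-grader study: manual splines vs guided tracing.

Simulates several graders annotating noisy phantoms with both methods and
compares the inter-grader reproducibility (mean per-column absolute
boundary difference across grader pairs, in micrometres) per layer, plus
the paired Wilcoxon test between the arms. The guided method's boundaries
are deterministic given the picks, so its inter-grader spread collapses
toward zero while the manual splines inherit each grader's seed jitter.

A reduced study size keeps this example quick; `octseg simulate` runs the
full configuration from the shell.
"""

from octseg.study import run_insilico_study

result = run_insilico_study(seed=42, n_phantoms=4, n_graders=3)

print("inter-grader reproducibility (um), 4 phantoms x 3 graders:\n")
comparison = result.comparison()
print(
    comparison[
        ["layer", "manual_mean_um", "edgeselect_mean_um", "p_value"]
    ].to_string(index=False, float_format=lambda v: f"{v:.4f}")
)
print(
    "\nagreement |manual - guided| of grader-mean locations (um):",
    {l: round(a.mean_um, 2) for l, a in result.agreement.per_layer.items()},
)
print(
    "\nLower is better: the guided arm reproduces boundaries near-identically "
    "across graders,\nwhile manual spline annotation varies by roughly the "
    "seed-placement jitter."
)
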