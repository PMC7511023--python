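"""Validate the counting pipeline on synthetic wallpaper images.

Generates 11 binary wallpapers of axis-aligned squares/rectangles with
exactly known septal density (VVsep) and mean linear intercept (Lm),
samples 20 random 680x680 fields from each, counts them, and compares
computed vs theoretical values by regression and Bland-Altman analysis.
"""

from alveomorph import run_validation_experiment

report = run_validation_experiment(n_images=11, fields_per_image=20, seed=1)

print(report.per_image.to_string(index=False, float_format="%.4f"))
print()
for name, res in (("VVsep", report.vv_sep), ("Lm", report.lm)):
    reg, ba = res.regression, res.bland_altman
    print(
        f"{name:5s}  R^2 = {reg.r_squared:.4f}   "
        f"y = {reg.slope:.4f} x + {reg.intercept:.4g}   "
        f"bias = {ba.bias:+.2f}%  (LoA {ba.loa_low:+.1f}% .. {ba.loa_high:+.1f}%)"
    )
print()
print(
    "R^2 near 1 and a slope near 1 mean the pipeline tracks the exact\n"
    "geometric truth across densities; the Bland-Altman bias is the mean\n"
    "relative error of the estimate (negative = underestimation)."
)
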