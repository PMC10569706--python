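"""Practical identifiability of 2T5P microparameters on the study design.

Asks: with the three-session framing and count-statistics noise, how well can
(v_b, K1, k2, k3, k4) be recovered?  Prints normalized sensitivities at the
session ends, the strongest parameter correlations, and Monte-Carlo
bias/SD/RMSE from 100 noisy replicates.
"""
import numpy as np

from petkin import (
    ModelSpec,
    REGION_ARCHETYPES,
    correlation_matrix,
    generate_blood,
    make_study_schedule,
    normalized_sensitivity,
    simulate_bias_sd,
)
from petkin.compartments import frame_weights

schedule = make_study_schedule()
blood = generate_blood()
params = REGION_ARCHETYPES["bone_marrow"]

sens = normalized_sensitivity(params, blood, schedule, model="2T5P")
print("normalized sensitivity |S| at 90 min / 6 h / 48 h:")
for name, s in sens.items():
    print(f"  {name:>3s}: {abs(s[45]):6.3f} / {abs(s[46]):6.3f} / {abs(s[47]):6.3f}")

corr = correlation_matrix(params, blood, schedule, frame_weights(schedule), model="2T5P")
i, j = np.unravel_index(np.argmax(np.abs(corr.matrix - np.eye(5))), corr.matrix.shape)
print(f"\nstrongest correlation: corr({corr.param_names[i]}, {corr.param_names[j]})"
      f" = {corr.matrix[i, j]:+.3f}")

report = simulate_bias_sd(params, blood, schedule, ModelSpec(model="2T5P"),
                          noise_scale=0.05, n_reps=100, seed=17)
print(f"\nMonte-Carlo over {report.n_reps} noisy replicates (noise scale "
      f"{report.noise_scale}):")
for k, name in enumerate(report.param_names):
    print(f"  {name:>3s}: bias {report.bias_pct[k]:+6.2f}%  "
          f"SD {report.sd_pct[k]:6.2f}%  RMSE {report.rmse_pct[k]:6.2f}%")
print()
print("Growing late-time sensitivity (especially for k4) is why the 48-h")
print("scan is needed; low bias means organ-level estimates are trustworthy.")
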