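"""Fit a DCE-MRI signal-time curve and derive its kinetic parameters.

Simulates one noisy liver ROI curve on the study schedule (4-s frames
to 30 min, 10-min frames to 90 min, injection at 2 min), normalizes the
baseline, fits the EMM and prints the wash-out rate plus the four
derived quantities.
"""

from hepamri import (AcquisitionSchedule, EMMParams, derive_parameters,
                     fit_emm, normalize_curve, simulate_dce_curve)

truth = EMMParams(A=57100, alpha=0.20, beta=0.037, gamma=0.001, q=0.432)
schedule = AcquisitionSchedule()

curve = simulate_dce_curve(truth, schedule, noise_sd=0.01, seed=1)
norm = normalize_curve(curve)
fit = fit_emm(norm)
d = derive_parameters(norm, fit.params)

print(f"fitted beta = {fit.params.beta:.4f} 1/min (truth {truth.beta})")
print(f"R^2         = {fit.r_squared:.4f} (quality gate 0.98)")
print(f"T_peak      = {d.t_peak:.2f} min;  C_max = {d.c_max:.0f} a.u.")
print(f"ES          = {d.es:.0f} a.u./min;  AUC = {d.auc:.4g} a.u.*min")
print(f"T_1/2       = {d.t_half:.1f} min (wash-out tail, 40-90 min)")
print()
print("Slower wash-out (smaller beta, longer T_1/2) signals impaired")
print("hepatocyte transport of the contrast agent.")
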