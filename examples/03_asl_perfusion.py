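"""Quantify liver perfusion from a FAIR-ASL inversion-recovery pair.

Builds a 64x64 liver phantom (parenchyma 245 ml/min/100 g, central
vessel pixels at 800), simulates selective/non-selective IR stacks at
the 10 study inversion times with 1% Rician noise, fits T1 per pixel,
computes the FAIR perfusion map, applies the [0, 500] threshold and
summarizes three parenchyma ROIs.
"""

from hepamri import (compute_perfusion_map, compute_t1_map,
                     make_liver_phantom, roi_summary, simulate_ir_pair,
                     threshold_map)

f_field, t1_field, vessel, rois = make_liver_phantom(
    shape=(64, 64), f_parenchyma=245.0, t1_ns=1249.0, f_vessel=800.0)
sel, ns = simulate_ir_pair(f_field, t1_field, noise_frac=0.01, seed=1)

t1_map = compute_t1_map(ns)
pmap = compute_perfusion_map(compute_t1_map(sel), t1_map, lambda_partition=0.9)
pmap = threshold_map(pmap, 0.0, 500.0)

perf = roi_summary(pmap, rois)
t1 = roi_summary(t1_map, rois)

print(f"ROI perfusion means: {[round(m, 1) for m in perf.means]} ml/min/100 g")
print(f"pooled perfusion   : {perf.pooled_mean:.1f} ml/min/100 g (truth 245)")
print(f"pooled T1 (non-sel): {t1.pooled_mean:.0f} ms (truth 1249)")
print(f"vessel pixels rejected by threshold: "
      f"{int((~pmap.valid_mask & vessel).sum())} of {int(vessel.sum())}")
print()
print("The threshold removes the supra-physiological vessel pixels so the")
print("ROI statistics describe parenchymal microcirculation only.")
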