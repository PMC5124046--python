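# hepamri

Quantitative liver MRI analysis for small-animal hepatitis studies:
dynamic contrast-enhanced (DCE) MRI curve kinetics with a hepatocyte-
specific contrast agent, FAIR arterial-spin-labelling (ASL) perfusion
and T1 mapping, and the cohort statistics that compare a healthy
control group with concanavalin-A (ConA)-induced acute liver injury.

## Who this is for

Researchers analysing murine (or other small-animal) liver MRI in
models of acute liver failure, where two complementary readouts matter:
how fast the liver parenchyma takes up and clears a hepatobiliary
contrast agent such as Gd-EOB-DTPA (hepatocyte integrity), and how well
the parenchyma is perfused (microcirculation). The package also ships a
full synthetic-cohort generator, so every stage can be exercised,
tested and benchmarked without any scanner data.

## The models

**DCE arm.** The normalized liver signal after injection is fitted with
the five-parameter empirical mathematical model (EMM)

```
C(t) = A (1 - e^{-αt})^q e^{-βt} (1 + e^{-γt}) / 2
```

where *A* is the enhancement ceiling (a.u.), *α* the uptake rate
(1/min), *β* the wash-out rate (1/min), *γ* the initial wash-out rate
(1/min) and *q* a shape exponent. From each fit the pipeline derives
T_peak (argmax of the fitted model), C_max (maximum of the measured
signal), the enhancement slope ES = C_max/T_peak, the 0–90 min
trapezoidal AUC, and the elimination half-life T_1/2 = ln2/k from a
mono-exponential fit to the 40–90 min wash-out tail. Slower wash-out
(small *β*, long T_1/2, late T_peak) indicates impaired hepatocyte
transport.

**ASL arm.** Selective and non-selective inversion-recovery stacks are
fitted per pixel with the three-parameter model
`S(TI) = M0 (1 - B e^{-TI/T1})` (polarity restored first for magnitude
data), and perfusion follows the FAIR relation

```
f = 6000 · λ · (1/T1_sel - 1/T1_ns)        [R1 in 1/s, λ in ml/g]
```

in ml/min/100 g, with λ = 0.9 ml/g by default. Maps are thresholded to
[0, 500] ml/min/100 g to reject vessels and noise, then summarized over
three parenchyma ROIs.

**Statistics.** Per-parameter group comparisons are gated by
Shapiro-Wilk normality (t-test if both groups pass, otherwise
Mann-Whitney U with per-group rank sums), and associations between MRI,
histological and biochemical parameters use Spearman rank correlation.

## Worked example

`examples/03_asl_perfusion.py` builds a 64×64 liver phantom with
parenchyma at 245 ml/min/100 g and supra-threshold vessel pixels,
simulates the IR pair at 1% Rician noise, and runs the full ASL chain:

```
ROI perfusion means: [252.4, 254.7, 256.6] ml/min/100 g
pooled perfusion   : 254.6 ml/min/100 g (truth 245)
pooled T1 (non-sel): 1249 ms (truth 1249)
vessel pixels rejected by threshold: 40 of 40
```

The pooled ROI mean recovers the generative parenchyma perfusion to a
few percent at this noise level, T1 is recovered almost exactly, and
every vessel pixel is removed by the physiological threshold.
`examples/02_dce_fitting.py` does the same for the DCE arm
(`fitted beta = 0.0369 1/min (truth 0.037)`, R² = 0.994), and
`examples/04_cohort_statistics.py` runs the entire two-group pipeline
and prints the comparison table.

A thin CLI mirrors the library:
`hepamri simulate --seed 1 --out results/` runs the full synthetic
experiment; `hepamri analyze-dce curve.csv` fits a single measured
curve; `hepamri analyze-asl sel.nii ns.nii --roi roi.nii` quantifies a
measured IR pair.

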