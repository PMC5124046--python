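# Methods

## DCE arm

### Model and time origin

The enhancement model is the five-parameter EMM
`C(t) = A (1-e^{-αt})^q e^{-βt} (1+e^{-γt})/2` with `t` in minutes
after contrast injection, so `C(0) = 0` exactly. Curves carry times on
the acquisition clock; the fit shifts by the injection time (default
2 min after the first frame). Frames strictly before the injection
instant form the baseline; a frame landing exactly on the injection
instant is excluded from both baseline and fit to avoid bolus-arrival
contamination. Normalization subtracts the baseline mean from the whole
course and stores the offset so the step is exactly invertible.

### Acquisition schedule

Defaults reproduce the study protocol: three 10-min series of 150
frames (one frame per 4 s) covering 0–30 min, then one frame every
10 min to 90 min — 456 frames in total, injection at 2 min.

### Fitting

Trust-region bounded least squares (`scipy.optimize.least_squares`)
with bounds A ∈ (0, 10·max signal], α ∈ (0, 5], β ∈ [0, 1],
γ ∈ [0, 1], q ∈ (0, 5] (open bounds enforced with ε = 1e−9; the q cap
prevents degenerate plateaus — fitted values sit near 0.4).
Multi-start over α ∈ {0.05, 0.2, 1} × q ∈ {0.4, 1}, with
A₀ = 1.2·max signal, β₀ = ln2/(t_last − t_max), γ₀ = 0.

γ is weakly identified: for small γ the factor `(1+e^{-γt})/2` is
nearly `e^{-γt/2}`, so γ and β trade off, and the one-sided γ ≥ 0
bound converts symmetric noise into a systematic downward drift of β.
The fit is therefore run twice per start — γ free and γ pinned to 0 —
and the extra parameter is kept only when it reduces the residual sum
of squares enough to pay its AIC cost (n·ln(SSE₀/SSE₁) > 2). On
noiseless curves this always selects the full model and recovers all
five parameters to < 1e−4 relative error; at 1% noise it removes the
β drift (mean bias < 1% over 50 replicates at the healthy-group means)
at the price of absorbing a truly non-zero but undetectable γ into β
(≈ γ/2), which stays well inside the wash-out parameter's population
spread. R² below the 0.98 quality gate flags a fit but never discards
it.

### Derived parameters

* **T_peak**: argmax of the *fitted* model, found as the root of
  d(log C)/dt by Brent bracketing on [1e−6, 90] min. The log-derivative
  is strictly decreasing from +∞, so the root is unique; a curve still
  rising at 90 min (β = γ = 0) raises a "no finite peak" error. For
  γ = 0 the closed form (1/α)·ln(1 + qα/β) is used as a test oracle.
* **C_max**: maximum of the measured normalized signal (earliest sample
  on ties) — deliberately data-side, not model-side.
* **ES** = C_max/T_peak.
* **AUC**: trapezoid on the measured normalized samples from injection
  to min(90 min, last sample); no extrapolation or interpolation.
* **T_1/2**: ln2/k from a log-linear least-squares mono-exponential fit
  to the measured samples ≥ 30 min after injection (the slow phase,
  safely past the peak in both groups). Requires ≥ 3 positive samples
  and a positive decay rate.

The half-life of a pure EMM tail is ≈ ln2/β (≈ 18.7 min at the healthy
group's β), whereas in-vivo wash-out tails are reported around
31.7 min: real clearance deviates from the single-exponential EMM tail.
The pipeline reports both β and T_1/2 and makes no attempt to reconcile
them.

## ASL arm

### IR model and fitting

Per-pixel three-parameter inversion recovery
`S(TI) = M0 (1 − B e^{−TI/T1})`. B is fitted rather than fixed at 2
because a finite repetition time leaves magnetization incompletely
recovered at liver-like T1. For magnitude data, polarity is restored by
locating the minimum-magnitude TI, negating earlier samples, and also
trying the null point shifted ±1 sample; the lowest-residual candidate
wins.

The solver uses variable projection: for fixed T1 the model is linear
in (M0, M0·B), so the per-pixel problem reduces to a 1-D search over
T1. A shared 128-point log grid on [50, 5000] ms is scanned for all
pixels at once, followed by three per-pixel zoom rounds and a final
parabolic refinement — fully vectorized, ~1 s for a 64×64 stack pair,
and exact to < 0.01% on noiseless data. Pixels are flagged invalid
(never interpolated) when T1 leaves (50, 5000) ms, M0 ≤ 0, B leaves
[1, 2.2], or the trace is constant. A generic scipy nonlinear fit
serves as the independent cross-check in the tests.

### Perfusion quantification

`f = 6000·λ·(1/T1_sel − 1/T1_ns)` with R1 in 1/s (equivalently
6×10⁶·λ·ΔR1 with T1 in ms), λ default 0.9 ml/g, configurable. The
vendor macro used in the original acquisition does not publish its
formula; this is the standard FAIR/Detre apparent-T1 relation, chosen
because it is invertible and self-consistent with the generator, which
derives the selective T1 by inverting the same relation. Absolute
scale therefore rests on this convention. Maps are computed per pixel
with no spatial smoothing (map-then-ROI order); thresholding to
[0, 500] ml/min/100 g only edits the validity mask — surviving values
are bit-identical. ROI summaries weight ROIs equally (mean of ROI
means).

## Synthetic cohorts

The generator emulates the study conditions: two groups of 7 animals,
EMM parameters, perfusion and non-selective T1 drawn from truncated
normal populations at the published group means/SDs (truncation at the
model invariant bounds, with an error if a spec would reject > 50% of
draws); DCE curves on the real schedule with additive Gaussian noise of
SD 1% of A on the ROI mean (ROI averaging over ~137 pixels makes the
mean near-Gaussian; the within-animal noise level is a default, not an
inference) plus a constant pre-contrast offset (5% of A) so baseline
normalization is genuinely exercised; IR stacks with Rician noise of
1% of M0 per pixel and a central cluster of vessel pixels at
800 ml/min/100 g to exercise the threshold. The 10 inversion times span
50–4500 ms with linear spacing (the spacing used in the original
acquisition is not stated).

Covariates are tied to an injury scale u = (z(1/β) + z(T1))/2 computed
over the pooled cohort: ALT and AST follow log-linear links anchored so
the group levels land near the published medians (control ≈ 38/61 U/l,
injured ≈ 1600/2000 U/l), and histology scores are clipped monotone
maps of u. The links are monotone by construction — they give the
Spearman stage real signal but claim no mechanism.

What the phantoms do **not** emulate: respiratory motion, self-gated
reconstruction, EPI distortion, transit-time effects, spatial
heterogeneity of parenchyma, or the conversion between signal and
gadolinium concentration. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not
robustness to scanner artefacts.

## Statistics

Normality is tested per group with Shapiro-Wilk (the gate requires both
groups to pass, the standard per-group reading); the parametric branch
is a two-sided equal-variance t-test (switchable to Welch), the
non-parametric branch Mann-Whitney U with mid-ranks, scipy's exact
p-value for tie-free samples of ≤ 8 per group and the tie-corrected
normal approximation otherwise. Ordinal variables (histology scores)
can bypass the gate via `force_test="mann-whitney"`. Rank sums over
both groups always total N(N+1)/2. Degenerate all-equal data reports
p = 1 with mid-rank sums. Spearman correlations use mid-ranks with
pairwise deletion (≥ 5 complete pairs required); no multiple-testing
correction is applied by default (per-test p at 0.05), with an optional
Holm-adjusted flag column.

## Problem sizes and determinism

The recovery experiments use 64×64 phantoms (4096 pixels), 7 curves per
group on the full 456-frame schedule, and 20 half-life replicates;
property suites use 100–1000 randomized draws. Every random quantity is
driven by explicit integer seeds (numpy `default_rng`); cohort animals
are reproducible from (cohort seed, animal index), and same-seed
pipeline runs write byte-identical data products.

## Known limitations

* Absolute perfusion scale depends on the chosen FAIR constant and λ.
* β inherits ≈ γ/2 when a small true γ is statistically undetectable.
* The mono-exponential T_1/2 is estimated from six slow-phase samples;
  its variance is correspondingly large at realistic noise.
* The corner-ROI phantom layout is deliberately simple; it does not
  model partial-volume mixing at vessel boundaries.
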