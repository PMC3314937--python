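# Methods

`tspopet` predicts, before any in vivo data exist, how well a TSPO PET
radioligand will perform in humans — and how the rs6971 polymorphism, which
splits the population into high- (HAB), mixed- (MAB) and low-affinity (LAB)
binders, degrades that performance in realistic study designs.  This note
records the model, its assumptions, the defaults, and what the simulations do
and do not show.

## The biomathematical model

**Brain entry.**  Passive blood–brain barrier permeability is predicted from
lipophilicity and molecular size,

    log10 P = −0.121 (clogD − 2.2982)² − 2.544 log10(Vx^{1/3}) − 2.525,

with `P` in cm·min⁻¹, `clogD` the computed pH 7.4 distribution coefficient and
`Vx` the McGowan characteristic volume (cm³·mol⁻¹/100).  The lipophilicity
term is a parabola (too polar and too lipophilic both penalise); permeability
falls monotonically with molecular size.  The influx rate constant follows
from the Renkin–Crone capillary extraction model,

    K1 = 3.43 · f (1 − e^{−PS/f}),

with perfusion `f = 0.6 mL·cm⁻³·min⁻¹`, capillary surface `S = 150 cm²·cm⁻³`,
and the 3.43 an empirical in vitro → in vivo scaling.  Efflux is tied to K1
through the free fractions,

    k2 = (V_aq_P / V_aq_T) · K1 · f_ND / f_P,

with apparent aqueous volumes 0.98 (plasma) and 0.9 (tissue).  The ratio
k2/K1 is therefore a closed form independent of permeability — a property the
test suite checks to machine precision.

**Binding.**  The binding potential of the non-displaceable compartment is
predicted per binding class:

    BP_ND = f_ND Bmax_H / Ki_H                      (HAB)
          = f_ND (Bmax_MH / Ki_H + Bmax_ML / Ki_L)  (MAB)
          = f_ND Bmax_L / Ki_L                      (LAB)

Inhibition constants stand in for dissociation constants throughout, and MABs
split their Bmax 50/50 between high- and low-affinity sites by default
(`mab_high_fraction`).  Disease is modelled as a uniform Bmax multiplier
(1.5 = moderate, schizophrenia-like; 5.0 = high, ALS-like) applied to every
class — inter-subject variation in the disease effect itself is deliberately
not modelled.

**Known numerical caveat.**  The packaged characterisation table stores the
printed two-decimal free fractions.  For the reference ligand 11C-(R)-PK11195
(f_ND printed as 0.01, evidently ~0.013 unrounded) and, mildly, for
11C-DPA713 (f_ND 0.12 vs ~0.124) the predicted BP_ND values are therefore a
few percent below the published ones; K1 and k2 are unaffected.  Tests
against these cells carry correspondingly wide or exempted tolerances.

## Simulation

**Input function.**  The original standard arterial input is unpublished, so
a synthetic tri-exponential with a linear bolus rise is used:

    C_P(t) = (A1 t − A2 − A3) e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t},

defaults (800, −4.0, 40, −0.5, 25, −0.05) in arbitrary activity units,
peaking near 0.35 min and cleared to <1% of peak by 90 min.  Whole blood is a
scalar multiple of plasma (default 1; no metabolite model).  This is safe for
the outcome of interest because BP_ND = V_T/V_ND − 1 is a ratio of two
distribution volumes estimated against the *same* input: its sensitivity to
the input shape largely cancels.  Absolute %COV values, by contrast, do
depend on the input/framing/noise details — see "calibration" below.

**TACs.**  The one-tissue compartment curves

    C_T(t)  = (1 − V_B) K1 e^{−k2 t/(1+BP_ND)} ⊛ C_P + V_B C_B
    C_ND(t) = (1 − V_B) K1 e^{−k2 t}           ⊛ C_P + V_B C_B

are evaluated by closed-form exponential algebra (`_expsum.py`): convolving a
sum of `(a + bt)e^{λt}` terms with an exponential kernel stays in that
family, and frame values are *exact* time-averages over each frame.  No
quadrature or ODE solver is involved; tests compare against adaptive
quadrature.  Blood volume is fixed at V_B = 5%, both in simulation and in
fitting.  Default framing: 6×10 s, 4×60 s, 4×120 s, 3×300 s, then 600 s
frames to 90 min (a trailing 120 s frame closes the schedule); any contiguous
schedule is accepted.

**Decay and noise.**  Frames are converted to non-decay-corrected activity
with the midpoint decay factor (half-lives 20.4 min for C-11, 109.77 min for
F-18).  Noise is zero-mean Gaussian per frame with variance

    ε² · (non-decay-corrected activity) / (frame duration),

added on the raw data and decay-corrected afterwards; negative noisy frames
are allowed, as in real ROI data.

**Calibration of ε.**  The noise scale is the one free parameter of the
simulator.  It is fixed once by anchoring the reference configuration —
PK11195, HAB, control — to %COV[BP_ND] = 36.2, and then held constant for
every ligand, class and disease state.  Because the %COV estimator is
heavy-tailed for the reference ligand, the frozen default (ε = 0.130) was
chosen so the anchor is met on average across Monte Carlo seeds at 1000
realizations (observed spread ≈ ±1.5 percentage points).
`calibrate_noise_scale` re-derives it.

## Estimation

The 1TCM is fitted to decay-corrected framed data by weighted least squares
with V_B fixed.  Weights are the inverse of the noise-rule variance, with the
raw-activity proxy taken from the observed frame (floored at 0.1% of its
maximum so empty early frames cannot dominate).  The model is linear in K1,
so K1 is profiled out in closed form and the fit reduces to a bounded 1-D
search over the apparent efflux constant (coarse 40-point log grid on
[10⁻⁶, 10] followed by Brent refinement); this is equivalent to the WLS
minimum of a 2-parameter bounded nonlinear least squares but has no
initialization failure modes.  A fit is flagged non-convergent when K1 pins
to a bound or the objective is degenerate; non-convergent realizations (and
V_ND ≤ 0) are excluded from Monte Carlo summaries with a recorded count, but
negative BP_ND estimates are retained to avoid truncation bias.

BP_ND is always derived as V_T/V_ND − 1 from separate fits to the total and
non-displaceable curves, and identifiability is summarised as
%COV[BP_ND] = 100·σ/μ over (by default) 1000 noisy realizations.

## Study power

Inter-subject variability uses truncated-at-zero normal factors with CVs of
10% (K1), 10% (k2, within-subject designs) or 20% (k2, between-subject), and
25% (Bmax within each class); truncations are counted (they are ~4σ events at
these CVs).  In every design, one simulated population is evaluated at both
the control and the elevated Bmax: a subject's K1/k2/Bmax draws are fixed
across disease states and only the measurement noise is re-drawn per scan.
This matches the "same population, healthy and diseased groups" construction
(visible in the published group SDs, where the diseased SD is exactly 1.5×
the control SD), keeps the class proportions identical across groups by
construction, and gives much lower Monte Carlo error on group differences
than independent cohorts would.  All group moments feeding the power
formulas come from the *estimated* BP_ND values.

Sample sizes are the smallest integers whose noncentral-t power reaches 0.90
at two-sided α = 0.05: a paired t-test for longitudinal designs, a Welch
two-sample t-test for class-stratified between-subject designs.  Mixed-class
cohorts (class unknown) use fixed class counts per ethnic group
(HAB:MAB:LAB = 49:42:9 Caucasians, 56:38:6 African Americans, 94:6:0.001 —
normalized by its own sum — Chinese/Japanese); since the mixture is
non-normal (tri-normal for high affinity-ratio ligands), the Welch sample
size is divided by a Pitman asymptotic relative efficiency to approximate a
Mann–Whitney U test.  The A.R.E. constant is configurable and defaults to
3/π ≈ 0.955, the Wilcoxon-vs-t value under normality; the mixture's true
A.R.E. is unknown, so mixed-population sample sizes are approximate by
construction.

## Problem sizes and reproducibility

Defaults match the study conditions: 1000 noisy realizations per
identifiability cell and 1000 subjects per simulated population.  The test
suite runs the identifiability grid at 200 realizations per cell (the
pattern claims it checks are stable well below 1000) and populations at the
full 1000.  Every simulation entry point takes an explicit seed; the CLI
derives per-command child seeds from one `--seed` and produces byte-identical
CSVs under a fixed seed.

## Limitations

* The synthetic input function, framing and noise scale are stand-ins for
  unpublished acquisition details; absolute %COV values and mixed-population
  sample sizes are therefore approximate, and only the anchored cell and the
  cross-ligand/cross-state patterns are quantitative claims.
* One-tissue kinetics, passive diffusion, fixed V_B, and Ki≈KD are modelling
  idealisations inherited from the prediction framework; no reference-region
  or two-tissue analysis is attempted.
* The generator emulates ROI-level counting statistics only — no scanner
  resolution, attenuation, motion, metabolite correction, or image
  reconstruction effects — so passing tests demonstrate internal consistency
  of the pipeline under its stated noise model, not scanner-level realism.
* Disease multipliers are uniform across classes and subjects; plasma free
  fraction differences between measurement techniques (dialysis vs
  ultrafiltration) propagate directly into k2 and BP_ND predictions.
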