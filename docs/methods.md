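# Methods

## The model

The package implements a deterministic ODE model of canonical NF-κB
activation in microglia under sustained TNFα. Fifteen species are tracked
in two compartments (units µM and minutes throughout; nuclear species are
concentrations per nuclear volume, and every cytoplasm↔nucleus flux
carries the cytoplasmic:nuclear volume ratio `kv` so that the NF-κB
moiety

    NFkB + IkBa·NFkB + pIkBa·NFkB + rIkBa·NFkB + uIkBa·NFkB
        + (NFkBn + IkBan·NFkBn)/kv

is a first integral, exact by construction of the reaction stoichiometry).

**IKK cycle.** IKK cycles through native → active → inactive → native
states. In the *new* model variant, TNF-gated activation is a Hill
function of native IKK,

    v_act = ka · TNF(t) · IKKn^h_a / (km_a^h_a + IKKn^h_a) · k_afb / (k_afb + A20),

spontaneous inactivation is a cooperative Hill function of active IKK,

    v_inact = ki · IKKa^h_i / (kmmi^h_i + IKKa^h_i),

A20 additionally inactivates active IKK by mass action
(`k_a20i · A20 · IKKa`), and recycling is first order (`kp · IKKi`). The
*legacy* variant uses linear activation/inactivation and places the A20
feedback on the recycling step instead
(`kp · IKKi · k_afb/(k_afb + A20)`).

**IκBα degradation chain.** Active IKK phosphorylates NF-κB-bound IκBα
(`kc1 · IKKa · IkBa·NFkB`). In the *four-step* variant the phosphorylated
complex is recognized by the E3 ligase (`kr`), polyubiquitinated (`ku`)
and degraded by the proteasome (`kd`), releasing NF-κB only at the final
step; in the *two-step* variant phosphorylation is followed directly by
degradation/release (`kd`). Free phosphorylated IκBα degrades in a single
lumped step (`kc2 · IKKa · IkBa`) — the intermediates matter for the
timing of NF-κB release, which flows through the bound pool. Basal
turnover: free IκBα at `c5a`, complexed at `c6a` (releasing NF-κB).

**Gene expression.** Nuclear NF-κB induces `ikba` and `a20` transcription
through a shared Hill function `NFkBn^h_t/(k_t^h_t + NFkBn^h_t)` with
maximal rates `c1a`/`c1`; transcripts decay (`c3a`/`c3`) and are
translated (`c4a`/`c4`); A20 protein decays at `c5`. There are no
constitutive (NF-κB-independent) production terms, so the empty state is
an exact fixed point of every variant.

**Transport.** NF-κB import/export (`ki1`/`ke1`), free IκBα
import/export (`ki3a`/`ke3a`), nuclear association at the same rate
constant as cytoplasmic (`ka1a`), and export of the nuclear
IκBα·NF-κB complex (`ke2a`).

The network is written symbolically (reaction list with rates and integer
stoichiometry) and compiled with sympy to the derivative function, the
analytic state Jacobian used by the stiff integrator, and the parameter
Jacobian used by the forward sensitivity equations. The same reaction
list drives the SBML Level 3 export (compartment sizes encode `kv`;
kinetic laws are amount fluxes).

## Nominal parameterization (synthetic stand-in)

Fitted rate constants for this microglial model family are not
redistributed with this package, and the underlying ELISA measurements
are available only as published figures, not as numbers.
The nominal parameter set in `model.DEFAULT_PARAMS` is therefore a
*synthetic stand-in*: values were chosen once, within the order-of-
magnitude ranges of the legacy two-feedback model lineage, so that the
simulated population-average dynamics reproduce the reported features of
TNFα-stimulated BV2 microglia:

* active IKK peaks near 4 min, falls to ~43 % of peak by 10 min and ~12 %
  by 30 min;
* nuclear NF-κB stays near basal through ~5 min (14.5 % of peak),
  peaks near 21 min, and shows a damped second phase near 95 min with an
  inter-peak trough of ~17 % of peak;
* total cellular IκBα falls below a quarter of its resting level by
  20 min and recovers later.

Two aspects deserve emphasis. First, the inter-peak trough and basal
level were deliberately kept at realistic population-average magnitudes
(not near zero): a switch-like transcription threshold (`k_t` far below
peak nuclear NF-κB) turns the feedback into a relaxation oscillator with
near-zero troughs, unlike measured bulk data, and it also pushes the
synthetic-noise model into its zero-truncation regime where the
consistency test's Gaussian assumption fails. Second, the parameter
values themselves should not be read as biological estimates — only the
dynamic shapes were matched.

Default bounds are ±2 decades around nominal for rate constants, [1, 6]
for Hill coefficients, with structural constants (`kv`, totals, `h_t`,
`k_t`) fixed. Upstream fits use the tighter literature-style ranges in
`estimation.UPSTREAM_BOUNDS` (minute-scale turnover, saturation constants
within the sub-µM operating range of the IKK pool).

## Simulation protocol

Equilibration starts from all NF-κB free and cytoplasmic, all IKK native,
everything else zero, with TNF = 0 (which makes the activation flux —
and hence active IKK — exactly zero), and integrates in growing chunks
until `max_i |dx_i/dt|/(|x_i|+ε) < 10⁻⁹ /min` (cap 10⁵ min). Negative
solver dust below 10⁻⁵ of the largest pool is zeroed at the protocol
boundary. The equilibrium seeds the stimulated run (TNF = 1 sustained).

Integration uses LSODA with the analytic Jacobian, rtol 10⁻⁸ and atol
10⁻¹⁰ µM by default; objective evaluations inside multistart fitting use
rtol 10⁻⁶/atol 10⁻⁹ plus a step cap (`mxstep = 4000`) so pathological
parameter draws fail fast into a finite penalty (10⁶) instead of
stalling the optimizer. Final reported simulations always use the tight
settings.

Loop breaking: `build_driven_model` removes either the IKK cycle
(downstream module, 12 species, active IKK supplied as an input) or
everything except the IKK cycle and A20 arm (upstream module, 5 species,
nuclear NF-κB supplied). Driven inputs are shape-preserving monotone
cubic Hermite (pchip) interpolants of their knots with a constant tail
beyond the last knot (default tail 5 % of the 5-min peak — the data are
only stated to remain "low" late, so the level is a convention exposed in
the config). Feeding a module its own closed-loop signal reproduces the
closed-loop solution to ≲0.05 % sup-norm.

## Synthetic data

`reference_profiles` encodes the reported dynamic features of each assay
on fixed canonical grids ({0,5,10,15,20,30} min for IKK,
{0,5,10,15,20,30,45,60,90,120} min for NF-κB): IKK normalized to 1.0 at
5 min, 0.33 at 10 min, basal (0.05, a convention) at 0 and 30 min; NF-κB
near basal through 5 min, 1.0 at 20 min, a smaller second peak (0.45) at
90 min, with a trough value (0.25 at 60 min) interpolated as a
convention. Non-anchor grid values come from a monotone pchip through
the anchors and are tagged `interpolated` in the metadata; every point
carries SD 0.1 (normalized units) and the assay's replication (n = 15
for NF-κB — five experiments in triplicate; n = 3 for IKK — three
experiments, one measurement each).

`generate_experiments` samples `value = truth(t) + N(0, sd(t)²)`,
truncated at zero, iid within and across experiments; the default noise
convention is `sd(t) = 0.05 + 0.05·truth(t)`. `normalize_experiment`
divides an experiment by the maximum over time of its per-time replicate
mean (removing per-experiment gain), and `ensemble_average` pools all
replicates per time point (mean, SD with n−1, n).

What the generator emulates — and what it does not: it reproduces the
replication structure, gain normalization, additive time-varying Gaussian
noise and non-negativity of plate-based population measurements. It does
not emulate assay chemistry (standards, absorbance saturation),
between-day biological drift, or single-cell heterogeneity; passing tests
therefore validate the statistical machinery under its stated
assumptions, not robustness to real-assay artifacts.

Calibration-grade null datasets are generated with unit gains and
*without* the per-experiment normalization step: with unit gains the step
is a no-op in intent, but dividing by a noise-dependent maximum biases
the exact null that the calibration property assumes (the effect is a few
percent at n = 3 replicates). The normalization operation itself is
tested for the property it exists to provide — scale invariance.

## Consistency testing

At each sampled time the replicates are compared with the simulated
population mean by a two-sided one-sample t-test (n−1 dof); the per-time
p-values combine as χ²_F = −2·Σ ln p_i, chi-square with 2n dof under the
shared null; the parameter set is rejected when the combined p-value
falls below α. p-values are floored at 10⁻³⁰⁰ before the log (logged
when it happens). Comparisons run on the normalized scale (NF-κB at
20 min, IKK at 5 min). The companion goodness-of-fit measure is the
plain sum of squared errors on the same scale. Under the exact null the
combined p-value is uniform: at 2000 replicates the rejection rate at
α = 0.05 sits inside the binomial 99 % interval and the KS distance from
uniformity is ≈0.01–0.02.

## Estimation

Bounded multistart local optimization: starts drawn log-uniformly within
bounds (uniformly for Hill coefficients), L-BFGS-B in log₁₀ space for
rates, objective tolerance 10⁻⁸, either SSE or χ²_F as the objective
(the two rank perturbed parameter sets concordantly, Spearman ρ > 0.8).
Pre-stimulus equilibria are cached across objective evaluations keyed on
the basal-relevant free parameters (fluxes gated by TNF = 0 or
IKKa = 0 cannot move the equilibrium), which roughly halves the cost of
gradient evaluations. Defaults: 50 starts (config-scalable), penalty 10⁶
on simulation failure (counted and logged).

The three-stage modular workflow mirrors the feedback structure:

1. **downstream** — fit the IκBα/NF-κB module (free: `kc1, kr, ku, kd,
   ka1a, c1a, ki1`) to NF-κB data with the measured IKK course as a fixed
   µM-scale input (the normalized data are scaled by an assumed peak
   active-IKK concentration, default 0.03 µM, exposed in the config);
2. **upstream** — fit the IKK cycle (free: `ka, h_a, km_a, k_afb, ki,
   h_i, kmmi, k_a20i, kp`) to IKK data with the stage-1 model's
   regenerated (never cached) nuclear NF-κB as input;
3. **full** — integrate and re-estimate only the loop-coupling rates
   (`k_afb, k_a20i, kp, ki3a`) against both assays.

Known limitation: with the canonical 6-point IKK grid, the pchip'd
measured-IKK input carries a systematic interpolation error that is large
compared to the NF-κB ensemble sem (0.1/√15 ≈ 0.026), so the driven
downstream stage cannot reach statistical consistency even against data
generated by the model itself (best SSE ≈ 0.036, p_F ≈ 5·10⁻⁵); the
upstream stage, whose nuclear-NF-κB drive is densely sampled, does reach
p_F > 0.05. The structure-discrimination experiment therefore drives the
downstream fits with a densely sampled IKK course.

A second limitation concerns the inactivation Hill coefficient: fitted to
the 6-point IKK reference profile with SD 0.1 and n = 3, the upstream
model is unidentifiable in `h_i` — about 90 % of 50 multistarts converge
to the same SSE floor with combined p-value 1.0 while their `h_i` values
spread uniformly over [1.5, 6] (activation-side cooperativity and
near-saturated inactivation reproduce the decline equally well). The
best-fit `h_i` is best read as undetermined under these data conventions;
`analysis/04_upstream_fit.py` reports the whole tie set for this reason.

## Structure discrimination

Synthetic NF-κB ensembles are generated from the four-step nominal model
(5 experiments × 3 replicates, standard noise), and both downstream
structures are fitted (≥20 starts each, χ²_F objective by default, same
densely-sampled IKK drive). The four-step chain — three sequential
first-order steps after phosphorylation — produces the observed ~5-min
lag in NF-κB onset; the two-step chain can imitate a lag only through a
slow single release step, whose exponential (rather than Erlang-3) shape
overshoots the early time points. Typical outcome: best four-step
p_F ≈ 0.9, best two-step p_F ≈ 10⁻⁶.

## Sensitivity analysis and scans

Normalized coefficients S_ij(t) = (θ_j/y_i)·∂y_i/∂θ_j are computed by
the forward sensitivity equations: the state trajectory is solved once
(LSODA, rtol 10⁻¹⁰) with continuous dense output, then each parameter's
15-dimensional linear time-varying sensitivity ODE is integrated along
it with the analytic state and parameter Jacobians. Initial sensitivities
are zero: the pre-stimulus state is held fixed, so coefficients measure
the response of the stimulated trajectory to a parameter change applied
at stimulus onset (both the forward and the central-finite-difference
oracle use this convention, and they agree to <10⁻³ absolute over
0–120 min; the oracle uses relative steps of 10⁻⁶). Coefficients are
reported as NaN wherever the output falls below 10⁻¹² µM. Time-averaged
scores are (1/T)·∫|S|dt by trapezoid; the first-phase screen uses
T = 10 min, heat maps are signed over the full 120 min.

Robustness scans vary one parameter at a time over log-spaced factors
(the nominal factor 1 always included), re-equilibrate, re-simulate, and
record the Euclidean distance between nominal and perturbed normalized
nuclear-NF-κB responses on a fixed output grid. Each perturbed
trajectory is normalized at its own 20-min value, matching the
measurement convention (an absolute-µM mode is provided as a config
switch). Failures at extreme factors are recorded as NaN, never
interpolated over.

## Problem sizes

Default experiment sizes used by the analysis scripts, the test suite and
the acceptance script: 50 multistarts for the upstream fit, 20 per
structure for the discrimination experiment (the study-scale analog used
1980), 2000 replicates for the null calibration, 25-point time grids for
the sensitivity oracle, and ±10-fold 9-point scans for the
robust/fragile contrast with 4-decade 13-point scans in the analysis
script. These sizes give stable outcomes for every reported quantity
while keeping a full pipeline run in the minutes range.
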