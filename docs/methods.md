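# Methods

## The system and the two competing models

Regnase-1 (encoded by *Zc3h12a*) is an endoribonuclease that degrades
inflammatory mRNAs such as *Il6* by recognizing stem-loops in their
3′ UTRs, and it also degrades its own mRNA. Inflammatory stimulation
(IL-1R/TLR signalling) has two opposing effects on the protein: it
triggers ubiquitin-dependent degradation of Regnase-1, and it induces
phosphorylation (at S494/S513) that recruits the adaptor protein 14-3-3.
Cells carrying the S513A knock-in cannot be phosphorylated at that site
and therefore cannot form the 14-3-3 complex.

`reg1dyn` implements two ordinary-differential-equation models of this
circuit that differ in a single biological assumption:

* **Model 1** — 14-3-3-bound Regnase-1 is *inactive*: it no longer
  degrades target mRNAs.
* **Model 2** — 14-3-3-bound Regnase-1 *retains* its mRNA-degrading
  activity (extra rate constants d1′, d2′).

The shared state is x1 = *Il6* mRNA, x2 = *Zc3h12a* mRNA, x3 = free
Regnase-1 protein, x4 = 14-3-3-bound Regnase-1:

    dx1/dt = k1·s(t) − d1·x1·x3 [− d1′·x1·x4] − d4·x1
    dx2/dt = k2·s(t) − d2·x2·x3 [− d2′·x2·x4] − d5·x2
    dx3/dt = k3·x2 − (d3 + d6·s(t) + d7·s(t))·x3 + d9·x4
    dx4/dt = d7·s(t)·x3 − (d8 + d9)·x4

with the bracketed terms present only in Model 2. The stimulation
signal s(t) is a delayed ramp–plateau pulse: basal strength `s_base`
until `t_delay`, a linear ramp to `s_input` over `t_raise`, a plateau of
length `t_pulse`, and afterwards either sustained stimulation
(`SUSTAINED`, the default) or exponential relaxation back to `s_base`
with timescale `t_decay` (`DECAYING`). Only the sustained mode is
admitted in equilibrium computations, because the fixed-point analysis
assumes s(t) → `s_input`. Time is in hours; signal and abundances are
dimensionless arbitrary units — nothing in the analysis depends on
absolute scales.

The S513A genotype is modelled by zeroing d7, d8, d9 (no complex ever
forms), applied by `apply_genotype`; all other rate constants are shared
between genotypes.

## Equilibria

Setting the derivatives to zero at constant signal s and eliminating
x4 = d7·s·x3/(d8+d9) reduces each model to one quadratic. With

    K = (1/k3) · (d3 + d6·s + d7·s − d7·d9·s/(d8 + d9)),

the wild-type free-protein fixed point X3 is the unique nonnegative
root of

    (d2 + (d7·s/(d8+d9))·d2′)·K·X3² + d5·K·X3 − k2·s = 0,

and X4, X2 = K·X3, X1 = k1·s/(d1·X3 + d1′·X4 + d4) follow. A
nonnegative equilibrium exists iff K ≥ 0; since
d7·s − d7·d9·s/(d8+d9) = d7·s·d8/(d8+d9) ≥ 0, K ≥ 0 holds throughout
the nonnegative parameter region, so the biologically meaningful
equilibrium always exists and is unique (the quadratic's second root is
negative whenever k2·s > 0). K < 0 remains representable
(`exists=False`) to keep the if-and-only-if condition honest. For
S513A the reduced system gives X4 = 0 exactly and a quadratic in X2
instead. Model 1 uses the same formulas with d1′ = d2′ = 0.

Corner cases are rejected rather than extrapolated: k3 = 0 (no
translation), d3 + d6·s = 0 on the reduced branch (protein never
degrades), and d8 + d9 = 0 with d7·s > 0 (complex forms but neither
degrades nor dissociates — X4 has no finite value). When d8 + d9 = 0
with d7·s = 0 the general branch falls back to the reduced formulas.

Quadratic roots use the cancellation-free form −2c/(b + √(b²−4ac)),
stable when the linear coefficient dominates.

An independent numeric oracle (`equilibrium_numeric_oracle`) solves
rhs = 0 directly with MINPACK's damped hybrid iteration on the state
projected onto the nonnegative orthant, retried from rescaled starts,
and accepts only roots with residual ∞-norm < 1e-10. When the bound
pool carries no flux (d7·s = 0 and d8+d9 = 0) x4 is conserved and the
root manifold is a line; the oracle then pins x4 = 0 — the biologically
meaningful pool for cells that never formed the complex — and solves
the remaining three equations. Tolerances: closed-form-vs-oracle 1e-8
relative, fixed-point residual 1e-9 absolute on unit-scale problems.

## Model discrimination

The discriminating observation is qualitative: at late stimulation
times, free Regnase-1 *and* both target mRNAs are comparable between
wild-type and S513A cells. `predicted_mrna_at_matched_x3` imposes a
common free-protein fixed point X3 on both genotypes and evaluates

    X1 = k1·s/(d1·X3 + d1′·X4 + d4),  X2 = k2·s/(d2·X3 + d2′·X4 + d5),

with X4 = (d7·s/(d8+d9))·X3 for WT and X4 = 0 for S513A. Under
Model 1 the genotypes coincide identically; under Model 2 with
d1′, d2′, d7·s > 0 the WT denominators are strictly larger, so WT mRNA
is strictly lower — inconsistent with "no difference". `discriminate`
operationalizes "comparable" as a relative tolerance (default 1e-6 for
analytic checks; ~0.1 is appropriate for noisy data), classifies each
mRNA pair as WT_LESS / EQUAL / WT_GREATER and reports whether the model
is consistent with the observation. Verdicts state consistency with the
supplied observation, not biological truth.

The matched X3 is an input, mirroring how the constraint comes from the
immunoblot observation rather than from the model. For validation, the
package can also *engineer* a full WT parameter set with a prescribed
equilibrium X3 by inverting the equilibrium quadratic for k2
(`solve_k2_for_target_x3` — the quadratic is linear in k2); the full
closed-form equilibria then reproduce the shortcut's verdicts.

## Simulation

Trajectories are solved with LSODA (automatic stiff/non-stiff
switching; degradation rates may span orders of magnitude) at
rtol = 1e-8, atol = 1e-10. The right-hand side is evaluated on the
state projected onto the nonnegative orthant, which keeps round-off
excursions within the absolute tolerance; sampled states below −1e-9
abort the run, smaller excursions are clipped to zero on output, so
consumers never see negative abundances. The default initial condition
is the basal equilibrium (the closed form at s = `s_base`): measured
time courses start from resting cells. Integration from the origin is
used in convergence tests. The fixed-point analysis proves existence
and uniqueness only; convergence is demonstrated numerically (50 random
systems integrated to t = 500/slowest-rate agree with the closed form
to 1e-3 relative).

## Synthetic data

`generate_dataset` emulates the measurement design the models were
built against: two genotypes, sample times {0, 0.5, 2, 4} h, three
replicates, and five observables mapped deterministically from the
state — total Regnase-1 (x3+x4, immunoblot band mass), free and bound
Regnase-1 (the fast- and slow-migrating fractions), and the two mRNAs
(RT-qPCR). BOUND_REG1 is exposed even though real experiments read it
only as a gel shift; it is synthetic-only and enables sharper fitting
tests. Noise is multiplicative lognormal — densitometry and qPCR are
positive, roughly log-scale measurements — parameterized by its
coefficient of variation with mean exactly 1 (underlying normal:
σ² = ln(1+cv²), μ = −σ²/2). cv = 0 reproduces model values exactly and
identical seeds give byte-identical tables.

The generator does **not** emulate blot saturation, background,
qPCR-efficiency bias, single-cell variability, or any absolute
calibration (no quantitative band intensities exist to calibrate
against). Passing tests therefore show that the *inference machinery*
behaves correctly under the stated noise model, not that the model fits
real measurements.

### Default parameter set

No numeric rate constants accompany the symbolic analysis, so the
packaged defaults are illustrative, chosen once so the noiseless
wild-type trajectory shows the qualitative signatures of the measured
system: k1 = k2 = k3 = 1, d1 = d2 = 1, d3 = 0.05 (stable resting
protein), d4 = 0.5, d5 = 1, d6 = 1.5 (fast signal-driven degradation),
d7 = 0.5, d8 = 0.2 (protected bound pool), d9 = 2 (fast dissociation),
all per hour; profile s_base = 0.05, s_input = 1, t_delay = t_raise =
0.25 h, sustained. The rationale: the early dip needs stimulated
degradation (d6+d7 ≈ 2/h) to outrun the transcription–translation lag
(~1 h via d5); the late overshoot needs the stimulated equilibrium X3
to exceed the basal one (d3 ≪ d6·s_input); the free-protein match
between genotypes needs the binding flux contribution to K
(d7·s·d8/(d8+d9) ≈ 0.05) to be small against d3 + d6·s ≈ 1.55, while
d7·s/(d8+d9) ≈ 0.23 still leaves a visible bound pool so that S513A
total protein sits clearly below WT. With these values: dip ratio 0.87
at 0.5 h, overshoot ratio 1.73 at 4 h, S513A/WT total 0.84 at 4 h, free
Regnase-1 and Il6 ratios 0.97 and 1.02. The Model 2 variant switches on
d1′ = d2′ = 1 with everything else shared.

## Fitting

The loss is the sum of squared log-residuals
(log(y+ε) − log(ŷ+ε))², ε = 1e-9 — the maximum-likelihood objective (up
to constants) under the generator's lognormal noise. Predictions
integrate the candidate model from its basal equilibrium per genotype;
candidates that make the integration fail score +∞ rather than raising.
Minimization is bounded derivative-free Powell search with seeded
lognormal multi-starts (geometric sd 2). The full 15-parameter model is
not identifiable from 5 observables × 4 time points; the intended use
is small subsets (the tests use {k1, d1}) with the remainder fixed.
Zero-noise recovery of that subset is exact to ~1e-15; at cv = 0.1 with
3 replicates the median recovery error across 20 seeds is ~10–15%.
No uncertainty quantification beyond seed-wise spread is attempted.

## Problem sizes and determinism

Randomized suites use fixed seeds: 1000 draws for the model-reduction
identity and the K ≥ 0 property, 200 per model/genotype pair for
closed-form-vs-oracle agreement, 50 integrations for convergence, 500
draws for the discrimination inequalities, 20 noisy datasets for the
recovery study. `scripts/acceptance.py` recomputes all of these from a
single `--seed`, fanned out to stage seeds via NumPy's `SeedSequence`
(all derived seeds < 2³¹), and writes the measured values as JSON.

## Known limitations

* No spatial compartments (nuclear/cytoplasmic shuttling is outside the
  model) and no stochastic kinetics.
* No stability or bifurcation analysis of the fixed points; convergence
  is shown numerically for the sampled parameter region only.
* The post-plateau behaviour of the stimulation signal is genuinely
  ambiguous; both readings are provided as explicit modes rather than
  resolved, and equilibrium computations require the sustained mode.
* Verdicts from `discriminate` are consistency statements relative to a
  stated tolerance, not hypothesis tests with error control.
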