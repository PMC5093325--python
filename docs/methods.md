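# Methods

## The model

`peptube` treats a supramolecular peptide filament (an FF nanotube, a
cycloFF needle, or anything with the same phenomenology) as a strictly
one-dimensional object with two chemically distinct termini. Elongation is
maturation of a preformed structure: monomers attach at an end at rate
`k_on · c` (μm/min, `c` the local free-monomer concentration in mM) and
detach at rate `k_off` (μm/min), giving the linear net growth law

```
R(c) = k_on · c − k_off,        c_s = k_off / k_on
```

with the critical concentration `c_s` the unique zero: supercritical
solutions drive growth, subcritical ones shrinkage. Nucleation, radial
growth, temperature dependence and spatial monomer transport are all
outside the model. The two termini carry independent rate pairs; the
fast, carboxylate-exposed face is called O and placed at the upper
coordinate (terminus B), the slow amino-exposed face N at the lower
coordinate (terminus A). Outward motion is positive for both ends, so
per-end rates are directly comparable.

## Stochastic simulation

The simulator is an exact Gillespie algorithm on a continuous-time Markov
jump process. Length is quantized in layers of `layer_um` (δL, default
0.01 μm): attach/detach events move the relevant end outward/inward by δL,
so propensities are length rates divided by δL — attach `k_on·c/δL`,
detach `k_off/δL` per minute per uncapped end, plus an optional
irreversible capping clock at `cap_rate` per minute per end (capping is
reported experimentally but with no kinetics; the default is off). δL is a
pure discretization knob, small against the μm measurement scale but large
enough to keep event counts tractable on a desktop; a refinement test
checks that halving δL leaves ensemble mean rates unchanged within Monte
Carlo error. Initial lengths are rounded to whole layers.

Two bath modes:

* **open** — `c` constant (continuous flow; the system never
  equilibrates). Between capping events all propensities are constant, so
  the event stream is sampled in vectorized blocks (exponential waiting
  times at the total propensity; types multinomial in the propensities;
  cap times drawn as independent exponential racers). This is
  distributionally identical to the naive per-event loop and roughly two
  orders of magnitude faster.
* **closed** — a finite pool: each attach removes, each detach returns, a
  depletion quantum γ (`depletion_quantum_mM`, default 1e-4 mM). Mass
  bookkeeping is integer (c is recomputed as `c0 − γ·net_layers` from an
  integer counter each event), so conservation is exact to floating
  round-off at every event, including through full dissolution. γ is the
  single coarse-graining parameter of the closed pool and sets the
  fluctuation scale of `c` around equilibrium (tail SD ~0.007 mM at the
  defaults). Attachment is blocked when `c < γ` so the pool can never go
  negative; with γ ≪ c_s this guard is never active in practice.

Termination: `t_max`, full dissolution (length 0; the trace ends at that
event and the state absorbs), or both ends capped. A single
`numpy.random.Generator` (PCG64) seeded from the bath config drives each
run; identical config + seed reproduces traces bit for bit.

At equilibrium of the closed pool the attach and detach propensities of
each face balance at exactly `c = k_off/k_on`, independent of the face's
absolute speed — so faces with equal ratios but different magnitudes share
the fixed point, and the leftover soluble concentration estimates `c_s`.
`equilibrium_concentration` reports the time-weighted tail mean of `c`.

### Presets

The measured growth laws constrain only the *summed* rates of the two
faces. The presets are therefore stylized limits, clearly labelled and
overridable: `ff_filament` puts the whole fitted pair (3.36 μm·min⁻¹·mM⁻¹,
7.4 μm/min) on the O face with a silent N face (strong-asymmetry limit —
whether the real silent terminus has strictly zero or merely reduced rates
is not determined by the data); `cycloff_filament` splits (0.15, 1.2)
equally between the two equivalent faces.

## Observation model

Real measurements are manual length reads on micrographs: each terminus
measured five times per time point and averaged. The synthetic observation
layer frame-samples the event trace at a fixed interval (zero-order hold —
lengths are constant between events — with the left-closed convention that
a frame exactly on an event time reports the post-event position) and
reports, per terminus per frame, the mean of `n_repeats` iid Gaussian
reads of SD `sigma_um` plus their sample SD. Defaults: `n_repeats = 5`;
`sigma_um = 0.25 μm`, chosen so the 5-replicate average has ~0.11 μm SD,
small against the 5–10 μm scale of the imaged structures (the source
measurements never quantify their error; this knob is surfaced in every
config). Frame intervals varied by system experimentally (tens of seconds
for the fast FF kinetics, minutes for cycloFF), so the default designs use
0.5 min (FF) and 4 min (cycloFF) frames.

What the generator does *not* emulate: drift and focus artefacts,
digitization bias, tube-to-tube rate heterogeneity, capping-time
truncation, and the flow-induced uneven mass transfer to the two ends
(neglected in the underlying analysis as well). Passing tests therefore
show the estimators are correct *under the stated model*, not that the
model exhausts real microscopy data.

## Estimation

* **Terminus rates** — OLS slope of position vs frame time over the whole
  trace, times the orientation sign (−1 for A, +1 for B). OLS over the
  trace, rather than frame-to-frame differences, is the minimum-variance
  linear estimator for a constant-rate segment and matches reporting one
  rate per terminus per condition. The reported SE is the usual OLS slope
  SE; note it reflects frame scatter and understates the sampling SD when
  the kinetic (random-walk) noise of the event process dominates — tests
  that compare against ground truth add the theoretical path-noise term
  `δL²·λ/T` to the error budget. Traces can be truncated at a
  user-supplied capping time before fitting; no automatic changepoint
  detection is attempted.
* **Tube growth rate** — the sum of the two outward terminus rates, i.e.
  d(length)/dt; its expectation equals the summed growth law under either
  preset, which is what "the" measured `R(c)` refers to.
* **Growth law** — per-condition rate = unweighted mean over the tubes of
  a condition; its SE = sample SD/√n. The condition means are fitted with
  weighted least squares (weights = inverse variance; an unweighted option
  exists, and the fit falls back to OLS when any condition SE is zero).
  Slope → k_on, negated intercept → k_off, conventional WLS standard
  errors and covariance, Student-t confidence intervals on the residual
  degrees of freedom. An exact two-point fit has zero residual dof; its
  SEs are reported as 0.
* **Critical concentration CI** — first-order (delta-method) propagation
  of the fit covariance through `k_off/k_on`, symmetric about the point
  estimate, using the fit's t quantile (normal when no dof information is
  attached). The interval is approximate by construction and a warning is
  raised when `k_on` is within 2 SE of zero, where the linearization is
  unreliable. Monte Carlo over the default design puts its coverage near
  nominal (the test asserts ≥ 85% at the 95% level over 100 replicates).

## Directionality classification

Per tube, each terminus is tested for activity: active iff
`|rate| > z_(1−α/2) · SE` (an SE of 0 is an exact measurement, so any
non-zero rate is active). Exactly one active end → *unidirectional*, two →
*bidirectional*, none → *stalled*; non-finite inputs give *indeterminate*
with a warning instead of an exception. The two-sample statistic
`(rate_A − rate_B)/√(SE_A² + SE_B²)` is reported alongside for the
"can the ends be told apart" question. The z-test is the simplest
formalization of "distinguishable within experimental error" and is a
package design choice, not something the source data prescribe.

When `run_recovery` tallies directionality across a whole experiment it
Bonferroni-corrects the per-end level to `α / (2·n_tubes)` by default.
This is deliberate: an ensemble statement such as "every tube grew
unidirectionally" is a family-wise claim, and because the per-end test
statistic is scale-invariant in the measurement noise, a fixed per-end α
would mislabel ~α of all silent termini as active (hence tubes as
bidirectional) *no matter how precise the data are*. Correcting across the
2·n_tubes tests makes the expected number of false "bidirectional" calls
~α per experiment. `multiplicity="none"` restores the uncorrected
per-tube behaviour.

## Co-flow mixing arithmetic

The in-channel concentration of a multi-inlet laminar reactor is the
flow-weighted mean Σcᵢqᵢ/Σqᵢ — complete mixing is assumed, as was
established empirically with dye co-injection in the device modelled;
no Péclet/diffusion computation is attempted. Concentration values carry
explicit unit tags (mg/ml vs mM) and mixing units raises rather than
coverts silently, because the literature alternates units freely and
silent coercion is the main foreseeable bug source. Conversions use
monomer molar masses (FF 312.4 g/mol, cycloFF 294.3 g/mol, overridable);
reported values are rounded half-up to the printed precision *only at
presentation boundaries*, never inside computations. One consequence:
the mixed cycloFF concentration 2.3375 mg/ml prints as 2.34 mg/ml and
7.94 mM — converting the rounded 2.34 instead would give 7.95.
`flow_rates_for_target` solves the two-inlet inverse problem in closed
form; targets outside the inlet band are unreachable and raise.

## Default study conditions and problem sizes

The default experiment designs mirror the study structure: 5
concentrations × 10 tubes, FF over 1.60–3.20 mM (10 min, 0.5 min frames,
start length 60 μm), cycloFF over 1.70–13.59 mM (60 min, 4 min frames,
start 80 μm). Generated datasets use δL = 0.05 μm — at the observation
scale the layer quantization is far below the measurement noise, and
δL-insensitivity is tested separately. Start lengths are chosen so that
subcritical conditions shrink without dissolving within the run.
Ensemble checks use 100 seeds per condition (3-SEM agreement with the
analytic law), parameter-recovery coverage uses 200 replicates of the
default design, and closed-pool equilibration uses 200 simulated minutes
(≈5 relaxation times at the default γ/δL) with the final quarter as the
averaging tail.

## Known limitations

* The growth law is linear by assumption; saturation of attachment at
  high concentration, nucleation and secondary processes are out of scope.
* Delta-method CIs on a ratio are symmetric and first-order; with few
  conditions and a weakly determined slope they can be poor.
* WLS with weights estimated from 10 tubes per condition is slightly
  optimistic; the Student-t intervals on 3 residual dof absorb most but
  not all of that (joint k_on/k_off coverage ≈ 93–95% empirically).
* The OLS terminus-rate SE does not include kinetic path noise; per-end
  activity calls on very coarse-layered simulations are anti-conservative
  in that regime.
* Open-mode block sampling assumes propensities change only at caps; any
  future state-dependent open-bath feature must switch to the event loop.
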