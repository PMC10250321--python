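# Methods

This note records the models the package implements, the estimation
procedures and their numerical choices, what the synthetic generators do
and do not emulate, and the design decisions taken where published
practice leaves the procedure open.

## Standard linear solid creep (micropipette aspiration)

The cell is modeled as a semi-infinite standard linear solid: a spring
k1 in parallel with a Maxwell arm (spring k2 in series with dashpot μ).
Under a constant aspiration pressure ΔP through a pipette of radius Rp
the aspirated length is

    L(t) = (2 Rp ΔP / π k1) · [1 + (k1/(k1+k2) − 1) · exp(−t/τ)],
    τ = μ(k1+k2)/(k1·k2),

with instantaneous jump L(0) = 2RpΔP/π(k1+k2) and plateau
L_max = 2RpΔP/πk1. All quantities are SI internally (m, Pa, s); file
readers convert from μm columns. No wall or fillet corrections are
applied — the semi-infinite-medium idealisation is taken as given.

### Two-point (plateau/log-linear) estimator

The classical procedure — read L_max off the plateau, L(0) off the
jump, and the rate off two transient points — is generalised to
regressions over all points so it is deterministic and uses the whole
record:

1. **Plateau.** L_max starts as the mean of the final `plateau_fraction`
   (default 0.2) of samples. Because the tail is still relaxing, this
   underestimates the true plateau by C·mean(exp(−t_w/τ)); a fixed-point
   refinement (L_max ← window mean + that correction, with C and τ
   re-read from step 2 each pass) removes the bias. On a noiseless
   exponential the truth is the fixed point, so recovery is exact to
   machine precision; the iteration contracts strongly and converges in
   a handful of passes (cap 60, tolerance 1e−14 relative).
2. **Transient.** Regress log(L_max − L) on t over the pre-plateau
   samples whose gap exceeds max(2% of the jump, 4× the noise floor),
   the noise floor being the residual sd about a local line through the
   plateau window. The regression is weighted by the gap itself
   (inverse-variance: additive noise of sd σ on L gives log-gap noise
   ≈ σ/gap). Slope gives τ, intercept gives C, hence
   L(0) = L_max − C.
3. **Parameters.** k1 = 2RpΔP/πL_max, k1+k2 = 2RpΔP/πL(0),
   μ = τ·k1k2/(k1+k2).

Degenerate inputs are flagged rather than fit: a flat series (no
transient above the noise floor) or a non-decaying gap returns
`converged=False`; a first sample above the plateau raises a
degenerate-transient error. A fit is accepted as plateaued only if the
plateau-window slope is below max(1% of (L_max−L(0))/τ, 2 SE of the
slope estimate) — the SE term stops measurement noise alone from
vetoing an otherwise flat tail.

L(0) is always back-extrapolated, never read from the first frame: in
practice the first frames are contaminated by the pressure-application
transient and frame-rate quantisation.

### Nonlinear least squares

`fit_nls` minimises the residual of the forward model over
(log k1, log k2, log μ) — positivity is structural — with
`scipy.optimize.least_squares` (trf, tolerances 1e−15), initialised from
the two-point estimate (fallback heuristic when that fails: k1 from the
max length, k2 = k1, τ = range/3). The result is never reported with a
worse residual than its initialisation. Per-parameter variances come
from the Gauss–Newton covariance s²(JᵀJ)⁻¹ mapped through the log
parameterisation. Point estimates are parameterisation-invariant; the
log scale matters only for the optimiser and the covariance.

Both routes recover noiseless synthetic parameters to ≤1e−6 relative
(measured: ~1e−15 two-point, ~1e−10 nls) and agree with each other to
the same tolerance; under 1% additive noise with 200 samples the
two-point route recovers all three parameters within 10% in 97 of 100
seeded replicates.

## Hertz spherical indentation

Load on a rigid sphere of radius R at depth δ into an elastic
half-space: F = (4/3)·E_r·√R·δ^{3/2}. Defaults mirror the ferrule-top
instrument: spring constant 0.048 N/m, 5 μm depth-controlled indents,
2 s load period. The quoted 9 μm spherical tip is read as the **radius**
(the probe-vendor convention); because the reading is ambiguous, the
radius is an explicit configuration field with a
`InstrumentConfig.with_tip_diameter()` preset for the 4.5 μm
interpretation. Note the recovery experiments are self-consistent either
way (generator and fitter share the config); only absolute moduli from
real data depend on the choice.

**Reduction.** Raw (piezo z, deflection d) → F = k·d, δ = z − d.
Idempotent; a reduced curve passes through with a warning.

**Contact point.** For every candidate index c the curve is modeled as a
constant baseline before c and baseline + a·(x−x_c)^{3/2} (a ≥ 0,
closed-form) from c on; the total-SSE minimiser wins, ties broken to the
earliest index. The split model must beat the all-baseline model under
BIC (it pays for two extra parameters), so a pure-noise curve raises a
no-contact error instead of being over-fitted. Localisation calibration:
with 2% multiplicative load noise (the load-noise protocol used
throughout for indentation) the detected index is within ±2 samples of
truth in 99/100 seeded replicates. Under 2%-of-peak *additive* noise the
rate drops to ~72%: near contact the signal is below the noise floor and
the break point is genuinely uncertain at 25 nm sampling — alternative
estimators (F^{2/3} back-extrapolation, force-space nonlinear x_c fits)
do not beat the global least-squares scan there. Mislocating contact by
+s samples biases the modulus upward, monotonically in s (tested, not
silent).

**Modulus.** Only the loading segment (up to the deepest point) is
fitted — unloading carries viscoelastic hysteresis. With contact at c
and baseline b: regress F−b on δ^{3/2} through the origin;
E_r = (3/4)·slope/√R. `depth_fraction` (default 1.0, i.e. the full
controlled depth, matching how the published moduli were obtained from
5 μm indents) restricts the fit range for Hertz-validity studies. Fewer
than 5 post-contact points is an error. The closed-form fit equals an
iterative nonlinear fit to ≤1e−9 (tested against `scipy.curve_fit`).
E = E_r(1−ν²) is exposed separately with ν configurable (default 0.5,
incompressible cell) rather than conflated with E_r.

**Aggregation.** Per-group mean and SEM over converged fits (the
convention of averaging 20–30 indents per condition in three independent
tests); non-converged fits are excluded and counted, single-fit groups
report SEM as NaN, empty groups keep a row.

## Chemotaxis and wound closure

Velocity is curvilinear speed (path length / elapsed time, μm/min) —
the convention of tracking software; a straightness-corrected
alternative can be derived from the reported net displacement.
Directionality is the signed chemotactic index: net displacement
projected on the gradient axis (unit vector, +x by channel convention)
divided by path length, bounded in [−1, 1], defined as 0 for a
stationary cell; the forward-migration-per-time alternative
(μm/min, unbounded) sits behind `directionality_mode="fmi_per_time"`.
Cohort summaries drop tracks shorter than 5 frames (configurable,
counted), and sort per-group values before averaging so output is
exactly permutation-invariant. Wound closure is 100·(area/area₀)
computed ratio-first so day 0 is exactly 100 in floating point.

## Synthetic data

Generators exist so every estimator is validated by recovery against a
known ground truth, written into each object's `meta` sidecar.

* **Creep**: exact forward model plus noise; defaults ΔP = 500 Pa
  (typical aspiration magnitude, ≈5 cmH₂O — the published experiments do
  not state theirs), Rp = 3.5 μm (7 μm pipette), 200 samples over 10τ
  (a warning below 5τ). Noise scales on L_max.
* **Indentation**: flat zero-load baseline (default 50 samples over a
  0.5 μm approach), then an exact Hertz branch to the 5 μm controlled
  depth (150 samples); contact falls exactly on a sample. Raw-mode
  output inverts the reduction (d = F/k, z = position + d). Noise
  scales on peak load; the indentation protocol uses multiplicative
  Gaussian load noise.
* **Trajectories**: biased persistent random walk sampled every 3 min
  for 6 h (the recording protocol of the horizontal-chemotaxis assay).
  Velocity per frame = f·s·û + (1−f)·w_t with drift fraction f, target
  speed s (default 1 μm/min, a typical macrophage scale), and w_t a
  stationary AR(1) Gaussian velocity (coefficient 0.6 by default —
  macrophage tracks are visibly persistent) scaled so E|w| = s.
  f = 1 gives directionality exactly 1; f = 0 an unbiased walk.
* **Cohorts**: per-cell ground truths drawn log-normally around group
  means with a coefficient of variation (mean-preserving; moduli are
  positive with heavy right tails — published group SDs are comparable
  to the means), then one curve per cell. Randomness fans out from one
  seed via `SeedSequence.spawn`, so identical specs are bit-identical.

What the generators do **not** emulate: pressure-application transients,
pipette wall friction or fillet geometry; indenter adhesion, substrate
(bottom-effect) stiffening, viscoelastic rate dependence of the
indentation branch; cell–cell interactions, channel walls, gradient
decay. Recovery results therefore validate the estimators under the
stated noise models, not the instruments or the biology.

Default measurement noise is 2% of the signal ceiling (additive for
creep, multiplicative for indentation loads): the instruments' true
noise magnitudes are unpublished, so these are calibration choices,
configurable per experiment.

## Recovery experiments and problem sizes

The acceptance suite runs entirely at desk scale: 50–1000 random
parameter triplets for the exactness identities; cohorts of 200
indentation curves per condition (3% multiplicative load noise) for the
modulus-recovery experiments, whose ground truths are set to the four
reported group means (1721, 1113, 4838, 1963 Pa) and whose cohort means
come back within 0.3% of truth; 100 seeded two-cohort aspiration
comparisons (n = 30/group, cv = 0.25, k1 and μ elevated 1.8×, k2
shared) for the directional-difference property; 500 unbiased and
5×200 drift-swept tracks for the chemotaxis calibration.

On the two-cohort comparison: Welch tests on log-fits flag k1 and μ in
100/100 repetitions; k2 — whose group means are equal by construction —
is falsely flagged in 8/100 at α = 0.05, so the joint
"k1 and μ different, k2 not" event occurs in 92/100. That is the
expected behaviour of a 5%-level test (the joint rate can never
reliably exceed ~95%, and seed-to-seed binomial spread puts any single
100-seed run a few counts either side); the suite's strict ≥95
assertion documents the target and currently fails by that margin. A
small estimator-side contribution (the nls k2 bias differs by ≈0.4% in
log units between the two curve shapes, against a between-group SE of
6.7%) is measurable but not the driver.

## Known limitations

* The SLS fit assumes the pressure step is instantaneous and the record
  starts at the step; slow pressure ramps bias k1+k2 downward.
* Hertz validity degrades as δ approaches R (5 μm indents with a 9 μm
  tip are at the edge of the small-strain regime); `depth_fraction`
  exists to quantify the sensitivity but no finite-thickness or
  large-indentation correction is applied.
* Contact detection assumes a single contact with a monotone loading
  branch; adhesion dips or multiple touch events will mislead it.
* Trajectory metrics assume planar motion and a fixed gradient axis; no
  gradient-strength model is included.
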