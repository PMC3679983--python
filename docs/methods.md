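# Methods

## The model and its assumptions

The package implements a four-variable nondimensional reduction of
the yeast cAMP–PKA network.  The full network (two G-protein inputs,
Cdc25/Ira regulation of Ras2, adenylate cyclase, two
phosphodiesterases, PKA holoenzyme activation) is collapsed under
three kinds of assumption:

- **Competitive PKA feedback.**  Pde1, Pde2 and Ira1/2 compete for
  the free PKA catalytic subunits.  The competitive Michaelis–Menten
  velocities (`camppka.kinetics.competitive_velocities`) carry each
  substrate's Michaelis constant into the competitors' denominators.
  When the affinity-separation condition holds
  (`check_condition_a`; "much less than 1" is operationalized as a
  configurable ratio threshold, default 0.1), the active
  phosphodiesterase pool collapses to a single case-dependent
  variable *p*: it stands for Pde1 in genotypes where Pde1 is
  present, and for Pde2 in the *pde1Δ* mutant.
- **Fast activation steps at steady state**, in particular PKA
  activation by cAMP.  Approximating the 4 cAMP : 2 catalytic-subunit
  stoichiometry by 2:1, away from saturation, makes PKA activity
  proportional to *x²*.
- **Nondimensionalization.**  All ten constants are dimensionless
  composites of microscopic rate constants; the microscopic constants
  are intentionally not carried as independent fields.  Laboratory
  units are restored by `DimensionalScale`: 24.95 fmol cAMP per 10⁶
  cells per unit of *x*, and a per-strain time scale (0.038 min for
  the reference short-term fits, 0.17 min for Σ1278b, 0.35 min for
  S288c).  The reference fixtures also record the alternative printed
  time scale 0.0377 min; the two printed values differ in the source
  material and the package defaults to 0.038.

The double knockout *pde1Δ pde2Δ* is modelled structurally: the *p*
equation and the *D*-term are dropped (equivalent to D = 0 with an
inert *p*, but with a three-dimensional state), and *B* is two orders
of magnitude larger — without PDE competition, PKA feedback on Ira is
greatly enhanced, which is what pins cAMP at its elevated pre-stimulus
level and explains the knockout's non-response to glucose.

## Parameters

Per-genotype fixtures (`src/camppka/fixtures/*.json`) store the
printed decimal strings to avoid transcription drift.  Shared
constants: A = 1.45, Γ₁ = 0.0004, N = 0.032, C = 0.044, D₀ = 0.013.
Genotype columns (M, D, Γ, B) for the reference background: wt and
*pde2Δ* identical (0.01, 1, 33.6, .0051), *pde1Δ* (0.0005, 0.26,
16.8, .0051), *pde1^ala152^* (0.0025, 0.54, 33.6, .0051), double
knockout B = .51.  Strain fits: Σ1278b wt (0.085, 0.247, 0.32),
S288c wt (0.19, 1.07, 0.15), Σ1278b *pde1Δ* (0.262, 0.0112, 0.04)
and *pde2Δ* (0.121, 0.107, 0.061).  The glucose input is G = 0 under
starvation and G = 1 after stimulus; pre-stimulus initial conditions
are always the starved equilibrium.

## Equilibria and stability

The reduced steady state is the unique nonnegative root of
`C₀ − D₀x − Dx³/(Γ+x) = 0`, solved via the equivalent cubic
(`numpy.roots`) and polished by Newton steps to an absolute residual
below 1e−10.  The full equilibrium uses z = p = x² and a nested
bracketed root-find: the Ras equation is solved for r(x) on [0, 1]
(left side decreasing, right side increasing, hence unique), and the
outer scalar equation in x is strictly decreasing on
[0, (C+G)/D₀].  Residual tolerance 1e−9; both tolerances sit far
below the precision of any printed parameter.  The test suite checks
both solvers against an independent plain-bisection oracle and checks
Jacobians against central finite differences.

The damped-oscillation criterion compares
`(M − D₀ − ΓD x_ss²/(Γ+x_ss)²)²` with `8MD x_ss²/(Γ+x_ss)`; it is
exactly the condition for the 2×2 equilibrium Jacobian to have
complex eigenvalues.  Because that Jacobian's trace
`−M − D₀ − DΓx_ss²/(Γ+x_ss)²` is always negative, the reduction can
never cross a Hopf bifurcation: Pde feedback alone damps.  Sustained
oscillations require the Ras arm and are located by `hopf_scan`,
which tracks the largest real part among complex eigenvalue pairs of
the full Jacobian along an A-grid and bisects sign changes to 1e−6.

### Region sweep bounds

The Figure-5-style sweep of the oscillation criterion over (D₀, D)
defaults to D₀ ∈ (0, 0.1] and D ∈ (0, 1.07] on a linear grid.  The
D-axis bound is the largest D fitted for any strain or genotype
(S288c, D = 1.07), so the sweep spans exactly the biologically
fitted range; D₀ runs to about eight times its fitted value.  On this
domain the oscillatory area fraction decreases strictly as Γ grows
through .336, 3.36, 33.6 for both the fed (C₀ = 1.044) and starved
(C₀ = .044) reductions.  That monotonicity is a property of this
domain, not of the whole quadrant: for the starved reduction the
Γ = 33.6 region regains area once D exceeds roughly 1.5, so sweeps
extended far beyond the fitted range will not show a strictly
decreasing sequence.

### Regime classification

`classify_regime` labels a parameter set `sustained_oscillation` when
a complex eigenvalue pair at the equilibrium has positive real part,
otherwise `high_steady_state`/`low_steady_state` by comparing x_ss to
a threshold.  The high/low distinction is qualitative; by default the
threshold is the geometric mean of the equilibrium cAMP levels at the
extremes of the stress scan range (A = 10⁻³ and A = 2).  The stress
regime examples (A = 1.4 high, 0.014 oscillatory, 0.005 low) are
checked with the non-A parameters at their wild-type reference values
and G = 1; the source material does not pin those non-A values, so
the check is configurable rather than hard-coded.  With `sim_check`
the oscillation verdict is confirmed by simulating past the transient
(default horizon 6000 time units, discard fraction 0.5) and requiring
a peak-to-trough amplitude above 1e−3.

## Simulation

`run_timecourse` integrates with SciPy's LSODA (stiff-capable,
adaptive) at rtol 1e−8 / atol 1e−10, restarting the integration at
the glucose switch so the discontinuity never crosses a solver step.
Output states are clipped to the physical region (the vector field is
forward-invariant there; clipping only removes integrator round-off).
Default output grid: 2000 uniform points.

`transient_metrics` reports two measures of the stimulus response:
**amplitude** (peak minus pre-stimulus baseline) and **excursion**
(peak minus the analytic post-stimulus steady state — the overshoot
that decays away).  Genotype-to-genotype comparisons use the
excursion: the excursion ratios reproduce the observed roughly
four-fold (*pde1Δ*, measured 3.36) and two-fold (*pde1^ala152^*,
measured 1.85) enlargements relative to wild type, whereas
peak-minus-baseline ratios (2.69 and 1.65) understate them because
the mutants also settle to higher steady states.  Both numbers are
always reported.

Peak detection for `oscillation_metrics` uses strict local maxima on
the output grid, plateaus breaking to the earliest index.  The
period is the mean spacing of successive maxima; the amplitude is the
last-cycle peak-to-trough difference.  `decaying` means strictly
decreasing peak heights; `sustained` means the amplitude stays above
tolerance without such decay — mutually exclusive by construction.

## Fitting

The forward map simulates the stimulus protocol from the starved
equilibrium (stimulus at t = 0), samples at the observation times
divided by the time scale, and multiplies by the amplitude scale.
Minimization is MINPACK Levenberg–Marquardt (via lmfit's `leastsq`)
on log10-transformed parameters — enforcing positivity and equalizing
steps across the orders of magnitude the constants span — with bounds
[1e−6, 1e3].  Residuals are unweighted, so the densely sampled first
two minutes dominate, mirroring how the bench protocol concentrates
information in the early transient.  The amplitude scale 24.95 is
fixed by default (only M, D, Γ and the time scale vary by strain) but
can be freed.  Integrator failures inside the objective return a
large constant penalty curve rather than raising.  The fit is
deterministic given data and start; `CampPkaModel.fit` optionally
restarts from scaled starting points (e.g. ×3 and ×1/3) and keeps the
lowest-RSS solution.

Noiseless self-fits on the experimental grid recover every fitted
parameter column to well within 1% from 3×-perturbed starts.  Under
measurement noise (CV = 0.1, three pooled replicates) the rate
parameters M and D come back within 10%, but Γ does not reliably: at
the small fitted values (Γ ≪ typical x) the decay term saturates and
Γ is weakly identified — a 12-seed Monte-Carlo gives a median
absolute error of ~17% (max ~50%) for Γ against ~3–5% for M and D.
Tests assert the precisions that the estimator's sampling
distribution actually supports.

`smooth_blackman` is the display smoother: convolution with a
normalized Blackman window (0.42 − 0.5cos + 0.08cos), reflection
padding at the edges, odd window lengths only.  It is linear and
constant-preserving; it is never applied before fitting.

## Synthetic data

`generate_dataset` emulates the bench experiment: glucose step at
t = 0, the piecewise sampling grid (15 s steps for the first 2 min,
30 s for the next 5, 60 s for the last 5 — 24 samples including the
t = 0 baseline; the source protocol descriptions disagree on whether
the 15 s cadence lasts one or two minutes, and the two-minute variant
is the default, fully configurable), and multiplicative lognormal
noise.  The noise multiplier is parameterized mean-one
(σ² = ln(1+CV²)), so the expected observation equals the model curve;
CV defaults to 0.1, reflecting immunoassay error that scales with
signal.  Replicates draw independent noise from a single seeded
generator; identical seeds give bit-identical datasets.  The
generator reproduces the sampling scheme and noise scaling of real
experiments but not assay-specific artifacts (freeze–thaw losses,
plate effects, baseline drift, negative-control subtraction), so
passing recovery tests demonstrate identifiability under the stated
noise model, not robustness to systematic error.

## Problem sizes

Defaults used by the tests and the acceptance script: 10⁴ draws for
the criterion-vs-eigenvalue agreement check, 60×60 sweep grids,
1000-draw uniqueness checks, 12-minute protocols on the 24-point
experimental grid, and 6000-time-unit horizons with 4000 output
points for the long-term regime simulations.

## Known limitations

- The nine-variable full network is out of scope; the Gpa2/Gpr1
  branch never appears as explicit state.
- No uncertainty quantification beyond the residual sum of squares.
- The Hopf scan reports crossings of the equilibrium's complex pair;
  it does not compute normal forms or Floquet multipliers, so
  sub/supercriticality is inferred only from simulation.
- Event handling covers the single glucose step; multi-pulse
  protocols are not implemented.
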