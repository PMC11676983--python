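# Methods

## The reaction model

A reversible toehold-mediated strand displacement (exchange) reaction is
modelled as a single lumped reversible bimolecular step

    X1 + X2  ⇌  X3 + X4,        v = ka·[X1][X2] − kd·[X3][X4]

with X1 the invading single strand, X2 the intact gate duplex, X3 the
exchanged gate and X4 the released strand. Both directions proceed through
a 6-nt toehold, and both rate constants are lumped second-order constants
in nM⁻¹ s⁻¹ that absorb toehold binding, branch migration and dissociation
into one step. Multi-step (three-phase) displacement models are explicitly
out of scope: the lumped description is what the fitted rate constants
parameterize, and it is the level at which the label-effect ratios are
defined.

The assumptions this buys: elementary mass action (no leak or side
reactions, no gate mis-hybridization), isothermal operation, and rate
constants independent of concentration. `kd = 0` is supported as the
irreversible limit.

### Exact progress curve

With 1:1:1:1 stoichiometry the state reduces to one extent of reaction
x(t) (x1 = a−x, …, x4 = d+x from initials a, b, c, d), and

    dx/dt = ka(a−x)(b−x) − kd(c+x)(d+x) = αx² + βx + γ,

a quadratic in x with α = ka−kd, β = −(ka(a+b)+kd(c+d)) ≤ 0,
γ = ka·ab − kd·cd. Separation of variables gives the exact solution

    x(t) = (r1 − r2·W)/(1 − W),    W = (r1/r2)·exp(α(r1−r2)t),

where r1 is the equilibrium root (the attractor reachable from x = 0) and
r2 the companion root; the exponent is strictly negative, so the formula is
stable for arbitrarily large t. Degenerate branches: γ = 0 (already at
equilibrium) returns 0; α = 0 (ka = kd) uses the linear-ODE solution
x_eq(1 − e^{βt}); a non-positive discriminant (coincident roots, e.g.
kd = 0 with equal initials) uses the double-root form αr²t/(1+αrt), which
reduces to the textbook second-order curve C²ka t/(1+C ka t).

This closed form serves two roles: an independent oracle for the numeric
integrator (they must agree to relative error 1e-5), and the fast model
function inside the least-squares fit.

### Numeric integration and equilibrium

`simulate` uses LSODA (stiff-capable; rtol 1e-8, atol 1e-10 nM) because the
rate constants span more than two decades across labelling conditions.
Conservation of x1+x3, x2+x3 and x4−x3 is asserted to drift < 1e-6 nM in
tests. `equilibrium_extent` solves ka(a−x)(b−x) = kd(c+x)(d+x) with the
numerically stable quadratic formula and selects, within the physically
admissible interval [−min(c,d), min(a,b)], the root of the same sign as γ
and smallest magnitude — the root continuously reachable from x = 0. Tiny
negative discriminants (≲ 1e-12·β², pure rounding) are clamped to zero.
For equal initials C the equilibrium substitution ratio reduces to
√(ka/kd)/(1+√(ka/kd)), independent of C.

### Substitution ratio

Reported as the displaced fraction (x1₀ − x1(t))/x1₀, i.e. x4/x1₀ when
products start at zero. This is the definition consistent with all four
steady-state percentages the reference conditions imply (a backward-
dominant construct shows a *small* ratio).

## Observation model

The FRET readout is affine in the unquenched reporter concentration:
intensity f0 + (f100−f0)·[reporter]/x1₀. Measured traces are normalized
between two calibration levels recorded per experiment — the intact
fluorophore+quencher gate alone (baseline, no reaction possible) and the
fluorophore-only species at the reference concentration (positive control,
the 100%-substitution signal). Calibration traces are reduced to
time-averaged scalars: this is robust to instrument jitter and makes the
normalization exactly invariant under any affine detector rescaling
a·F + b (a > 0). Normalized values are deliberately not clipped to [0, 1]
before fitting; clipping would bias the noise distribution near the
endpoints. Replicates are aggregated pointwise (mean, sample SD with n−1).

## Synthetic data

The generator emulates the measurement protocol: samples every 10 s for
90 min (541 points), three replicates per system, baseline and positive-
control trace sets alongside the reaction traces. Noise is additive i.i.d.
Gaussian on the intensity scale with SD equal to 2% of the dynamic range
f100 − f0 by default — shot noise at high photon counts is approximately
Gaussian, and the true instrument noise level of a given fluorometer is
unknown, so 2% is a declared, realistic choice rather than an inferred one. A linear drift
term (default 0) exists purely to stress-test the normalization. The same
seed regenerates a dataset bit for bit.

What a green synthetic-recovery test does *not* establish: robustness to
leak reactions, truncated strands, gate mis-hybridization, photobleaching,
or correlated instrument noise — none of which the generator produces.

## Rate estimation

(ka, kd) are estimated by unweighted least squares on the mean normalized
time course, with the analytic progress curve as the model. Optimization
runs in log10 parameter space within bounds [1e-8, 1] nM⁻¹ s⁻¹: the
residual surface is nearly flat along the dominated direction when one
rate exceeds the other by ~two decades, and log-space multi-start (a 5×5
log-grid of starting points, 25 starts; trf with xtol = ftol = gtol =
1e-10) is the cheap way to avoid the flat-valley local minima. Either
parameter can be clamped (e.g. to the theoretical rate) and only the free
one optimized. If no start converges the result is an explicit
non-converged `FitResult`, not an exception. Inverse-variance weighting by
the replicate SD is available but off by default.

Estimates are compared with the theoretical lumped rate for the toehold
length (5.0e-4 nM⁻¹ s⁻¹ at 6 nt) as unitless ratios, rounded to two
significant figures in reports (full precision retained internally).
Report tables also carry the equilibrium substitution percentage the
fitted rates predict at equal 10 nM initials, rounded to the nearest
percent.

## Default operating point

x1₀ = x2₀ = 10 nM, x3₀ = x4₀ = 0. Under equal initials the equilibrium
substitution ratio is concentration-invariant (tested at 1, 10 and
100 nM), so every steady-state quantity reported here is insensitive to
this choice.

## Design choices that were genuinely open

- **Fit raw fluorescence or the normalized ratio?** The pipeline fits the
  normalized ratio: it is the quantity of scientific interest and
  normalization removes the two nuisance parameters f0, f100.
- **Loss, optimizer, initialization** have no single canonical choice for
  this problem; the defaults above (unweighted SSR, multi-start trf in
  log space) are declared in `FitOptions` and easy to override.
- **Pre-reaction stabilization window**: real measurements include a
  ≥120 s stabilization segment before the reaction starts; the fit
  supports excluding a leading segment via `fit.exclude_before_s`, and the
  generator does not emulate the segment.

## Known limitations

- Lumped one-step kinetics cannot represent transient toehold-occupancy
  effects; sequences, thermodynamics and secondary structure are metadata
  only.
- The noise magnitude and drift of a real fluorometer are declared
  defaults, not fitted ones.
- When one rate dominates by more than ~50×, the dominated rate is weakly
  identifiable from a single time course; its recovery tolerance is
  explicitly widened (0.15 vs 0.05 in log10) in the tests rather than
  hidden.
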