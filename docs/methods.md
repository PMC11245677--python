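# Methods

## Model

The oscillator is the two-variable delayed-autorepression system

    dp/dt = a·m(t − T_p) − b·p(t)
    dm/dt = k / (1 + (p(t − T_m)/p_crit)^n) − c·m(t)

with continuous (real-valued) molecule counts — the model is
deterministic; no demographic noise, no cell–cell coupling, no wavefront.
`n = 2` throughout (the repressor acts as a dimer). `b = ln2/h_p` and
`c = ln2/h_m` tie the rate constants to half-lives, which is how the
biology is usually reported.

Default kinetic constants: `a = 4.5` protein/mRNA/min, `k = 33`
mRNA/min/cell, `h_m = 3` min, `h_p` swept over 3–22 min (typical reported
clock-protein stabilities), `p_crit` from nuclear volume at 10⁻⁹ M
(161 molecules for the 4-µm frog nucleus, 420 for the 5.5-µm axolotl
nucleus).

## Delay derivation

Delays are carried in minutes. `T_tx` = primary transcript length at
20 nt/s; `T_p` = CDS length at 6 nt/s; `T_in` = 8.3% of the species clock
period (the empirically near-constant splicing share); `T_exp` from the
export simulations. Components are quantised to 0.01 min (round half away
from zero, via `Decimal` so exact rational ties such as 783/360 = 2.175
round up) before summing, so assembled totals match the reported working
precision; unrounded values remain available from the individual
functions. `p_crit` is kept continuous in the Hill function and rounded
only for reporting; the grid/sensitivity baselines use the integer values
(161/420) the analyses quote — a <0.1% effect on any period.

When a sweep varies the *total* delay, `T_p` stays at the species value
and the mRNA-side components are rescaled proportionally. The dynamics
depend on the delays only through `T_m` and `T_p` separately, and in fact
only on their sum (verified as a test invariant), so the split is pure
bookkeeping.

## DDE integration

Fixed-step classical RK4 with the method of steps: state and derivative
are stored at every node and delayed values are read back by cubic
Hermite interpolation of that dense history (numba-compiled kernel).
Default step 0.02 min over a 3100-min span. A fixed step makes runs
bit-reproducible and convergence checkable by halving — at the axolotl
baseline, halving the step moves the extracted period by <0.1%, far below
every tolerance used. Steps larger than one tenth of a positive delay are
rejected; exactly-zero delays collapse the delayed lookup onto the
current RK stage value, which is the classical ODE RK4 limit, handled
exactly. Pre-history is constant (default the empty cell, m = p = 0);
extracted periods are history-independent after transient removal, which
is tested. Non-finite states abort with the offending time stamp.

## Period and amplitude protocol

Extrema-based, not spectral, mirroring how the trajectories are read in
practice. Local extrema of the sampled trace are located by slope sign
change, plateaus resolving to their midpoint sample; no sub-sample
interpolation (at 0.02-min steps the induced error is ≪0.1 min). A cycle
is the interval between successive local minima. The first 5 cycles are
discarded as transient; the period is the mean gap between the remaining
minima; the amplitude of a cycle is the rise from its minimum to the
following maximum. If fewer than two minima remain, or any retained
cycle's amplitude falls below 10 molecules, the trace is classified
damped: period = +inf, amplitude = 0. The threshold applies per cycle
("robust throughout the span"), not to the mean. mRNA is the reporting
variable; the protein trace gives the same period to within 0.2 min
(asserted), and anchoring cycles on maxima instead of minima gives the
same result (asserted).

## Export-time simulation

Each mRNA is a 3-D random walk in a sphere; the export delay is the first
step (1 s each) at which the walker's distance from the centre exceeds
the nuclear radius — strict crossing, no within-step interpolation, pore
transit neglected (sub-second). Normal diffusion uses i.i.d. Gaussian
increments; obstructed diffusion uses fractional Gaussian noise with
H = 0.25 (α = 2H = 0.5, mid-range of reported nuclear subdiffusion
exponents), generated by Davies–Harte circulant embedding with a Cholesky
fallback and oracle. Only the increment covariance matters for exit-time
statistics, so the choice of fGn generator is immaterial beyond cost.

**Calibration.** The spatial step scale (µm per unit increment) is set per
diffusion mode so that a centre-start walker leaves a 3-µm sphere in 3.36
min (~202 steps) on average. A pilot ensemble of unit-scale walks is
simulated once; because each walk's running-maximum distance is
monotone, the mean exit step count is a monotone function of the exit
threshold, and the threshold is found by bracketed root-finding on the
pilot ensemble (tolerance 2%, default pilot 2× the production ensemble
up to 10,000 walks). Scaling space at a fixed 1-s step is equivalent, for
mean exit times, to scaling time at a fixed step length, and keeps the
"202 steps ≈ 202 s" identity.

**Horizons and exclusions.** Brownian walks are simulated blockwise with
early stopping, capped at 10⁷ steps. Fractional paths cannot be extended
blockwise without breaking the increment covariance (exact conditional
extension is O(n²)), so they are simulated at a fixed horizon sized
empirically: a 256-walk pilot at a generous MSD-based horizon, then the
production ensemble at twice the pilot maximum (≥6× the pilot mean,
power of two). Walkers that have not exited by the horizon are excluded
and counted; at the radii used here the exclusion count is zero to
negligible (asserted <1% in tests) and far below Monte-Carlo error.

**Start rules.** Centre start is the default (clock genes sit on
centrally located chromosomes). The alternative draws starts uniformly
from the ball of radius ¾r — rejection sampling from the enclosing cube,
since independent per-axis uniforms would put corner starts outside the
sphere. Calibration always anchors on centre starts.

**RNG.** Increments are drawn vectorised from one PCG64 stream per job,
with independent child streams per radius in sweeps; results are
bit-reproducible for a fixed seed and trajectory count. (Per-trajectory
streams would survive trajectory-count changes but forfeit the batched
generation that keeps 10,000-walk ensembles in seconds.)

**Fixed inputs.** The tabulated export delays (6.39/11.97 min normal,
8.36/26.27 min obstructed) parameterise the DDE stage as fixed inputs.
Freshly simulated estimates are computed and reported alongside; the two
are not forced to agree, because the published per-radius scaling cannot
be reproduced exactly from the stated protocol and the DDE conclusions
depend only on the tabulated values.

## Linear stability

The steady state solves the scalar monotone equation
p* = (a/(bc))·f(p*) (bracketed root-find); m* = f(p*)/c. Linearising
gives the characteristic equation (λ+b)(λ+c) = g·e^(−λT) with
g = a·f′(p*) < 0 and T the total delay. A purely imaginary root needs
|g| > bc — equivalently the geometric mean √(bc) of the degradation
rates below the gain-implied bound — and then

    ω² = [−(b²+c²) + √((b²+c²)² − 4(b²c² − g²))]/2,
    T_crit = (π − atan(ω/b) − atan(ω/c))/ω

is the smallest delay with a crossing; |g| ≤ bc means stability for every
delay (T_crit = +∞). The derivation here is the standard linearisation
route, implemented numerically and verified by simulation on both sides
of the threshold: T_crit rises with protein half-life, trajectories decay
at 0.85·T_crit and grow at 1.15·T_crit, and the simulated period just
above threshold matches 2π/ω within 5%.

## Experiments and problem sizes

Grids are 21 × 20 by default (total delay ± 5 min in 0.5-min steps ×
protein half-life 3–22 min in 1-min steps; the resolution resolves the
capture bands at desk-scale cost), each cell one 3100-min integration at
step 0.02. Capture tolerance is ±2 min around the observed period (56 or
154 min), configurable. The sensitivity analysis perturbs each of
{a, k, p_crit, h_m, h_p, total delay} by ±50% around the axolotl
normal-diffusion baseline with h_p = 15 min and reports
100·|ΔP|/P_base, with damping reported categorically. The
mRNA-stability scenarios re-run the axolotl grids at h_m = T_exp,
T_exp/2, T_exp/4 using the diffusion-specific tabulated export delay
(¼·26.27 = 6.5675 min is used as computed). The nuclear degradation
fraction is 1 − 2^(−T_exp/h_m) (50%/75%/93.75% for the three scenarios);
a distribution-based expectation 1 − E[2^(−T/h_m)] over a simulated
exit-time ensemble is exposed alongside, and is the smaller of the two
for skewed ensembles since survival is convex in T.

## Synthetic fixtures

Fixtures exist to give every stage a known ground truth, not to imitate
biology: gene models with explicit UTR padding so primary lengths can be
matched exactly; offset (optionally damped, noisy) cosines with recorded
period/amplitude for the metrics stage — additive Gaussian noise only,
since the model itself is deterministic, so these test estimator
robustness, not dynamics; and radius/diffusion-coefficient pairs carrying
their analytic r²/6D expectation. Passing fixture tests therefore
demonstrates correctness of the machinery on idealised signals; real
trajectories differ in ways the fixtures deliberately omit (relaxation
waveforms, slow transients), which is why the grid tests run the actual
model as well.

## Known limitations

- Single-cell, deterministic: no coupling, noise, or posterior period
  gradient; conclusions concern the cell-autonomous oscillator only.
- Obstruction is represented solely by the Hurst exponent; no explicit
  chromatin geometry, and H = 0.25 is taken from other cell types.
- The exit-time ensemble for fractional walks carries a truncation
  horizon; its exclusion tail is logged and negligible here but would
  need care at radii ≫ 6 µm with H ≪ 0.5.
- The splicing delay is a fixed fraction of the observed period, so it is
  an input anchored to phenomenology, not a mechanistic prediction.
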