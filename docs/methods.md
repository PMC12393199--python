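# Methods

## Model and scope

The package propagates the magnetization of a spin-1/2 isochromat under
shaped RF pulses in the rotating frame, with relaxation neglected. The
state is the 3-vector `M` in units of the equilibrium magnetization M0;
its norm `|M| ∈ (0, 1]` is a constant of the motion. The driving field
is `w1(t) = wAM(t) e^{i phi1(t)}` and the dynamics are
`dM/dt = a × M`, `a = -(wAM cos phi1, wAM sin phi1, Omega)`, where
`Omega = w0 - wc` is the resonance offset (rad/s). The phase convention
throughout is `d(phi1)/dt = +wFM(t)`: the pulse phase is the running
integral of the frequency-modulation function, so positive `A` (HS1 and
chirp) sweeps the instantaneous frequency upward through resonance.

Three driving-function families have exact solutions here — HS1
(sech/tanh), chirp (constant amplitude, linear sweep), square — plus
composites chained from them. Everything else (arbitrary AM/FM shapes,
relaxation, multidimensional or second-rotating-frame pulses) is out of
scope.

## The Riccati route to closed forms

Stereographic projection `f = (Mx + iMy)/(|M| + Mz)` maps the state
sphere onto the extended complex plane; the Bloch equation becomes the
Riccati equation `df/dt = (i/2)w1 - i Omega f - (i/2)conj(w1) f^2`. The
logarithmic substitution `ln q = (i/2)∫ conj(w1) f dt` linearizes it to a
second-order ODE for `q`, and a driving-function-specific time
reparameterization makes that ODE classical:

* **HS1**: with `p = (1 + tanh((2 beta/Tp)(t - tc)))/2 ∈ (0,1)` the
  equation is hypergeometric with parameters
  `a = (Tp/4beta)(-iA + sqrt(w1m^2 - A^2))`,
  `b = (Tp/4beta)(-iA - sqrt(w1m^2 - A^2))`,
  `c = 1/2 + i(Tp/4beta)(Omega - A)` (principal square root). The
  sign of the `iA` terms is tied to the `+wFM` phase convention above;
  flipping both reproduces the same physics. With `A = 0` these reduce
  to real `a = -b = Tp w1m/(4 beta)` and `c = 1/2 + i Tp Omega/(4 beta)`.
  The fundamental pair about `p = 0` is the Gauss series
  `FA = 2F1(a,b;c;p)` and `FB = p^{1-c} 2F1(a-c+1,b-c+1;2-c;p)`; because
  `Re(c) = 1/2` exactly, no degenerate (integer-parameter) cases of the
  hypergeometric equation can occur for any physical parameters.
* **Chirp** (`A ≠ 0`): with the complex time
  `p = sqrt(iA/Tp)(t - tc + Tp Omega/(2A))` the equation is
  `q'' + 2pq' + 2(a+1)q = 0` with order
  `a = -1 - i Tp w1m^2/(8A)`. The basis is the even confluent
  solution `FA = 1F1((a+1)/2; 1/2; -p^2)` and the Hermite function
  `H_a(p)` carrying an `e^{-p^2}` factor. Both branches are verified by
  residual substitution into the ODE at random complex points
  (relative residual < 1e-20 at working precision) and by Abel's
  identity for their Wronskian.
* **Square** (`A = 0`, constant phase): elementary solution
  `f = e^{i phic}/w1m (-Omega + weff tanh(C + (i/2) weff t))`,
  `weff = sqrt(Omega^2 + w1m^2)`. A chirp with `A = 0` dispatches here
  automatically (the chirp reparameterization divides by `A`).

In all cases `f(t)` is a Möbius-type ratio parameterized by one complex
constant `C`, fixed without approximation by the orientation at any
single time. The constant is stored as a projective pair `(CA : CB)` so
anchors at the south pole (`f = ∞`) and vanishing denominators are exact
rather than overflow hazards; trajectories are converted back to `M`
through a homogeneous form of the inverse projection that is stable on
the whole sphere.

## Numerical choices

* **Working precision.** Hypergeometric/Hermite values are computed with
  mpmath at 30 significant digits by default (configurable per solver
  context); magnetization is emitted in double precision. The headroom
  covers series cancellation in the `p → 1` tail, where mpmath's
  built-in analytic continuation (its internal `z → 1-z` connection
  formulas) is relied upon rather than hand-rolled transformations.
* **Branches.** Principal square root in the HS1 parameters and in
  `sqrt(iA/Tp)`; `p^{1-c}` is `exp((1-c) ln p)` with real `ln p` —
  single-valued on `(0,1)`, so no branch crossing can occur during a
  pulse. The square-pulse `artanh` uses its principal branch; its `i pi`
  ambiguity is a period of `tanh` and is irrelevant to trajectories,
  but constant-of-motion comparisons reduce constants to a common
  branch (`align_square_constants`). Anchors landing within 1e-10 of an
  `artanh` branch point (magnetization exactly along the effective
  field, a fixed point of the motion) are rejected with
  `BranchPointError` instead of being silently perturbed.
* **Pole policy.** `project` switches to the point at infinity when
  `|M| + Mz < 1e-12 |M|`; for `Mz < 0` the denominator is computed
  through the cancellation-free identity `(Mx^2+My^2)/(|M| - Mz)`.
* **Angular error.** Discrepancies are reported as the angle between
  vectors, computed as `atan2(|M1 × M2|, M1·M2)` — frame-independent,
  symmetric, and accurate down to the round-off floor (the arccos form
  loses everything below ~1e-8).
* **Magnetization container.** Only a positive norm is enforced on the
  type itself; the physical bound `|M| ≤ M0` is enforced where states
  enter as physical inputs (the fixture generator). Coarse RK4 runs
  legitimately overshoot `|M| = 1` by their O(h^4) error and must remain
  representable for convergence studies.

## SIT closed form

For `A = 0`, `Omega = 0` the motion is a rotation about a fixed axis by
the accumulated pulse area, and the general solution with `C = 0`
collapses to `f = i tan(2a arcsin sqrt(p))`, i.e. polar angle
`theta(t) = (w1m Tp/beta) arctan(e^{(2beta/Tp)(t-tc)})`. The package
reports this **absolute** angle: it is the ideal *untruncated* sech-pulse
trajectory, which reaches exactly +z at the end of a 2π pulse
(`sit_amplitude` returns `w1m = 2 pi beta/(Tp arctan e^beta)`). The
truncated, equilibrium-anchored solution deviates from it by the initial
tilt `theta(t_start) ≈ 2 × truncation`; the two converge as the
truncation shrinks, which is the meaningful convergence statement — a
"relative angle" convention would make the closed form coincide with the
equilibrium-anchored solution identically (both are exact rotations by
the same area) and turn the comparison into round-off noise. By the same
area argument, the equilibrium-start 2π pulse ends
`2π arctan(e^{-beta})/arctan(e^{beta}) ≈ 2 × truncation` away from +z:
about 2.0e-3 rad at 0.1% truncation, scaling linearly to zero with the
truncation level.

## BIR-4 construction

The composite is four asymmetrically truncated half-HS1 segments, each
of duration `Tp/2`, with amplitude peaks at the composite start, middle
and end and the frequency sweep following the component's tanh branch
within each half. The flip-angle-setting phase offsets `pi + theta/2`
are applied to the two middle segments (phase jumps at the quarter and
three-quarter points), returning to zero for the last segment. The
printed sources describe the construction only in prose; this layout
follows the original B1-insensitive-rotation convention, and its net
rotation was verified against RK4 (equilibrium start, adiabatic
parameters: final `Mz ≈ cos theta` to a few percent). Analytic
propagation chains the particular constants segment-to-segment using the
full-working-precision projective orientation at each junction, so
junction jumps sit at the double-precision floor (< 1e-14 rad measured)
and no error accumulates across segments.

## RK4 reference

The verification oracle is the classic fixed-step RK4 scheme with the RF
field sampled at the half-step stage times (required for fourth order
with time-dependent fields). Composite pulses are integrated segment by
segment with steps allotted proportionally to duration, so field
discontinuities fall on step boundaries and each step sees a smooth
integrand — otherwise the junction phase jumps degrade convergence to
first order locally. Requested evaluation times snap to the nearest
grid point. Against every analytic solver the final angular error falls
as `steps^-4` (measured log-log slopes −4.0 ± 0.2 over 1e2–1e5 steps)
until it hits the double-precision floor near 1e-14 rad; RK4's norm
drift at 1e4 steps is below 1e-10.

## Problem sizes used in validation

The test suite and the acceptance script compare trajectories at
500–1000 uniformly spaced sample points per pulse, use 1e4-step RK4
references for trajectory-mean errors (1e5–1e6 steps for convergence
floors and constant-of-motion studies), 100 randomized parameter draws
for the square-pulse/rotation-oracle equivalence, and 1e4 random
orientations for projection round-trips. These sizes put the RK4
reference error orders of magnitude above the analytic solver's own
floor, so the measured discrepancies characterize the integrator, not
the closed forms.

## Known limitations

* Relaxation is absent by construction; trajectories are exact only on
  the timescale where T1/T2 effects are negligible.
* The chirp solver's Hermite-function evaluations grow expensive for
  very large `|p|` (extreme `Tp Omega / A`); precision can be raised per
  context if needed.
* `sit_closed_form` describes the on-resonance, no-sweep case only.
* The square solver requires `w1m > 0`; free precession is a rotation
  about z and needs no solver.
* Only the HS1/chirp/square families and composites of them are
  supported; arbitrary user-supplied AM/FM shapes are not.
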