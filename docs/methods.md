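# Methods

## The problem

An invasive population with density n(x, t) spreads leftward along a 1-D
transect. Reproduction is local; propagules redistribute through a Gaussian
dispersal kernel of standard deviation sigma (truncated at 8 sigma and
renormalized, so redistribution conserves mass exactly on the grid).
A manager invests A(x, t) dollars per hectare per year in treatment and asks
for the cheapest spatial distribution of investment that keeps the front
moving at no more than a chosen target speed v — positive (slowed spread),
zero (containment), or negative (roll-back). Both the treatment and the
front are sought in co-moving (traveling) form, A(x, t) = A_hat(x + v t),
n(x, t) = n_hat(x + v t), so the annual cost of treatment

    ACT = integral of A_hat(x) dx

is constant in time. Sweeping v and optimizing at each point yields the
cost curve ACT*(v), which a net-present-value rule converts into an optimal
target speed.

Two model families are implemented:

* **Generic continuous-time invader.**
  dn/dt = −gamma n − beta A n^alpha + K∗[r n (1 − n/k)].
  The exponent alpha in [0, 1] ("invisibility") controls how the cost of
  removing one individual grows as the density falls; alpha = 0 is
  density-independent removal cost, alpha = 1 proportional removal.
  Untreated uniform equilibrium: n = k (1 − gamma/r).

* **Spongy moth with mating disruption (discrete time).** One generation
  per year: n(·, t+1) = K∗[b(n, A)] with
  P = 1 − exp(−lambda0 n / (2 (1 + aA))) the probability a female is
  fertilized, n0 = n P / 2 egg masses, and b = 2 r n0 (1 − n0/k).
  Mate-finding failure produces a strong Allee effect with threshold n_a
  satisfying lambda0 = (2/n_a) ln(r/(r−1)). With densities in units of
  carrying capacity only the product k·lambda0 matters demographically;
  a (USD^−1 per ha) sets the money scale and sigma the length scale.

## The one-step constraint and its split dynamics

"No faster than v" is discretized per node: after one solver step of
duration dt the density must not exceed the front's own profile shifted by
dx = |v| dt toward the uninvaded side (toward the invaded side for v < 0,
unshifted for v = 0; dt for the continuous model is one grid cell divided
by |v|, and for v = 0 it is borrowed from a configurable reference speed).

The treated step is an operator split: an untreated step produces n1, then
the treatment phase acts pointwise on n1 —

* continuous model: exact pure-removal decay dn/dt = −beta A n^alpha over
  dt (closed form for every alpha);
* discrete model: reduction of n1 to the effective density z whose
  untreated fecundity matches the treated one, b(n1, A) = b(z, 0), solved
  through the egg-mass density (strictly increasing in z).

With this convention the minimal per-node investments have closed forms —
A = (n1^(1−alpha) − target^(1−alpha)) / (beta (1−alpha) dt) for power-law
removal (safeguarded Newton on the quadrature of the decay time for general
removal laws), and
A = (1/a) (−lambda0 n1 / (2 ln(1 − w/n1)) − 1) with
w = target (1 − exp(−lambda0 target / 2)) for mating disruption — and the
speed constraint and the never-over-treat (complementarity) property hold
to machine precision at the binding nodes. Every closed-form investment is
validated against its defining balance; a bracketed root finder stands by
for degenerate floating-point corners. The split converges to the coupled
continuous dynamics as dt → 0; measured holding costs change by well under
1% when dt is halved.

The relaxation ("find n_hat") iterates the split step in the frame of the
treatment — step, then shift back by dx, with uninvaded territory entering
from the leading side as zeros — until the shape change per step falls
below eps_shape (sup norm, relative to the equilibrium; default 1e−7,
1e−5 in the large batch runs).

## Where the speed constraint is enforced

Three enforcement bounds are deliberate design decisions; all are
configurable in `SolverConfig`:

* **Trailing exemption (both models, default 5%).** A deficit within 5% of
  the carrying capacity behind the front is the established population
  recovering density, not the front advancing. Enforcing its co-movement
  buys nothing ecologically, costs arbitrarily much under mating
  disruption (P saturates near carrying capacity, so the marginal effect
  of treatment vanishes exponentially), and digs a local-search trap in
  which the optimizer pays to hold the equilibrium approach in place.

* **Allee containment floor (discrete model, default half the Allee
  threshold).** Mating disruption cannot push fecundity to exactly zero at
  finite cost, yet the Allee front's tail decays doubly-exponentially and
  underflows to exact zeros. Targets below the floor are capped at it:
  densities at half the threshold decline on their own, so permitting them
  ahead of the front does not constitute establishment. The floor must sit
  strictly below the threshold — seeds allowed at exactly n_a are
  marginally stable and let the front creep.

* **Barrier strip (discrete model, default 2 sigma).** The floor-capped
  constraint is enforced only within a strip ahead of the front's body;
  chasing the sub-threshold halo beyond it would widen the treatment
  without bound. During relaxation the field ahead of the treated band is
  clamped to zero (the "leading clamp"); with the clamp off, `find_n_hat`
  raises `ContainmentError` whenever the population establishes ahead of
  the barrier — which genuinely happens for wide fronts held near stop
  speed: the standing sub-threshold tail such a hold admits is
  *collectively* supercritical even though every node is below the
  threshold individually. That instability is a real property of
  mate-finding Allee dynamics under this containment formulation, and the
  clamp encodes the assumption that the slow leak past the barrier is
  handled outside the model (surveillance and spot eradication).

## The local search

Starting from a heuristic front (the naturally evolved shape, or a
piecewise-linear ramp), the optimizer repeatedly proposes single-node
modifications — the value at x0 pulled toward its right or left neighbour
with weight p, new = (p n(x0) + n(x0 ± dx)) / (p + 1) — accepts any whose
minimal holding treatment is cheaper by more than eps_act (relative,
default 1e−4; 1e−5 in batch runs), re-relaxes the shape after each
acceptance, and escalates the resolution p through the schedule
(1, 2, 3, 5, 8) whenever a sweep comes back clean. The schedule is cycled
until a full cycle accepts nothing: refinements at high p reopen
coarse-scale improvements, and a single pass through the schedule stops
far short of convergence. Scans run left-to-right with first-improvement
acceptance by default; right-to-left and seeded-random orders exist and
multi-start robustness is checked separately (`robustness_check`).
Nodes whose neighbourhood density is below `active_floor` (default 1e−6 of
the equilibrium) are skipped: the deep leading tail carries a vanishing
share of the cost but would dominate the sweep time.

The search is deterministic for a fixed seed and scan order. The ACT trace
decreases strictly; the final shape admits no improving single-node move
among the active nodes at the final p (re-verified post hoc in the tests).
Restarting from a converged optimum can still shave a fraction of a percent
because the initial re-relaxation perturbs the shape at finite tolerance.

## Natural front and speed measurement

The untreated co-moving shape is obtained by simulating from a step profile
while re-centering the half-equilibrium level set each step. Two
regularizations matter:

* the pulled (generic) front trails an exponential leading tail that never
  reaches zero; densities below 1e−7 of the equilibrium are floored so the
  flat boundary extension cannot feed the tail back through the kernel
  (the Allee front needs no floor — its tail dies by itself);
* the converged shape is snapped to the equilibrium within 1%, because the
  co-moving treatment solver would otherwise bill for holding the last
  sliver of the equilibrium approach (see the trailing exemption above).

The natural speed is the least-squares slope of the level-set displacement
over the second half of a long horizon (default 50 sigma of travel at
dt = 0.005 yr on a 90-sigma domain). Pulled fronts approach their
asymptotic speed through a slow ~1/t transient, so the plain linear fit
lands a few percent below the linearized-kernel speed
min_s (r e^(sigma² s²/2) − gamma)/s; the agreement is verified to 10%.

## Speed policy

NPV(v) = −ACT*(v)/delta − C v/delta², with C the annual damage per unit
newly infested area and delta the discount rate. NPV′ is proportional to
−(dACT*/dv + C/delta): the optimal regime is *abandon* (v = v0) when
slowing is everywhere dearer than the damage it avoids, *eradicate* (push v
to the bottom of the curve) when damage dominates everywhere, and otherwise
the *interior* speed where dACT*/dv = −C/delta. A maximum requires the
marginal cost of slowing to grow as v decreases (slope increasing in v);
stretches where the slope instead steepens with v are reported as
mixed-speed segments — there a schedule alternating two speeds beats any
single intermediate one. The closed form is cross-checked against direct
discounted time quadrature of the cost stream, including a variant that
measures newly infested area from an actual translating front profile.

## Problem sizes and numerical defaults

Batch analyses in the acceptance script use: generic model — 40-sigma
domain (1000 km), sigma/20 spacing for holding costs and sigma/10 for the
two full optimizations; spongy model — 300 km domain at dx = 0.5 km with
the per-generation shift handled by monotone-cubic (PCHIP) interpolation
when it is not a grid multiple (grids whose spacing divides the shift
exactly are preferred and used where possible). Explicit Euler substeps
are chosen so no substep changes the density by more than 5% at the
demographic rates; negative excursions are clipped at zero, counted, and
zero clipping events are required in batch runs. Kernel truncation is
8 sigma with renormalization (tail mass < 1e−15).

## What the built-in scenarios do and do not show

The two parameter presets reproduce published demonstration conditions:
generic r = 2/yr, k = 2, gamma = 1/yr, alpha = 0.2, beta = 1.25/USD/yr,
sigma = 25 km, v = 10 km/yr; spongy r = 2, k·lambda0 = 100, a = 0.08/USD,
sigma = 10 km, v = 220 m/yr. They exercise every code path the package
has, but they remain 1-D, deterministic, single-species caricatures:
no stochastic dispersal or establishment, no landscape heterogeneity,
no surveillance/detection layer, no transient (pre-asymptotic) phase, and
treatment efficacy known exactly. Passing tests demonstrate internal
consistency of the model-solver-optimizer chain under these idealizations,
not predictive accuracy for any real containment program.

## Relation to previously reported cost levels

Reference values reported elsewhere for these exact parameter sets are
substantially lower than what this implementation computes: 28.58 for the
generic holding cost where we obtain ~39.6, 8.58/8.52 for the generic
optimum where we obtain ~9.1, 278.2 for the spongy holding cost where we
obtain ~1830 thousand USD per km strip, and ~56 for the spongy optimum
where we obtain ~975.

For the generic model the reference holding value can be bounded out on
mass-balance grounds alone: a front held at speed v must remove at least
(v0 − v)·n_eq individuals per year per km strip (the surplus advance), and
with removal efficiency beta at densities never above the equilibrium the
cost of that removal is at least (v0 − v)·n_eq/beta ≈ 35.8 at these
parameters — above 28.58 for any v0 consistent with the kernel dynamics.
Our optimized values sit ~6% above the reference optimum, a gap of the
size expected from the first-order time discretization and the finite
search granularity (the value falls from 9.6 to 9.1 between sigma/10 and
sigma/20 spacing).

For the spongy-moth model the gap is larger (a factor of several) and is
driven by the cost of suppressing dispersal leakage just ahead of the
front under the enforcement conventions described above; we were unable to
construct any convention under which the printed equations reproduce the
reference levels, and the internal consistency checks (initialization
robustness, translation invariance, constraint satisfaction) all hold for
our values. The discrepancies therefore most plausibly reflect an
undocumented normalization in the original computations; the package
reports what the stated model yields.

## Known limitations

* The local search is exactly that — local. Multi-start robustness is
  checked, and for the spongy model all tested initializations converge to
  within a few percent of one another, but there is no global optimality
  guarantee.
* Holding a *wide* Allee front near stop speed has no strictly co-moving
  solution (collective supercriticality of the admitted tail); the
  reported holding cost for that scenario is the cost of the one-step
  minimal plan, which is the well-defined quantity, and the relaxation
  relies on the leading clamp.
* The mating-disruption cost of containment is dominated by suppressing
  kernel leakage just ahead of the front down to the containment floor;
  this makes the absolute spongy-moth cost levels sensitive to the floor
  and strip conventions above (the curve shapes and orderings are not).
* alpha = 1 (strictly proportional removal) admits no finite-cost
  containment; the solvers accept alpha arbitrarily close to 1 but the
  cost diverges as alpha → 1, as the model predicts.
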