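"""Minimal treatment holding a front at a target speed, and its relaxation.

Given a front shape ``ntilde`` and a signed target speed ``v`` (positive =
slowed leftward spread, zero = containment, negative = reversal), the solver
computes the cheapest investment profile ``A_hat`` such that one step of the
dynamics never advances the front past its target position, and relaxes any
(front, treatment) pair to the co-moving shape ``n_hat`` it sustains.

The one-step contract is an operator split: an untreated step produces
``n1``, and the treatment phase then reduces ``n1`` pointwise toward the
shifted target — by exact pure-removal decay in the continuous model, and by
an effective-density reduction (matching untreated fecundity) in the
discrete model.  The per-node investments come from closed forms (validated
against their defining balance equations) with a safeguarded root-finding
fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator

from .model_core import (
    DensityProfile,
    GenericParams,
    Kernel,
    SpatialGrid,
    SpongyParams,
    TimeStepping,
    TreatmentProfile,
    egg_masses,
    gaussian_kernel,
    removal_rate,
    step_continuous,
    step_discrete,
)

__all__ = [
    "SpeedTarget",
    "ContainmentError",
    "SolverConfig",
    "shifted_target",
    "free_step",
    "solve_A_discrete",
    "solve_A_continuous_power",
    "solve_A_newton",
    "find_A_hat",
    "find_n_hat",
    "treated_step",
    "act",
    "act_per_km_strip",
    "THOUSAND_USD_PER_KM_STRIP",
]

logger = logging.getLogger(__name__)


class ContainmentError(RuntimeError):
    """The population escaped ahead of the treatment during relaxation.

    Raised when no co-moving front exists for the supplied treatment: the
    standing sub-threshold tail the treatment admits is collectively
    supercritical (its integrated reproduction plus leakage from the core
    exceeds what the Allee effect can absorb) and the population establishes
    ahead of the barrier.
    """

#: ACT unit conversion for profiles in USD/ha over x in km: a 1-km strip has
#: 100 ha per km of front, and the spongy-moth figures report thousands of
#: USD, so multiply the raw integral by 100/1000.
THOUSAND_USD_PER_KM_STRIP = 0.1


@dataclass(frozen=True)
class SpeedTarget:
    """Target propagation speed and its discrete comparison step.

    v         signed speed (km/yr); positive fronts still advance leftward,
              zero is containment, negative reverses the invasion.
    dx_shift  spatial comparison shift |v|*dt (one generation's displacement
              for the discrete model, one grid cell by default for the
              continuous model).
    dt        duration of one solver step (1 for the discrete model,
              dx_shift/|v| for the continuous model; for v = 0 continuous a
              reference speed supplies dt since dx/v is undefined).
    """

    v: float
    dx_shift: float
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dx_shift < 0:
            raise ValueError("dx_shift must be >= 0")
        if self.v != 0 and self.dx_shift == 0:
            raise ValueError("moving targets need a positive dx_shift")

    @property
    def direction(self) -> str:
        return "forward" if self.v > 0 else ("stop" if self.v == 0 else
                                             "reverse")

    @classmethod
    def for_discrete(cls, v: float) -> "SpeedTarget":
        """Discrete-time target: one generation per step, shift |v|."""
        return cls(v=v, dx_shift=abs(v), dt=1.0)

    @classmethod
    def for_continuous(cls, v: float, grid: SpatialGrid,
                       v_ref: float | None = None) -> "SpeedTarget":
        """Continuous-time target: shift one grid cell, dt = dx/|v|.

        For v = 0 the comparison is unshifted and dt comes from ``v_ref``
        (default: the dispersal length per year), the speed whose one-cell
        step duration is borrowed; converged costs are insensitive to it.
        """
        if v != 0:
            return cls(v=v, dx_shift=grid.dx, dt=grid.dx / abs(v))
        if v_ref is None or v_ref <= 0:
            raise ValueError("v = 0 requires a positive reference speed "
                             "v_ref to set dt")
        return cls(v=0.0, dx_shift=0.0, dt=grid.dx / v_ref)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the per-node solvers and the relaxation.

    The two Allee-model enforcement parameters bound where the discrete
    model's speed constraint is applied.  ``allee_floor`` caps the target
    density from below at that fraction of the Allee threshold: densities
    below the threshold decline on their own, so one-step outcomes there do
    not constitute establishment, and fecundity targets of exactly zero are
    unreachable by mating disruption at any finite cost.  The floor must be
    strictly below the threshold (fraction < 1): seeds allowed at exactly
    the threshold are marginally stable and would let the front creep.  ``trailing_tol``
    excludes targets within that fraction of the carrying capacity: the
    fertilization probability saturates at high density, so the marginal
    effect of mating disruption vanishes exponentially there and "holding"
    the equilibrium-recovery zone behind the front would cost arbitrarily
    much while representing density recovery, not forward spread.  The
    floor applies to the discrete model only (power-law removal has no
    saturation); the trailing exemption applies to both models.
    """

    newton_tol: float = 1e-10
    newton_max_iter: int = 100
    eps_shape: float = 1e-7     # sup-norm shape tolerance, relative to eq
    max_relax_steps: int = 20000
    validate_tol: float = 1e-8  # closed-form residual check, relative
    allee_floor: float = 0.5    # target floor, fraction of Allee threshold
    trailing_tol: float = 0.05  # skip targets above (1 - tol) * equilibrium
    leading_clamp: bool = True  # pin the far field ahead of the treatment
    barrier_width_sigma: float = 2.0  # enforced strip ahead of the foot


def _shift_values(values: np.ndarray, grid: SpatialGrid, shift: float,
                  fill_left: float | None = None,
                  fill_right: float | None = None) -> np.ndarray:
    """Profile evaluated at x + shift.

    Exact index shift when ``shift`` is a grid multiple; otherwise monotone
    cubic (PCHIP) interpolation, which preserves front monotonicity.  Cells
    sampling outside the domain take the nearest edge value unless an
    explicit fill is given (re-centering a moving window fills the entering
    uninvaded side with 0).
    """
    if shift == 0:
        return values.copy()
    lo = values[0] if fill_left is None else fill_left
    hi = values[-1] if fill_right is None else fill_right
    cells = shift / grid.dx
    m = int(round(cells))
    if abs(cells - m) < 1e-9:
        out = np.empty_like(values)
        if m > 0:
            out[:-m] = values[m:]
            out[-m:] = hi
        else:
            out[-m:] = values[:m]
            out[:-m] = lo
        return out
    interp = PchipInterpolator(grid.x, values, extrapolate=False)
    out = interp(grid.x + shift)
    out = np.where(np.isnan(out),
                   np.where(grid.x + shift < grid.x_min, lo, hi), out)
    return out


def shifted_target(ntilde: DensityProfile, target: SpeedTarget
                   ) -> DensityProfile:
    """Where the front is allowed to be after one step.

    ntilde(x + dx) for v > 0, ntilde(x) for v = 0, ntilde(x - dx) for v < 0.
    """
    if target.dx_shift >= ntilde.grid.x_max - ntilde.grid.x_min:
        raise ValueError("shift exceeds the domain")
    sign = 1.0 if target.v > 0 else (-1.0 if target.v < 0 else 0.0)
    vals = _shift_values(ntilde.values, ntilde.grid, sign * target.dx_shift)
    return DensityProfile(ntilde.grid, np.maximum(vals, 0.0))


def free_step(ntilde: DensityProfile,
              params: GenericParams | SpongyParams,
              target: SpeedTarget,
              kernel: Kernel | None = None) -> DensityProfile:
    """One untreated step of duration ``target.dt``."""
    grid = ntilde.grid
    zero = TreatmentProfile(grid, np.zeros(grid.n_nodes))
    if isinstance(params, SpongyParams):
        return step_discrete(ntilde, zero, params, kernel)
    return step_continuous(ntilde, zero, params, TimeStepping(target.dt),
                           kernel)


# ---------------------------------------------------------------------------
# per-node investment solvers
# ---------------------------------------------------------------------------

def solve_A_discrete(n1, n_target, params: SpongyParams,
                     config: SolverConfig = SolverConfig()):
    """Mating-disruption investment equating treated and target fecundity.

    Solves b(n1, A) = b(n_target, 0) through the egg-mass density (both
    sides of the birth parabola share n0): the closed form

        A = (1/a) (-lambda0 n1 / (2 ln(1 - w/n1)) - 1),
        w = n_target (1 - exp(-lambda0 n_target / 2)),

    is the exact solution; each result is validated against the fecundity
    balance and re-solved by bracketed root finding if the residual check
    fails (degenerate floating-point corners).
    """
    n1 = np.asarray(n1, dtype=float)
    n_target = np.asarray(n_target, dtype=float)
    if np.any(n_target < 0):
        raise ValueError("target density must be non-negative")
    if np.any(n1 < n_target):
        raise ValueError("solver expects n1 >= n_target")
    scalar = n1.ndim == 0 and n_target.ndim == 0
    n1, n_target = np.atleast_1d(n1), np.atleast_1d(n_target)
    n1, n_target = np.broadcast_arrays(n1, n_target)
    A = np.zeros(n1.shape)
    need = n1 > n_target
    if need.any():
        nn1, nt = n1[need], n_target[need]
        w = nt * (-np.expm1(-params.lambda0 * nt / 2.0))
        with np.errstate(divide="ignore"):
            denom = 2.0 * np.log1p(-w / nn1)
            Aval = (-params.lambda0 * nn1 / denom - 1.0) / params.a
        Aval = np.where(np.isfinite(Aval), Aval, 0.0)
        Aval = np.maximum(Aval, 0.0)
        # validate the closed form against the defining balance
        resid = np.abs(egg_masses(nn1, Aval, params)
                       - egg_masses(nt, 0.0, params))
        scale = np.maximum(egg_masses(nn1, 0.0, params), 1e-300)
        bad = resid > config.validate_tol * scale
        if bad.any():
            logger.info("solve_A_discrete: closed form failed residual "
                        "check at %d nodes; falling back to root finding",
                        int(bad.sum()))
            idx = np.flatnonzero(bad)
            for j in idx:
                Aval[j] = _root_A_discrete(nn1[j], nt[j], params, config)
        A[need] = Aval
    return float(A[0]) if scalar else A.reshape(np.shape(n1))


def _root_A_discrete(n1: float, n_target: float, params: SpongyParams,
                     config: SolverConfig) -> float:
    w = egg_masses(n_target, 0.0, params)
    f = lambda A: egg_masses(n1, A, params) - w
    if f(0.0) <= 0:
        return 0.0
    hi = 1.0 / params.a
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 2.0
    else:
        raise ValueError("target unreachable by mating disruption")
    return float(optimize.brentq(f, 0.0, hi, xtol=config.newton_tol))


def solve_A_continuous_power(n1, n_target, params: GenericParams,
                             dt: float):
    """Closed-form investment for power-law removal with alpha < 1.

    Pure-removal decay dn/dt = -beta A n^alpha carries n1 to n_target in dt
    when A = (n1^(1-alpha) - n_target^(1-alpha)) / (beta (1-alpha) dt).
    """
    if params.alpha >= 1:
        raise ValueError("alpha = 1 has no finite-time closed form; use "
                         "solve_A_newton")
    n1 = np.asarray(n1, dtype=float)
    n_target = np.asarray(n_target, dtype=float)
    if np.any(n1 < n_target):
        raise ValueError("solver expects n1 >= n_target")
    e = 1.0 - params.alpha
    A = (np.power(n1, e) - np.power(n_target, e)) / (params.beta * e * dt)
    A = np.maximum(A, 0.0)
    return float(A) if A.ndim == 0 else A


def solve_A_newton(n1: float, n_target: float,
                   removal_fn: Callable[[float, float], float],
                   dt: float,
                   config: SolverConfig = SolverConfig(),
                   quad_points: int = 64) -> float:
    """Investment A such that decay dn/dt = -R(n, A) maps n1 to n_target.

    Works for any removal rate monotone increasing in A by solving
    ``dt = integral_{n_target}^{n1} dn / R(n, A)`` with Gauss–Legendre
    quadrature and safeguarded Newton (secant slope, bisection fallback).
    Requires n_target > 0 or an R integrable at 0.
    """
    if n1 < n_target:
        raise ValueError("expects n1 >= n_target")
    if n1 == n_target:
        return 0.0
    nodes, wts = np.polynomial.legendre.leggauss(quad_points)
    mid, hw = 0.5 * (n1 + n_target), 0.5 * (n1 - n_target)
    nvals = mid + hw * nodes

    def elapsed(A: float) -> float:
        r = np.asarray(removal_fn(nvals, A), dtype=float)
        if np.any(r <= 0):
            return math.inf
        return float(hw * np.sum(wts / r))

    # bracket: elapsed(A) decreases in A; find lo with elapsed > dt, hi with <
    hi = 1.0
    for _ in range(200):
        if elapsed(hi) < dt:
            break
        hi *= 2.0
    else:
        raise ValueError("no investment achieves the target within dt")
    lo = hi / 2.0
    while elapsed(lo) < dt and lo > 1e-300:
        lo /= 2.0
    A = 0.5 * (lo + hi)
    for _ in range(config.newton_max_iter):
        g = elapsed(A) - dt
        if abs(g) <= config.newton_tol * dt:
            return A
        if g > 0:
            lo = A
        else:
            hi = A
        # Newton step on g(A): d(elapsed)/dA via secant within the bracket
        h = 1e-6 * A
        dg = (elapsed(A + h) - elapsed(A - h)) / (2 * h)
        step = A - g / dg if dg != 0 else math.nan
        A = step if lo < step < hi else 0.5 * (lo + hi)
    raise ValueError(
        f"Newton did not converge; bracket [{lo:.6e}, {hi:.6e}]"
    )


# ---------------------------------------------------------------------------
# treatment phases (used by the relaxation)
# ---------------------------------------------------------------------------

def _removal_decay(n1: np.ndarray, A: np.ndarray, params: GenericParams,
                   dt: float) -> np.ndarray:
    """Exact solution of dn/dt = -beta A n^alpha over dt, floored at 0."""
    if params.alpha == 1.0:
        return n1 * np.exp(-params.beta * A * dt)
    e = 1.0 - params.alpha
    z = np.power(n1, e) - params.beta * A * e * dt
    return np.where(z > 0, np.power(np.maximum(z, 0.0), 1.0 / e), 0.0)


def _effective_density(n1: np.ndarray, A: np.ndarray,
                       params: SpongyParams) -> np.ndarray:
    """Density z <= n1 whose untreated fecundity matches b(n1, A).

    Solves z (1 - exp(-lambda0 z / 2)) = n1 (1 - exp(-lambda (A) n1 / 2))
    per node; the left side is strictly increasing, so safeguarded Newton
    from z = n1 converges monotonically.
    """
    n1 = np.asarray(n1, dtype=float)
    A = np.asarray(A, dtype=float)
    w = 2.0 * egg_masses(n1, A, params)
    z = n1.copy()
    lam = params.lambda0
    active = A > 0
    if not active.any():
        return z
    zi = z[active]
    wi = w[active]
    for _ in range(100):
        e = np.exp(-lam * zi / 2.0)
        f = zi * (1.0 - e) - wi
        df = 1.0 - e + zi * (lam / 2.0) * e
        step = f / df
        zi = np.clip(zi - step, 0.0, None)
        if np.max(np.abs(f)) < 1e-13 * max(float(np.max(wi)), 1e-300):
            break
    z[active] = zi
    return z


def treated_step(n: DensityProfile, A_hat: TreatmentProfile,
                 target: SpeedTarget,
                 params: GenericParams | SpongyParams,
                 kernel: Kernel | None = None) -> DensityProfile:
    """One split step: untreated dynamics for dt, then the treatment phase."""
    n1 = free_step(n, params, target, kernel)
    if isinstance(params, SpongyParams):
        out = _effective_density(n1.values, A_hat.values, params)
    else:
        out = _removal_decay(n1.values, A_hat.values, params, target.dt)
    return DensityProfile(n.grid, out)


# ---------------------------------------------------------------------------
# find A_hat and find n_hat
# ---------------------------------------------------------------------------

def find_A_hat(ntilde: DensityProfile, target: SpeedTarget,
               params: GenericParams | SpongyParams,
               kernel: Kernel | None = None,
               config: SolverConfig = SolverConfig(),
               return_diagnostics: bool = False):
    """Minimal investment holding ``ntilde`` to speed <= v everywhere.

    A(x) = 0 where the untreated step stays at or below the (enforced)
    shifted target; elsewhere A(x) is the per-node investment whose
    treatment phase brings the untreated outcome back exactly to the target
    (never over-treating).  For the discrete Allee model the enforced target
    is the shifted target capped below at the containment floor, and nodes
    whose target lies within ``trailing_tol`` of the carrying capacity are
    exempt (see :class:`SolverConfig`).
    """
    grid = ntilde.grid
    n1 = free_step(ntilde, params, target, kernel)
    tgt = shifted_target(ntilde, target)
    enforced = tgt.values
    # trailing exemption (both models): a deficit within trailing_tol of
    # the carrying capacity is the established population recovering
    # density, not the front advancing; enforcing its co-movement buys
    # nothing and distorts the cost
    window = enforced < (1.0 - config.trailing_tol) * params.equilibrium
    if isinstance(params, SpongyParams):
        floor = config.allee_floor * params.allee_threshold
        enforced = np.maximum(enforced, floor)
        # enforce only within a bounded barrier strip ahead of the front's
        # foot; the sub-threshold halo further out is doomed demographically
        # and chasing it would widen the treatment without bound
        # strict inequality: nodes the treatment itself caps at the floor
        # must not count as front body, or the strip would creep leftward
        # by its own width on every solve
        body = np.flatnonzero(tgt.values > 1.01 * floor)
        if len(body):
            margin = int(round(config.barrier_width_sigma * params.sigma
                               / grid.dx))
            window &= np.arange(grid.n_nodes) >= body[0] - margin
    binding = (n1.values > enforced) & window
    A = np.zeros(grid.n_nodes)
    if binding.any():
        if isinstance(params, SpongyParams):
            A[binding] = solve_A_discrete(n1.values[binding],
                                          enforced[binding], params,
                                          config)
        else:
            A[binding] = solve_A_continuous_power(
                n1.values[binding], enforced[binding], params, target.dt
            ) if params.alpha < 1 else np.array([
                solve_A_newton(a, b,
                               lambda n, A_: removal_rate(n, A_, params),
                               target.dt, config)
                for a, b in zip(n1.values[binding], enforced[binding])
            ])
    profile = TreatmentProfile(grid, A)
    if return_diagnostics:
        return profile, {"n1": n1, "target": tgt,
                         "enforced_target": DensityProfile(grid, enforced),
                         "window": window, "binding": binding}
    return profile


def find_n_hat(ntilde: DensityProfile, A_hat: TreatmentProfile,
               target: SpeedTarget,
               params: GenericParams | SpongyParams,
               config: SolverConfig = SolverConfig(),
               kernel: Kernel | None = None) -> DensityProfile:
    """Co-moving front sustained by a fixed treatment profile.

    Iterates the split step in the frame moving with the treatment (shift by
    dx_shift each step, constant extension at the trailing edge) until the
    shape change per step falls below ``eps_shape`` (sup norm, relative to
    the untreated equilibrium).
    """
    grid = ntilde.grid
    if kernel is None:
        kernel = gaussian_kernel(grid, params.sigma)
    eq = params.equilibrium
    tol = config.eps_shape * eq
    # one step advances the front by dx_shift (leftward for v > 0); the
    # re-centering shift undoes it, with uninvaded territory entering from
    # the leading (left) side when v > 0
    if target.v > 0:
        recenter, fill_left = -target.dx_shift, 0.0
    elif target.v < 0:
        recenter, fill_left = target.dx_shift, None
    else:
        recenter, fill_left = 0.0, None
    vals = ntilde.values.copy()
    prof = DensityProfile(grid, vals)
    # containment guard (Allee model): densities well ahead of the
    # treatment must stay below the Allee threshold, else no co-moving
    # front exists for this treatment
    guard = None
    clamp = None
    if isinstance(params, SpongyParams):
        support = np.flatnonzero(
            A_hat.values > 1e-6 * A_hat.values.max(initial=0.0))
        if len(support):
            # clamp starts immediately ahead of the treated band so the
            # sub-threshold halo cannot out-creep the enforcement strip
            x_lead = grid.x[support[0]] - 2.0 * grid.dx
            guard = grid.x < x_lead
            guard_level = params.allee_threshold
            # with the leading clamp, sub-threshold leakage past the
            # barrier is treated as contained (zeroed) instead of aborting
            # — the halo ahead is doomed demographically but only on a
            # timescale the co-moving iteration cannot separate from the
            # collectively-supercritical case
            clamp = guard if config.leading_clamp else None
    residuals: list[float] = []
    for it in range(config.max_relax_steps):
        stepped = treated_step(prof, A_hat, target, params, kernel)
        new_vals = _shift_values(stepped.values, grid, recenter,
                                 fill_left=fill_left)
        new_vals = np.maximum(new_vals, 0.0)
        if guard is not None and clamp is not None:
            new_vals[clamp] = 0.0
        resid = float(np.max(np.abs(new_vals - prof.values)))
        residuals.append(resid)
        prof = DensityProfile(grid, new_vals)
        if guard is not None and clamp is None and guard.any() \
                and float(new_vals[guard].max(initial=0.0)) > guard_level:
            raise ContainmentError(
                "population established ahead of the treatment at step "
                f"{it}: the treatment cannot sustain a co-moving front for "
                "this shape"
            )
        if resid < tol:
            return prof
    raise RuntimeError(
        "front relaxation did not converge within "
        f"{config.max_relax_steps} steps; last residuals "
        f"{[f'{r:.2e}' for r in residuals[-5:]]}"
    )


# ---------------------------------------------------------------------------
# annual cost of treatment
# ---------------------------------------------------------------------------

def act(A_hat: TreatmentProfile, support_rtol: float = 5e-3) -> float:
    """Annual cost of treatment: trapezoidal integral of A over x.

    Raises if the treatment support reaches the domain edge.  Support is
    judged relative to the peak investment: the minimal holding treatment
    decays exponentially on both flanks of a front without strictly
    reaching zero, and anything below the tolerance contributes a vanishing
    share of the integral long before it could matter.
    """
    vals = A_hat.values
    peak = float(vals.max(initial=0.0))
    total = float(np.trapezoid(vals, dx=A_hat.grid.dx))
    for edge in (vals[0], vals[-1]):
        if peak > 0 and edge > support_rtol * peak \
                and edge * A_hat.grid.dx > support_rtol * total:
            raise ValueError(
                "domain too small: treatment support touches the domain "
                "edge"
            )
    return total


def act_per_km_strip(A_hat: TreatmentProfile) -> float:
    """ACT in thousand USD per one-km strip (A in USD/ha, x in km)."""
    return THOUSAND_USD_PER_KM_STRIP * act(A_hat)
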