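"""Discretized 1-D population dynamics for invasion fronts.

Two model families share a dispersal-kernel (integrodifference) structure:

* a generic continuous-time model with logistic propagule production
  ``b(n) = r n (1 - n/k)``, natural mortality ``d(n) = gamma n`` and a
  removal treatment ``R(n, A) = beta A n**alpha``;
* a discrete-time spongy-moth model in which mating disruption lowers the
  female-finding rate ``lambda = lambda0 / (1 + a A)``, producing a
  mate-finding Allee effect.

Space is a uniform 1-D grid; propagules redistribute through a truncated,
renormalized Gaussian kernel.  Fronts are monotone profiles connecting the
uninvaded state (n ~ 0 at small x) to the established state at large x, and
invade leftward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "SpatialGrid",
    "DensityProfile",
    "TreatmentProfile",
    "GenericParams",
    "SpongyParams",
    "TimeStepping",
    "Kernel",
    "gaussian_kernel",
    "propagule_redistribution",
    "step_continuous",
    "step_discrete",
    "mating_success",
    "spongy_birth",
    "allee_lambda0",
    "natural_speed",
    "linearized_speed",
    "front_position",
    "clip_counter",
]

logger = logging.getLogger(__name__)


class ClipCounter:
    """Counts events in which a forward step clipped negative densities."""

    def __init__(self) -> None:
        self.events = 0
        self.worst = 0.0

    def record(self, undershoot: float) -> None:
        self.events += 1
        self.worst = max(self.worst, undershoot)
        logger.debug("density clipped at 0 (undershoot %.3e)", undershoot)

    def reset(self) -> None:
        self.events = 0
        self.worst = 0.0


#: Module-wide clip log; acceptance-grade runs must leave it at zero.
clip_counter = ClipCounter()


# ---------------------------------------------------------------------------
# grid and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D spatial grid, positions in kilometers."""

    x_min: float
    x_max: float
    dx: float

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")
        if not self.dx > 0:
            raise ValueError("dx must be > 0")

    @property
    def n_nodes(self) -> int:
        return int(round((self.x_max - self.x_min) / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n_nodes)

    @classmethod
    def for_sigma(
        cls,
        sigma: float,
        length_in_sigma: float = 40.0,
        cells_per_sigma: float = 20.0,
        center: float = 0.0,
    ) -> "SpatialGrid":
        """Grid sized relative to the dispersal length sigma.

        Defaults give a domain of 40 sigma at a spacing of sigma/20, which
        keeps the kernel well resolved and leaves room for a front plus its
        treatment zone away from both edges.
        """
        half = 0.5 * length_in_sigma * sigma
        return cls(center - half, center + half, sigma / cells_per_sigma)

    def matched_to_shift(self, sigma: float, dx_shift: float,
                         length_in_sigma: float = 40.0,
                         cells_per_sigma: float = 20.0,
                         center: float = 0.0) -> "SpatialGrid":
        """Grid whose spacing divides ``dx_shift`` exactly (integer shifts).

        Used by the discrete-time solver, where the per-generation shift is
        fixed at |v| and interpolation-free index shifts are preferable.
        """
        target = sigma / cells_per_sigma
        if dx_shift <= 0:
            dx = target
        else:
            dx = dx_shift / max(1, math.ceil(dx_shift / target))
        half = 0.5 * length_in_sigma * sigma
        return SpatialGrid(center - half, center + half, dx)


@dataclass
class Profile:
    """Values attached to the nodes of a :class:`SpatialGrid`."""

    grid: SpatialGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_nodes} nodes)"
            )
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def copy(self) -> "Profile":
        return type(self)(self.grid, self.values.copy())


class DensityProfile(Profile):
    """Population density n(x) on a grid (>= 0 everywhere)."""

    def is_front(self, rtol: float = 1e-6) -> bool:
        """True if monotone non-decreasing, ~0 on the left, positive right."""
        v = self.values
        top = v[-1]
        if top <= 0:
            return False
        mono = np.all(np.diff(v) >= -rtol * top)
        return bool(mono and v[0] <= rtol * top)


class TreatmentProfile(Profile):
    """Investment density A(x) on a grid (USD per hectare per year, >= 0)."""

    def support(self, atol: float = 0.0) -> np.ndarray:
        return np.flatnonzero(self.values > atol)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenericParams:
    """Constants of the continuous-time model.

    r      per-capita juvenile production rate at low density (1/yr)
    k      carrying-capacity parameter of the logistic birth term
    gamma  adult natural mortality rate (1/yr)
    sigma  dispersal length (km)
    beta   treatment efficiency (1/USD/yr); removal rate is beta*A*n**alpha
    alpha  invisibility exponent in [0, 1]: alpha = 0 means the cost of
           removing one individual is density-independent, alpha = 1 means
           removal is proportional to density.
    """

    r: float
    k: float
    gamma: float
    sigma: float
    beta: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.r > self.gamma > 0):
            raise ValueError("need r > gamma > 0 for an invasive population")
        if self.k <= 0 or self.sigma <= 0 or self.beta <= 0:
            raise ValueError("k, sigma, beta must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def equilibrium(self) -> float:
        """Untreated uniform equilibrium k (1 - gamma/r), where b(n)=d(n)."""
        return self.k * (1.0 - self.gamma / self.r)


def allee_lambda0(r: float, n_a: float) -> float:
    """Female-finding rate implied by an Allee threshold ``n_a``.

    At the Allee threshold the per-capita growth of the spongy-moth map
    equals one (in the low-density, large-k limit), which pins
    ``lambda0 = (2/n_a) ln(r/(r-1))``.
    """
    if r <= 1:
        raise ValueError("r must exceed 1 (no growth anywhere otherwise)")
    if n_a <= 0:
        raise ValueError("n_a must be positive")
    return (2.0 / n_a) * math.log(r / (r - 1.0))


@dataclass(frozen=True)
class SpongyParams:
    """Constants of the discrete-time spongy-moth model.

    r        females produced per egg mass at low density
    k        carrying capacity of the egg-mass map (egg masses / ha), or 1
             when densities are normalized to carrying capacity
    lambda0  per-male per-season female-finding probability (ha/individual)
    a        mating-disruption efficiency (1/USD per ha)
    sigma    dispersal length (km)

    The product ``k * lambda0`` controls the Allee threshold relative to the
    carrying capacity and is the only demographic combination that matters
    once densities are measured in units of k.
    """

    r: float
    k: float
    lambda0: float
    a: float
    sigma: float

    def __post_init__(self) -> None:
        if self.r <= 1:
            raise ValueError("r must exceed 1")
        if min(self.k, self.lambda0, self.a, self.sigma) <= 0:
            raise ValueError("k, lambda0, a, sigma must be positive")
        eq = self._upper_equilibrium()
        if eq is None:
            raise ValueError(
                "k*lambda0 too small: untreated map has no viable upper "
                "equilibrium (mate-finding Allee effect extinguishes the "
                "population everywhere)"
            )
        slope = self._map_slope(eq)
        if abs(slope) >= 1.0:
            raise ValueError(
                "untreated local map is oscillatory/chaotic at its upper "
                "equilibrium (|map slope| >= 1); reduce r"
            )

    @classmethod
    def normalized(cls, r: float, k_lambda0: float, a: float,
                   sigma: float) -> "SpongyParams":
        """Parameters with density in units of carrying capacity (k = 1)."""
        return cls(r=r, k=1.0, lambda0=k_lambda0, a=a, sigma=sigma)

    # -- local (non-spatial) untreated map -------------------------------
    def _local_map(self, n: np.ndarray | float) -> np.ndarray | float:
        return spongy_birth(n, 0.0, self)

    def _map_slope(self, n: float, h: float = 1e-6) -> float:
        h = h * max(1.0, abs(n))
        return (self._local_map(n + h) - self._local_map(n - h)) / (2 * h)

    def _upper_equilibrium(self) -> float | None:
        n = np.linspace(1e-9 * self.k, 2.0 * self.k, 4001)
        g = self._local_map(n) - n
        sign = np.sign(g)
        crossings = np.flatnonzero(np.diff(sign) < 0)  # descending b(n)-n
        if len(crossings) == 0:
            return None
        i = crossings[-1]
        root = optimize.brentq(lambda z: self._local_map(z) - z,
                               n[i], n[i + 1], xtol=1e-14 * self.k)
        # viable only if per-capita growth exceeds 1 somewhere below it
        mid = np.linspace(root * 1e-4, root, 2001)
        if np.max(self._local_map(mid) - mid) <= 0:
            return None
        return float(root)

    @property
    def equilibrium(self) -> float:
        """Stable positive fixed point of the untreated local map."""
        eq = self._upper_equilibrium()
        assert eq is not None  # guaranteed by __post_init__
        return eq

    @property
    def allee_threshold(self) -> float:
        """Density below which the untreated population declines."""
        eq = self.equilibrium
        f = lambda z: self._local_map(z) - z
        lo = 1e-12 * self.k
        if f(lo) >= 0:
            raise ValueError("no Allee threshold: growth at zero density")
        return float(optimize.brentq(f, lo, 0.999 * eq, xtol=1e-14 * self.k))


@dataclass(frozen=True)
class TimeStepping:
    """Explicit-integration control for the continuous-time model.

    ``substeps`` splits one dt into equal Euler sub-iterations.  When left at
    0, a step chooses ``ceil(dt*(r+gamma)/max_rel_change)`` substeps so that
    no substep changes the density by more than ``max_rel_change`` relative
    to the demographic rates.
    """

    dt: float
    substeps: int = 0
    max_rel_change: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 0:
            raise ValueError("substeps must be >= 0")

    def resolve_substeps(self, params: GenericParams) -> int:
        if self.substeps:
            return self.substeps
        rate = params.r + params.gamma
        return max(1, math.ceil(self.dt * rate / self.max_rel_change))


# ---------------------------------------------------------------------------
# dispersal kernel
# ---------------------------------------------------------------------------

class Kernel:
    """Discrete symmetric kernel with constant-extension convolution.

    The domain is padded on each side with its edge value before convolving,
    so a spatially uniform profile is an exact fixed point and fronts do not
    decay artificially at the boundary.  The kernel FFT is cached per data
    length, which makes repeated convolutions cheap.
    """

    def __init__(self, dx: float, weights: np.ndarray) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 1 or len(weights) % 2 != 1:
            raise ValueError("kernel weights must be a 1-D odd-length array")
        self.dx = float(dx)
        self.weights = weights
        self.half_width = (len(weights) - 1) // 2
        self._fft_cache: dict[int, tuple[int, np.ndarray]] = {}

    @property
    def offsets(self) -> np.ndarray:
        return self.dx * np.arange(-self.half_width, self.half_width + 1)

    def _kernel_fft(self, n_padded: int) -> tuple[int, np.ndarray]:
        try:
            return self._fft_cache[n_padded]
        except KeyError:
            n_fft = _fft.next_fast_len(n_padded + len(self.weights) - 1)
            kf = _fft.rfft(self.weights, n_fft)
            self._fft_cache[n_padded] = (n_fft, kf)
            return n_fft, kf

    def convolve(self, values: np.ndarray) -> np.ndarray:
        """Convolution with constant (edge-value) extension."""
        values = np.asarray(values, dtype=float)
        h = self.half_width
        padded = np.empty(len(values) + 2 * h)
        padded[:h] = values[0]
        padded[h:-h] = values
        padded[-h:] = values[-1]
        if len(self.weights) < 32:
            full = np.convolve(padded, self.weights)
            out = full[2 * h: 2 * h + len(values)]
        else:
            n_fft, kf = self._kernel_fft(len(padded))
            vf = _fft.rfft(padded, n_fft)
            full = _fft.irfft(vf * kf, n_fft)
            out = full[2 * h: 2 * h + len(values)]
        # convolving non-negative inputs with non-negative weights cannot
        # go negative; the FFT path leaves round-off-scale negatives in
        # exact-zero regions
        tol = 1e-10 * float(np.max(np.abs(out), initial=0.0))
        out[(out < 0) & (out > -tol)] = 0.0
        return out


def gaussian_kernel(grid: SpatialGrid, sigma: float,
                    truncate: float = 8.0) -> Kernel:
    """Zero-mean Gaussian dispersal kernel discretized on grid offsets.

    Weights are exact cell integrals of the Gaussian (CDF differences),
    truncated at ``truncate`` standard deviations and renormalized to sum to
    one so that redistribution conserves propagule mass on the grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sigma <= grid.dx:
        raise ValueError(
            f"kernel under-resolved: sigma={sigma} <= dx={grid.dx}; refine "
            "the grid"
        )
    half = int(math.ceil(truncate * sigma / grid.dx))
    edges = grid.dx * (np.arange(-half, half + 1 + 1) - 0.5)
    weights = np.diff(norm.cdf(edges, scale=sigma))
    weights /= weights.sum()
    return Kernel(grid.dx, weights)


def propagule_redistribution(b_profile: Profile | np.ndarray,
                             kernel: Kernel) -> np.ndarray:
    """Redistribute locally produced propagules through the kernel."""
    values = b_profile.values if isinstance(b_profile, Profile) else b_profile
    return kernel.convolve(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# local demographic rates
# ---------------------------------------------------------------------------

def logistic_birth(n: np.ndarray | float, params: GenericParams):
    return params.r * n * (1.0 - n / params.k)


def removal_rate(n: np.ndarray | float, A: np.ndarray | float,
                 params: GenericParams):
    """Adult removal rate R(n, A) = beta * A * n**alpha."""
    n = np.asarray(n, dtype=float)
    return params.beta * np.asarray(A, dtype=float) * np.power(n, params.alpha)


def mating_success(n, A, params: SpongyParams):
    """Probability that a female is fertilized, P = 1 - exp(-lambda n/2).

    Mating disruption divides the female-finding rate by (1 + a A).
    """
    n = np.asarray(n, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(n < 0) or np.any(A < 0):
        raise ValueError("density and investment must be non-negative")
    lam = params.lambda0 / (1.0 + params.a * A)
    out = -np.expm1(-lam * n / 2.0)
    if out.ndim == 0:
        return float(out)
    return out


def spongy_birth(n, A, params: SpongyParams):
    """Next-generation local density before dispersal.

    Each fertilized female lays one egg mass (n0 = n P / 2); each egg mass
    yields 2 r adults at low density with logistic larval competition,
    b = 2 r n0 (1 - n0/k).  Degenerate inputs with n0 > k are floored at 0.
    """
    n = np.asarray(n, dtype=float)
    P = np.asarray(mating_success(n, A, params))
    n0 = n * P / 2.0
    if np.any(n0 > params.k):
        logger.debug("spongy_birth: n0 exceeded k; output floored at 0")
    b = 2.0 * params.r * n0 * (1.0 - n0 / params.k)
    b = np.maximum(b, 0.0)
    if b.ndim == 0:
        return float(b)
    return b


def egg_masses(n, A, params: SpongyParams):
    """Egg-mass density n0 = n P(n, A) / 2 (monotone in n at fixed A)."""
    n = np.asarray(n, dtype=float)
    return n * np.asarray(mating_success(n, A, params)) / 2.0


# ---------------------------------------------------------------------------
# forward steps
# ---------------------------------------------------------------------------

def _require_same_grid(n: Profile, A: Profile) -> None:
    if n.grid != A.grid:
        raise ValueError("profiles must share a grid")


def step_continuous(n: DensityProfile, A: TreatmentProfile,
                    params: GenericParams, stepping: TimeStepping,
                    kernel: Kernel | None = None) -> DensityProfile:
    """One dt of dn/dt = -gamma n - beta A n^alpha + K*[r n (1 - n/k)].

    Integrated by explicit Euler over ``stepping`` substeps.  Negative
    intermediate values are clipped at zero and counted; an undershoot beyond
    ``max_rel_change`` of the equilibrium raises instead of clipping.
    """
    _require_same_grid(n, A)
    if kernel is None:
        kernel = gaussian_kernel(n.grid, params.sigma)
    substeps = stepping.resolve_substeps(params)
    h = stepping.dt / substeps
    v = n.values.copy()
    Av = A.values
    tol = stepping.max_rel_change * params.equilibrium
    for _ in range(substeps):
        growth = kernel.convolve(logistic_birth(v, params))
        v = v + h * (-params.gamma * v - removal_rate(v, Av, params) + growth)
        worst = -float(v.min(initial=0.0))
        if worst > 0:
            if worst > tol:
                raise ValueError(
                    "time step too large: density undershoots zero by "
                    f"{worst:.3e}; increase substeps"
                )
            clip_counter.record(worst)
            np.maximum(v, 0.0, out=v)
    return DensityProfile(n.grid, v)


def step_discrete(n: DensityProfile, A: TreatmentProfile,
                  params: SpongyParams,
                  kernel: Kernel | None = None) -> DensityProfile:
    """One generation: offspring b(n, A) redistributed through the kernel."""
    _require_same_grid(n, A)
    if kernel is None:
        kernel = gaussian_kernel(n.grid, params.sigma)
    out = kernel.convolve(spongy_birth(n.values, A.values, params))
    np.maximum(out, 0.0, out=out)  # guards FFT round-off only
    return DensityProfile(n.grid, out)


# ---------------------------------------------------------------------------
# untreated front speed
# ---------------------------------------------------------------------------

def linearized_speed(params: GenericParams) -> float:
    """Pulled-front speed min_s (r exp(sigma^2 s^2 / 2) - gamma)/s.

    Obtained by substituting an exponential leading edge into the linearized
    continuous-time dynamics; serves as the analytic check on the measured
    untreated speed.
    """
    f = lambda s: (params.r * math.exp(0.5 * (params.sigma * s) ** 2)
                   - params.gamma) / s
    res = optimize.minimize_scalar(f, bounds=(1e-8 / params.sigma,
                                              4.0 / params.sigma),
                                   method="bounded")
    return float(res.fun)


def front_position(values: np.ndarray, grid: SpatialGrid,
                   level: float) -> float:
    """x where the profile first crosses ``level`` (linear interpolation)."""
    v = np.asarray(values)
    above = v >= level
    if not above.any() or above.all():
        raise ValueError("profile does not cross the requested level")
    i = int(np.argmax(above))
    if i == 0:
        return float(grid.x[0])
    x = grid.x
    f = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(x[i - 1] + f * (x[i] - x[i - 1]))


def _step_profile(grid: SpatialGrid, top: float,
                  frac: float = 0.5) -> DensityProfile:
    v = np.where(grid.x >= grid.x_min + frac * (grid.x_max - grid.x_min),
                 top, 0.0)
    return DensityProfile(grid, v)


def natural_speed(params: GenericParams | SpongyParams,
                  grid: SpatialGrid | None = None,
                  horizon: float | None = None,
                  dt: float = 0.005) -> float:
    """Asymptotic leftward speed of the untreated front (km/yr).

    Simulates from a step initial condition and fits the displacement of the
    half-equilibrium level set over the second half of the horizon by least
    squares.  Raises if the front reaches the domain edge first.

    The continuous-model default dt is finer than the solver's: the pulled
    front's speed converges slowly (a ~1/t transient) and is biased low by
    explicit time stepping, so the measurement needs a longer, finer run
    than the treatment solver does.
    """
    if grid is None:
        grid = SpatialGrid.for_sigma(params.sigma, length_in_sigma=90.0)
    kernel = gaussian_kernel(grid, params.sigma)
    eq = params.equilibrium
    n = _step_profile(grid, eq, frac=0.75)
    discrete = isinstance(params, SpongyParams)
    A = TreatmentProfile(grid, np.zeros(grid.n_nodes))
    if discrete:
        step = lambda prof: step_discrete(prof, A, params, kernel)
        dt = 1.0
        if horizon is None:
            horizon = 25.0
    else:
        stepping = TimeStepping(dt)
        step = lambda prof: step_continuous(prof, A, params, stepping, kernel)
        if horizon is None:
            horizon = 50.0 * params.sigma / linearized_speed(params)
    n_steps = int(round(horizon / dt))
    times = np.empty(n_steps)
    pos = np.empty(n_steps)
    margin = grid.x_min + 4.0 * params.sigma
    for i in range(n_steps):
        n = step(n)
        times[i] = (i + 1) * dt
        pos[i] = front_position(n.values, grid, 0.5 * eq)
        if pos[i] < margin:
            raise ValueError(
                "domain too small: front reached the left edge before the "
                "speed estimate converged"
            )
    half = n_steps // 2
    slope = np.polyfit(times[half:], pos[half:], 1)[0]
    return float(-slope)  # leftward displacement => positive speed
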