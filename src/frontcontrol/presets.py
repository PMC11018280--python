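"""Reference parameter sets and initial fronts for the two case studies.

These are the published demonstration configurations: a generic
continuous-time invader with partially density-dependent removal cost, and
the North American spongy moth managed by mating disruption, with density in
units of carrying capacity so that the single product k*lambda0 carries the
demography.
"""

from __future__ import annotations

from .model_core import DensityProfile, GenericParams, SpatialGrid, SpongyParams
from .optimizer import natural_front, piecewise_linear_front

__all__ = [
    "generic_demo_params",
    "spongy_demo_params",
    "generic_grid",
    "spongy_grid",
    "demo_initial_fronts",
]


def generic_demo_params(alpha: float = 0.2,
                        sigma: float = 25.0) -> GenericParams:
    """Generic invader: r=2/yr, k=2, gamma=1/yr, beta=1/(1-alpha).

    The removal efficiency convention beta = 1/(1-alpha) keeps the cost of
    removing one unit of density from the equilibrium comparable across
    alpha values (for alpha=0.2 it gives the quoted beta=1.25).
    """
    return GenericParams(r=2.0, k=2.0, gamma=1.0, sigma=sigma,
                         beta=1.0 / (1.0 - alpha), alpha=alpha)


def spongy_demo_params(k_lambda0: float = 100.0,
                       sigma: float = 10.0) -> SpongyParams:
    """Spongy moth with mating disruption: r=2, a=0.08/USD, normalized k."""
    return SpongyParams.normalized(r=2.0, k_lambda0=k_lambda0, a=0.08,
                                   sigma=sigma)


def generic_grid(params: GenericParams,
                 length_in_sigma: float = 40.0,
                 cells_per_sigma: float = 20.0) -> SpatialGrid:
    return SpatialGrid.for_sigma(params.sigma, length_in_sigma,
                                 cells_per_sigma)


def spongy_grid(params: SpongyParams, dx_shift: float,
                length_in_sigma: float = 30.0,
                cells_per_sigma: float = 20.0) -> SpatialGrid:
    """Grid whose spacing divides the per-generation shift exactly."""
    return SpatialGrid.for_sigma(params.sigma, length_in_sigma,
                                 cells_per_sigma).matched_to_shift(
                                     params.sigma, dx_shift,
                                     length_in_sigma, cells_per_sigma)


def demo_initial_fronts(params, grid,
                        ramp_width_sigma: float = 10.0) -> dict:
    """The two published initializations: natural and piecewise-linear.

    The linear ramp spans ``ramp_width_sigma`` dispersal lengths centered in
    the grid (the published figures do not state the original ramp extent;
    the optimum is insensitive to it, which the robustness check verifies).
    """
    center = 0.5 * (grid.x_min + grid.x_max)
    half = 0.5 * ramp_width_sigma * params.sigma
    return {
        "natural": natural_front(params, grid),
        "piecewise_linear": piecewise_linear_front(
            grid, center - half, center + half, params.equilibrium),
    }
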