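# frontcontrol

Cost-minimal spatial treatment strategies for slowing, stopping, or
reversing the spread of an invasive species along a one-dimensional front.

Managers of biological invasions — the North American spongy-moth
*Slow the Spread* program is the motivating example — must decide **where**
to spend treatment effort along an advancing population front and **how
fast** to let the invasion move. `frontcontrol` couples integrodifference
population dynamics (local reproduction + Gaussian dispersal kernel) with a
local-search optimizer that finds the cheapest *co-moving* treatment
profile holding the front at a chosen target speed v, and a policy layer
that picks the economically optimal v from the resulting cost curve.

## The model in brief

Density n(x, t) spreads leftward; investment A(x, t) (USD/ha/yr) suppresses
it. Both are sought in traveling form A(x, t) = Â(x + v t),
n(x, t) = n̂(x + v t), so the annual cost of treatment
ACT = ∫ Â(x) dx is constant in time. Two model families:

* **generic invader** (continuous time):
  dn/dt = −γn − βAn^α + K∗[rn(1 − n/k)], where α ∈ [0, 1] sets how removal
  cost scales with density;
* **spongy moth** (one generation per year) with mating disruption:
  n′ = K∗[b(n, A)], where the probability a female is fertilized,
  P = 1 − exp(−λ₀n / (2(1 + aA))), creates a mate-finding Allee effect.

Given a front shape ñ, the solver computes the minimal per-node investment
such that one step of the dynamics never advances the front beyond its own
profile shifted by |v|·Δt (closed forms; see `docs/methods.md`), relaxes
(ñ, Â) to the co-moving shape the treatment sustains, and then the
optimizer improves the shape itself by single-node modifications with an
escalating resolution schedule until no modification lowers the ACT.
Sweeping v yields ACT*(v), and NPV(v) = −ACT*(v)/δ − Cv/δ² picks the
optimal target speed given damage rate C and discount rate δ.

## Worked example

```python
from frontcontrol import (GenericParams, SpatialGrid, SpeedTarget,
                          natural_front, find_A_hat, act)

params = GenericParams(r=2.0, k=2.0, gamma=1.0, sigma=25.0,
                       beta=1.25, alpha=0.2)
grid = SpatialGrid.for_sigma(params.sigma)      # 40 sigma, sigma/20
front = natural_front(params, grid)             # untreated co-moving shape
target = SpeedTarget.for_continuous(10.0, grid) # slow to 10 km/yr
A_hat = find_A_hat(front, target, params)
print(f"ACT to hold the natural front at 10 km/yr: {act(A_hat):.2f}")
```

prints

```
ACT to hold the natural front at 10 km/yr: 39.55
```

— the annual cost (model units) of the minimal treatment that keeps the
naturally evolved front, which would otherwise advance at ≈52 km/yr, down
to 10 km/yr. Optimizing the front shape as well roughly quarters this:

```python
from frontcontrol import OptimizerConfig, optimize_front

grid10 = SpatialGrid.for_sigma(params.sigma, cells_per_sigma=10.0)
res = optimize_front(natural_front(params, grid10),
                     SpeedTarget.for_continuous(10.0, grid10), params,
                     OptimizerConfig(eps_act_rel=1e-5))
print(f"optimized ACT*: {res.act_star:.2f} "
      f"after {res.accepted_moves} accepted moves")
```

```
optimized ACT*: 9.10 after 1980 accepted moves
```

The same pipeline runs for the spongy-moth model with
`SpongyParams.normalized(r=2, k_lambda0=100, a=0.08, sigma=10)` and
`SpeedTarget.for_discrete(0.22)` (220 m/yr), reporting costs in thousand
USD per one-kilometer strip via `act_per_km_strip`.

## Command line

A thin CLI wraps the library for reproducible runs; every command writes a
JSON manifest (config hash, version, seed) next to its artifacts:

```
frontcontrol fixtures                     # demo parameter files + fronts
frontcontrol hold config.yaml             # minimal holding treatment
frontcontrol optimize config.yaml         # front-shape optimization
frontcontrol curve config.yaml            # ACT*(v) over a speed grid
frontcontrol policy config.yaml           # optimal target speed
```

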