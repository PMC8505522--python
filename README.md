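# vrank-cascade

Spatially-explicit agent-based simulation of how a natural-disaster shock
to food production cascades through an economy's trade and migration
networks — together with **VRank**, a multi-layer vulnerability index
that condenses each location's food-security risk into one number.

## Who this is for

Researchers and analysts studying disaster risk, food security and
shock propagation in agriculture-dependent regions: the package lets you
ask *what happens away from the epicenter* — how price spikes, income
losses, displacement and supply re-routing spread a localized food
output loss across locations that were never hit directly, and which
locations end up most vulnerable during the transition.

## The model

Locations (nodes) live in the unit square and are connected by three
link sets — population, food and non-food goods flows — forming a
multi-layer network. Each node runs a circular-flow economy over two
goods, food *F* and non-food *G*:

- real output `y_i = β_F x_iF + β_G x_iG` (food producers have
  β = (0.9, 0.1), non-food producers the reverse);
- the wage bill exhausts output value: `w_i = ρ y_i / L_i` with unit
  cost ρ and labor `L_i`;
- income is fully spent — a share α on food — so local market clearing
  gives `p_iF = α w_i L_i / x_iF`, `p_iG = (1−α) w_i L_i / x_iG`, the
  equal-weight price index `p_i = (p_iF + p_iG)/2`, and nominal output
  `Y_i = Σ_k p_ik x_ik`.

Two behavioral thresholds drive the cascade. Households defend a
minimum per-capita food bundle c̄ by adjusting their food budget share,
`α = clamp(p_F c̄ / w, ᾱ, 1)` — hitting the cap 1 marks a node food
insecure. Producers sell only in markets covering unit cost
(`p ≥ ρ`). Flows follow a gravity model: the propensity to migrate or
ship to neighbor *j* is `Π_ij = Π^q_ij (1 − Π^d_ij)`, a logistic in the
relative economic gain times a reversed logistic in normalized
distance; propensities normalize to destination shares and a fraction μ
of the mobile stock diffuses per tick.

**VRank** for node *i* at tick *t* is

```
VRank_it = sqrt( (p_it c̄_i)/(w_it L_it) · β · (Σ_j p_jt c̄_j)/(Σ_j w_jt L_jt) )
```

with *j* over union-graph neighbors, node bundle `c̄_i = c̄ L_i` and
dampening β = 0.85: the damped geometric mean of the node's own
minimum-bundle cost-to-income ratio and its neighborhood's. Higher is
more vulnerable; on an identical network at ratio *r* it equals
`r·√β` exactly.

A scenario runs burn-in to a stable price/wage distribution, then cuts
the food capacity of the epicenter's food producers by 40–80%,
permanently, and tracks the adjustment to the post-shock equilibrium.

## Worked example

```python
import dataclasses
from vrank_cascade import indicators, run
from vrank_cascade.fixtures import experiment_scenario

cfg = experiment_scenario(seed=0)          # 80 nodes, 50% food producers, s = 0.8
traj = run(cfg)
base = run(cfg.replace(shock=dataclasses.replace(cfg.shock, magnitude=0.0)))
ind = indicators(traj, base)
post = ind[ind.tick > traj.shock_tick]
print(post["food_labor_ratio_pct"].mean(), post["consumption_pc_pct"].mean())
```

prints (see `examples/02_single_run.py`):

```
burn-in converged at tick 315, shock at 315, post-shock converged at 723
mean post-shock food-to-labor price ratio change: +92.8%
mean post-shock per-capita food consumption change: -10.3%
```

The 80% food output loss nearly doubles the food-to-labor price ratio
relative to the no-shock baseline (food affordability collapses) while
average per-capita food consumption falls about 10% — the gap between
the two is what migration and re-routed trade absorb. The other
examples show the network generator, the VRank spatial gradient
(`+8.9%` near the epicenter vs `+4.1%` in the most distal band) and the
counter-clockwise adjustment cycles.

A thin CLI wraps the same library surface:

```
vrank-cascade run --out out/            # one scenario
vrank-cascade sweep --levels 0.4:0.8:0.1 --networks 10 --out grid/
vrank-cascade vrank --trajectory out/ --out vrank.csv
vrank-cascade report --runs grid/ --out report/
vrank-cascade fixtures --list
```

## Layout

- `src/vrank_cascade/` — `netgen` (spatial multi-layer networks),
  `economy` (node economy primitives), `diffusion` (gravity-model
  flows), `simulator` (scheduler, shock, sweep), `vrank` (the index),
  `metrics` (indicators, heat bins, cycle traces), `fixtures`
  (deterministic test networks), `cli`.
- `examples/` — four short narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameter defaults and their
  rationale, numerical choices and known limitations.
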