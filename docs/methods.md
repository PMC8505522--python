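# Methods

## Model overview

The simulator couples two decision layers on one spatial node set: a
production layer (output, trade) and a household layer (labor supply,
consumption, migration). Every node is a circular-flow economy — labor
produces output, earns the entire value of production as wages, and
spends it on the two goods — so prices and wages are fully endogenous
and the only exogenous event is the disaster: a permanent cut of food
capacity at the epicenter's food producers. There is no recovery
process, no household savings, food stocks or assets; migration is the
only coping mechanism. Capital is fixed; production always runs at
(post-shock) capacity.

Time is discrete. Each tick applies one synchronous update computed
entirely from start-of-tick values, so node ordering never matters:
production → wages → trade flows → market clearing (prices on
post-trade marketed quantities) → food-budget-share update → migration
flows → record. A run is burn-in to stability, shock, then post-shock
evolution to stability or `t_max`.

## Parameters, defaults, and why

| parameter | default | meaning / rationale |
|---|---|---|
| `n_nodes`, `food_frac` | 80, 0.5 | experiment scale: 80 locations, half food producers |
| `target_mean_degree` | 8 | spatial graphs of moderate density; the random-geometric radius is solved from the sorted pairwise distances to hit this exactly before MST augmentation |
| `rho` | 1 | unit production cost = the wage scale (numeraire) |
| `L0`, `x_major/x_minor` | 100, 90/10 | identical endowments; β = (0.9, 0.1) makes real output y = 82 equal across node types by construction |
| `alpha0`, `alpha_min` | 0.5, 0.3 | initial and minimum food budget share |
| `c_bar` | 0.35 | minimum per-capita food bundle, chosen so the baseline required share p_F·c̄/w sits strictly between ᾱ and 1 (food is neither free nor unaffordable before the shock) |
| `mu` | 0.1 | mobile fraction per tick, identical for goods and labor; changes the speed, not the destination, of adjustment |
| `a`, `b` | 1, 1 | logistic shape Π(z) = 1/(a + b·e^(−z)) |
| `gain_center`, `gain_scale` | 0.2, 0.1 | gain logistic centered at a 20% relative gain, width 10% — small gains map near zero, large gains near one |
| `min_gain` | 0.01 | actionable-gain dead band (see Numerical choices) |
| `dist_center`, `dist_width` | 0.5, 0.25 | distance penalty: logistic over the normalized neighbor distance [0, 1] |
| `signal_smoothing` | 0.1 | adaptive-expectations weight on the newest price/wage observation |
| shock | 0.4–0.8 | food-capacity cut at epicenter food nodes, permanent |
| epicenter | centroid (0.25, 0.25), 20% of nodes | circular region in the low corner quadrant; radius solved per network |
| convergence | tol 1e−6, window 10, `t_max` 5000 | a phase ends when the max relative per-tick change of all wages and price indices stays below tol for 10 consecutive ticks |

## Flow behavior

Migration gains are relative real-income differences
z = (w_j/p_j − w_i/p_i)/(w_i/p_i); only positive gains count, and the
joint weight is Π^q(z)·(1 − Π^d(d_norm)). Trade destinations are layer
neighbors plus the home market with price covering unit cost
(p ≥ ρ); markets exactly at cost stay in the destination set with zero
margin. Trade shares are the normalized profit margins (z = (p−ρ)/ρ);
a config switch routes trade through the same joint probability as
migration instead.

Three design choices make the coupled dynamics settle into a fixed
point rather than a limit cycle, all with the property that they vanish
at equilibrium and therefore do not move the fixed points:

1. **Self-limiting totals.** The quantity diffused per tick is
   μ · stock · (best candidate weight, capped at 1), not the full
   μ · stock. With full-μ diffusion, share normalization moves the
   same mass no matter how small the gains are, which overshoots any
   equilibrium and oscillates forever; scaling by the best weight makes
   flows taper smoothly as gains vanish.
2. **Actionable-gain dead band.** Gains below `min_gain` (1%) are
   ignored, and migration weights ramp linearly from zero across
   [min_gain, 2·min_gain]. Without the band the system chatters around
   the profit threshold indefinitely; with it, the state freezes
   exactly once all remaining gains are negligible. The price of this
   realism is that residual real-wage dispersion of up to ~2% persists
   at convergence.
3. **Adaptive expectations.** Agents evaluate destinations against
   exponentially smoothed price signals
   (sig_t = 0.9·sig_{t−1} + 0.1·p_t). Reacting to raw last-tick prices
   is a cobweb map: producers collectively swamp whichever thin market
   posted a high price, collapsing it, and period-2 price flips of
   factor ~5 result. Smoothing the decision signal damps the cobweb;
   market clearing, the α update and convergence detection all use
   actual values. Migration uses raw signals — wages respond to labor
   immediately, so lagging them would itself cause overshoot.

Allocation is deterministic expected-share by default (conservation is
exact to floating point and runs are bit-reproducible); a sampled mode
draws integer migrants/shipments multinomially under the run seed.

## Equilibrium structure and the equalization caveat

Because wages exhaust the value of production (w = ρy/L) and income is
fully spent, total revenue equals the total wage bill: the economy-wide
average price per unit of goods is ρ·Σy/Σx = 0.82ρ under the default
endowments. The profit threshold p ≥ ρ therefore cannot be satisfied
in every market simultaneously at uniform prices — full per-good price
equalization is structurally impossible in this economy. What the
simulator converges to is a *partial-trade* equilibrium: goods flow
steadily from producers to the markets that clear above cost, thin home
markets stay cheap, and cross-node dispersion of nominal prices and
wages persists (CoV ≈ 0.3 at the converged baseline) while *real* wages
equalize to within the dead band (CoV ≈ 0.02). Convergence in the
simulator means convergence in time — per-tick changes below tolerance
— not spatial uniformity. Note also that wL = ρy identically, so
nominal incomes are invariant to migration; migration equalizes real,
not nominal, wages.

## What the synthetic networks emulate — and what they do not

The generator reproduces the experiment's study conditions: uniform
random locations, random-geometric edges at a target density, forced
connectivity, a 50/50 producer split, identical endowments, and a
corner epicenter holding ~20% of nodes. Real regions differ in ways
the generator deliberately omits: heterogeneous endowments and
populations, directed or weighted infrastructure links, geographic
barriers, multiple crops, storage, and policy frictions. Passing tests
therefore demonstrate the internal mechanics of the cascade — price
surges, displacement waves, vulnerability gradients — under clean
conditions, not calibrated predictions for any real region.

## Numerical choices

- Marketed quantities are floored at 1e−9 goods units before price
  computation; a node at the floor is flagged `market_collapsed`.
- Nodes below one worker emit no migrants but keep their markets open
  (`depopulated` flag); incomes in VRank are floored at 1e−12.
- Producers whose every admissible market (neighbors and home) is below
  cost keep their goods on the home market and are flagged `no_market`
  — quantities must be marketed somewhere for prices to exist, and this
  keeps per-tick goods conservation exact.
- The α update uses the share reading of the consumption threshold:
  α = clamp(max(p_F·c̄/w, ᾱ), ᾱ, 1), with the node bundle c̄·L so the
  share is population-size invariant.
- VRank neighborhoods default to the union graph (the index is
  multi-layer); isolated nodes fall back to the undamped own ratio,
  flagged, which is strictly above the identical-network value r·√β —
  isolation increases vulnerability.
- Cycle orientation uses the standard shoelace convention: positive
  signed area = counter-clockwise in the (price-ratio change,
  consumption change) plane.
- Distance-to-epicenter is measured from the epicenter centroid
  (switchable to nearest-member); density is union-graph degree binned
  by quantiles so bins are populated.

## Problem sizes used in tests and the acceptance script

Unit tests run on 1–20-node fixtures; the scenario-scale checks use the
full 80-node configuration, 5 shock levels × 10 networks (50 runs plus
10 baselines), the sizes the experiment defines. A full 80-node run
converges in ~700–1600 ticks and takes well under a second, so the
entire grid completes in under a minute.

## Known limitations

- No recovery dynamics, savings, stocks, or financial/public layers.
- Goods are not re-traded: shipments go producer → market in one hop,
  so remote nodes with no food-producing neighbors can stay expensive
  food islands indefinitely.
- The dead band leaves sub-percent arbitrage unexploited by design.
- Time is abstract ticks; no calendar mapping is implied.
- The box-plot summaries are descriptive; no statistical inference is
  attached to sweep distributions.
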