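# Methods

## The process being modeled

In the early postnatal lung, tropoelastin (TE) monomers secreted into the
extracellular space self-aggregate (coacervate) into micron-scale TE
spheres, which crosslink onto a pre-existing collagen/fibrillin scaffold to
form the elastic cable line element of the alveolar septa. The package
models this as a four-stage stochastic cellular automaton on a 2-D torus:
monomer production, monomer diffusion, sphere nucleation/coalescence/
splitting, and size-gated attachment to the scaffold. All randomness flows
from one master seed through named sub-streams (production, monomer motion,
nucleation order, sphere motion, split axes), so any single process's
randomness can be varied independently and every run is bit-reproducible.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `n` | 200 | cells | domain side; 1 cell = 1 μm |
| `total_Time` | 2400 | steps | run length (~57.6 days) |
| `generate_Time` | 500 | steps | production window (~12 days) |
| `generate_Tol` | 0.04 | content | quantum added per production event |
| `generate_Rate` | 0.032 | 1/step | per-cell event probability |
| `sigma1` | 0.7 | content | single-cell nucleation threshold |
| `sigma2` | 2 | content | Moore-neighborhood nucleation threshold |
| `delta1` | 42 | px | droplet split size (≈6.5 μm diameter disk) |
| `delta2` | 38 | px | minimum size to crosslink (≈0.9 δ₁) |
| `shape` | square | — | scaffold tiling (square/hexagon/triangle) |
| `linewidth_px` | 4 | px | cable line width |
| `tile_area_px` | 2500 | px | enclosed area of one periodic unit |
| `brownian_multiplier` | 1.0 | — | motion applications per step |
| `spatial_fraction` | 1.0 | — | producing fraction of the domain |

Defaults reproduce the model's standard parameter table exactly.

## Diffusion and the time scale

Monomer diffusion is the Margolus block automaton: the torus is cut into
2×2 blocks, alternately aligned with the even and odd grids, and each block
rotates its four values ±90° with equal probability (one coin per block).
This is a conservative permutation of cell values — total content is
conserved to machine precision, and the *value histogram* is invariant;
"mixing" is purely spatial.

A tracer advected by this rule performs a persistent walk: each rotation
moves it exactly one cell, and the next rotation either continues that move
(probability 1/2) or turns 90°, never reversing. The lag-1 step correlation
is exactly 1/2 and all higher lags vanish, giving the closed form
MSD(t) = 2t − 1 px². The factor 2 is what makes the physical calibration
consistent: 2-D Brownian motion has MSD = 4Dτ, so one step of lattice MSD 2
corresponds to 2λ_l² = 4Dλ_t, i.e. the walk relation λ_l² = 2Dλ_t used by
`calibration.time_scale`. `experiments.brownian_msd_validation` verifies the
simulated slope against this closed form (agreement ~1%).

With η = 1.9 Pa·s, d = 1 μm and T = 310 K, Stokes–Einstein gives
D ≈ 2.39×10⁻¹⁶ m²/s (the reference value 2.412×10⁻¹⁶ back-solves to T ≈ 313 K;
the temperature is configurable and both lie within 2%). At the reference
D, λ_t ≈ 2072 s ≈ 0.024 days/step. Note a tension in the calibration
itself: the ~800-step formation interval is often read against the observed
8–10 days of septal development, yet 800 × 0.024 ≈ 19 days. This package
uses the λ_t mapping consistently and surfaces step counts alongside day
equivalents, so users can judge either reading.

## Sphere geometry and bookkeeping

Spheres are disks described by an integer center, a real conserved mass in
content units, and a derived area `max(1, round(mass/σ₁))` px — one
nucleation quantum per pixel, so a bare σ₁ nucleation yields the minimal
1-px (1 μm) sphere and δ₁ = 42 px corresponds to the largest observed
~6.5-μm droplets. Mass is the conserved ledger quantity: at every step,
cumulative production equals field content + sphere mass (+ directly bound
content in the ablation) to 1e-6 relative, and the suite checks this.

Numerical/tie-break choices:

- **Threshold strictness.** Nucleation thresholds fire at ≥ (a value that
  *reaches* σ fires); size gates are strict > (a sphere must be *larger
  than* δ to split or attach). Area 42 does not split, 43 does; area 38
  does not attach, 39 does.
- **Nucleation order.** Candidate cells are scanned in a seeded random
  permutation; consumed cells are zeroed immediately, so content is
  consumed at most once per step and σ₁ consumption can pre-empt an
  overlapping σ₂ neighborhood.
- **Splitting.** An oversize sphere of area a divides into areas
  ⌈a/2⌉ and ⌊a/2⌋ with mass partitioned proportionally (exact halves for
  even a); the fragments sit one cell apart along a uniformly random axis.
- **Contact.** Two spheres are in contact when their center distance (on
  the torus) is ≤ r_i + r_j + 1 cell, r = √(area/π). Contacting free
  spheres merge by transitive closure into one sphere at the mass-weighted
  centroid (wrapped, rounded).
- **Attachment is absorbing and rigid.** Crosslinked spheres never move,
  never split, and never merge with each other; a free sphere contacting a
  crosslinked sphere is absorbed into it (mass only — the crosslinked
  center is fixed). This keeps the attached count and attached area
  monotone non-decreasing, which the engine enforces as an invariant. The
  mass-weighted-centroid rule is reserved for free-free merges for the same
  reason: moving a crosslinked sphere to a centroid would contradict
  crosslinking.
- **Excluded volume.** A free sphere's move is cancelled when the
  destination footprint would overlap a cable cell (periodic
  distance-to-scaffold ≤ radius, computed once per scaffold by an EDT on a
  3×3 tiling).
- **Step order.** production → monomer stirring → nucleation → split →
  attach → sphere moves → merge → re-split of any oversize free merge
  product. The Brownian-intensity knob applies its multiplier to both the
  stirring and sphere-move phases (integer part, plus a Bernoulli draw on
  the fractional part).

## Scaffold geometry

Cable lines are straight segments rasterized with a symmetric brush
(pixel-center distance < linewidth/2, centerline offset by (w−1)/2 so an
axis-aligned line is exactly w px wide) into a periodic tile that is then
tiled over the torus. Tiling periods are snapped to divisors of n on each
axis so periodicity is exact; the hexagon and triangle unit polygons are
mildly sheared from regular when the ideal period is not a divisor, but
their enclosed per-unit areas are matched to `tile_area_px` exactly
(2500 px² by default on the 200-px domain, i.e. ~50-μm units — several
units per domain, as in the septal geometry). Adjacency ("next to the
cable") is 8-connectivity with wrap, consistent with the Moore neighborhood
used for nucleation.

## The monomer-only ablation

The ablation asks how long cable formation would take if TE monomers bound
the scaffold individually, without the sphere intermediate. Nucleation is
disabled; each step, every scaffold-adjacent cell fires with probability
`p_bind` (default `generate_Rate`) and transfers **one production quantum**
(`generate_Tol`) of its content to an immobile bound-content ledger — the
exact time-reverse of the production rule, introducing no new constants.
The bound ledger is reported as attached area through the same mass→area
rule, so completion times are directly comparable.

The quantum-per-event rule is the package's design choice for the
under-specified direct-binding mechanism, on the grounds that "monomer
binding alone" means monomers bind one at a time; an alternative
whole-cell-per-event rule is available as `bind_whole_cell=True`. The
choice matters: quantum binding is production-rate-limited and completes in
~3500 steps (~80 days, ~5-fold slower than the sphere-mediated ~650 steps),
while whole-cell binding is diffusion-limited and completes in ~1200 steps
(~28 days, ~1.8-fold). The headline several-fold/45-day comparisons are
therefore reported together with the binding rule and `p_bind` used.
Completion is measured on an extended 9600-step horizon, since the ablation
is far from plateau at the standard 2400 steps.

## Observables and "completion"

Per step the engine records total free-monomer content, the count of
nonzero monomer cells, attached/unattached sphere counts and pixel areas,
and the mean unattached-sphere area ignoring spheres under 3 px (the
convention used when reporting average TE size). "Formation of the cable" has
no canonical endpoint in the underlying biology, so it is operationalized
as `completion_time(series, q)`: the first step at which attached area
reaches a fraction q (default 0.95) of its end-of-run value, with a
"not reached" sentinel when nothing ever attaches.

## What the simulations do and do not show

All experiments are generated internally; there is no external data. The
generator's defaults are the study conditions: a 200×200 μm² septal patch,
a 12-day production window, and the nucleation/size thresholds calibrated
to observed 1–6 μm TE spheres. Sweep presets cover the standard experimental
designs (spatial concentration over 20-fold with totals conserved,
production window 200–800 steps with totals conserved, Brownian intensity
1.0–2.5×, σ₂ ∈ {2,3,4}, σ₁ and (δ₁,δ₂) variations, three scaffold shapes,
Gaussian production profiles). The acceptance tests run the sweeps on a
half-size (100×100) domain with 5 seeds — the orderings they check are
insensitive to domain size, and the standard-run and ablation checks use
the full 200×200 domain.

The model is 2-D, treats the scaffold as rigid and immortal, ignores
monomer degradation, mechanotransduction and collagen realignment, and
reduces crosslinking chemistry to an irreversible size-gated event. Passing
tests therefore validate the self-organization logic (production →
coacervation → coalescence → anchoring) and its parameter sensitivities,
not any quantitative fit to in vivo imaging.

## Known limitations

- Sphere footprints are ideal disks; contact and scaffold overlap use
  center-distance tests, so very aspherical aggregates are not represented.
- The Gaussian temporal profile maps the window onto μ ± 3σ of the normal
  pdf and renormalizes to conserve totals; other mappings are possible and
  would change the transient (not the total).
- `completion_time` is relative to the end-of-run value, so runs truncated
  mid-growth report optimistic completion; the ablation horizon is extended
  for this reason, and comparisons should use the same horizon policy.
- On domains whose side has few divisors, period snapping can distort the
  hexagon/triangle tilings noticeably; the builder enforces the equal-area
  invariant and rejects degenerate tilings.
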