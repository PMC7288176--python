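# Methods

This note documents the model, the numerical methods and the design
choices behind `ampersim`, in the spirit of a solver manual: what is
computed, with which defaults, and what the tests do and do not show.

## Model

One axisymmetric unit cell (radius 1 after scaling by the cell radius
`a1*`) represents the hexagonally perforated membrane. Regions, from the
electrode up: selective membrane Ω1 (`0≤z≤b1`, product only, diffusivity
1), enzyme Ω2 (full-width slab `b1≤z≤b2` plus the enzyme-filled hole
bottom `b2≤z≤b3`, diffusivity `D2`), outer diffusion layer Ω3 (open hole
top `b3≤z≤b4` plus the slab `b4≤z≤b5`, diffusivity `D3`), and the
impermeable carrier Ω4 (the annulus outside the hole wall `r=a(z)` for
`b2≤z≤b4`), which carries no field and enters only as zero-flux walls.

Dimensionless fields (concentrations over `Km`, time over `a1*²/D1*`):

* product `P` on Ω1∪Ω2∪Ω3: `∂t P = D ΔP + σ² S/(1+S)·1_{Ω2}`,
* substrate `S` on Ω2∪Ω3: `∂t S = D ΔS − σ² S/(1+S)·1_{Ω2}`,

with `σ² = Vmax a1*²/(Km D1*)` the Damköhler number. Boundary conditions:
`P=0` at the electrode (instant oxidation) and at the bulk top; `S=S0` at
the bulk top; zero flux on the axis, outer radius, hole wall and carrier
faces. The substrate has no equation in the selective membrane; zero
normal flux at its top face Γ1 is the unique mass-conserving closure.
Interface matching (value and normal-flux continuity at Γ1/Γ3) is imposed
weakly by using one continuous field per species with region-wise
diffusivity in a conforming Galerkin discretization — no explicit
interface equations are needed.

Initial state: `S=P=0` everywhere; the bulk Dirichlet values are applied
from the first time step (the initial discontinuity at the top boundary
is a modelling idealization of immersing the sensor at t=0).

Outputs: `i(t) = ∫₀¹ ∂z P|_{z=0} r dr` (no 2π factor; all reported
integrals use the r-weighted measure consistently), its long-time limit
`I`, and the half-time `T½` (first `t` with `i(t)=I/2`, linearly
interpolated between samples). The dimensional conversion is
`i* = 2 ne F D1* Km / a1* · i`; the printed dimensional and dimensionless
current-density formulas in the source literature differ by this factor 2,
and the package follows the dimensionless convention for everything it
reports (ratios, orderings and `T½` are unaffected).

## Geometry and descriptors

The hole wall `a(z)` interpolates the throat `a2` and mouth `a3`
(`a2 ≤ a3`): cylinder (constant `a2`), cone (linear), paraboloid
(quadratic, vertex i.e. zero slope at the narrow end), concave paraboloid
(quadratic, vertex at the wide end). **Orientation convention:** *upward*
shapes carry the throat at the hole top `z=b4`. This choice was fixed by
transport physics: with the constriction in the fast outer layer and the
wide end on the enzyme side, upward shapes have the lower series
resistance and hence the higher current, and the upward concave paraboloid
(the widest channel of the seven) is the maximal-current shape — the
ordering the study design expects. `GeometrySpec(flip_orientation=True)`
swaps the convention. Perforation level `α = 1−a2`; filling level
`γ = (b3−b2)/(b4−b2)`. With the mouth fixed at `a3=0.1` the admissible
perforation range is `α ∈ [0.9, 1)`.

## Discretization

* **Mesh.** Block-structured, boundary-fitted quadratic (6-node)
  triangles: an inner block mapped to `0≤r≤a(z)` and outer blocks over the
  full-width slabs. All nodes of wall edges (including midnodes) lie
  exactly on `a(z)`; since every profile is at most quadratic in `z`, the
  isoparametric edges reproduce the curved wall to round-off (mesh area =
  analytic area to ~1e-12). Axial lines always contain `b1..b4`, so no
  element crosses a region or coefficient interface; they are graded
  geometrically (ratio 1.3–1.5) toward the enzyme interface `z=b3`, where
  the reaction boundary layer of width `δ ≈ sqrt(D2(1+S0)/σ²)` sits
  (`δ ≈ 0.011` at the study operating point), with smallest size
  `h_min ≈ δ/4` (default profile). Degenerate fillings `γ=0`/`γ=1` are
  meshed with Γ3 collapsed onto the carrier planes; `α=0` collapses the
  cell to a radially uniform three-slab stack.
* **Weak form.** Axisymmetric Galerkin with the cylindrical measure
  `r dr dz` — the self-adjoint, volume-weighted equivalent of the
  axisymmetric strong operator (an equivalent-in-substance reformulation
  of the separate `(1/r)∂r` convention sometimes printed); the axis needs
  no special treatment because the weight vanishes there. 7-point
  (degree-5) Gauss quadrature integrates the r-weighted quadratic mass and
  stiffness exactly on straight elements.
* **Time stepping.** Implicit θ scheme (backward Euler default,
  Crank–Nicolson optional) with a Newton–Raphson solve per step;
  convergence criterion: residual sum of squares over free dofs ≤ 1e-7.
  Because the criterion is absolute, at least one Newton update is always
  taken per step (otherwise runs at `S0≪1` would satisfy the criterion
  without solving). The substrate equation does not involve the product,
  so the Jacobian is block-triangular: the substrate block is solved by
  Newton (sparse LU), then the linear product block by a cached
  factorization — exactly Newton on the full system.
* **Step ramp.** Initial `dt=0.01` (the classical half-time-evaluation
  step), growing geometrically (×1.04 default, ×1.08 fast) to a cap
  (0.2 / 0.5). Steady state needs O(100) time units at the study layout;
  steady currents are fixed points of the implicit scheme and therefore
  independent of the ramp (halving all steps moves `I` by <0.1%), while
  `T½` accuracy is controlled by the cap (`T½ ≈ 9–11` here, so the cap is
  ≈5% of `T½` and the interpolation error is well under the 2% oracle
  tolerance). On Newton failure the driver retries with `dt/4` (up to 4
  times) before propagating the failure with its time.
* **Source handling.** `S/(1+S)` is evaluated with `S` clamped at zero
  inside the source only, with the exact (semismooth) derivative — zero
  where clamped — so Newton keeps its fast local convergence; iterates are
  never clamped. A bounds guard rejects states with
  `S ∉ [−ε, S0(1+ε)]` or `P < −ε·max(P)` with `ε = 2e-2`: quadratic
  elements started from the discontinuous initial condition produce
  percent-level Gibbs ripples on the first few steps on coarse meshes, so
  the guard is sized to catch solver blow-up, not discretization ripples
  (an approximate, not exact, discrete maximum principle).
* **Current extraction.** Consistent boundary flux: the interior weak
  residual summed over the electrode Dirichlet nodes. This estimator is
  conservative and superconvergent (measured self-convergence order ≈ 4.6
  on nested meshes, order ≥ 2 guaranteed by the quadratic elements); a
  direct-gradient estimator cross-checks it to <0.5%.
* **Steady detection.** `I` is declared when `|i(t)−i(t−w)| ≤ ε_ss·i(t)`
  with window `w=1` and `ε_ss=1e-4`, not before `t_min=5` (so the initial
  dead time of an inert run is not mistaken for steady state); tightening
  `ε_ss` tenfold moves `I` by <0.1%.
* **Determinism.** Assembly order is fixed and nothing is randomized:
  reruns are bit-identical.

## Oracles

The solver is validated against an independent 1-D path in the fully open
limit (`α=0`, radially uniform):

* a finite-volume three-layer transient solver on its own graded grid
  (different discretization, different code path), matched to the 2-D
  solver within 0.1% on `I` and `T½` across `σ² ∈ {1, 10², 3.33×10⁴}`;
* a closed-form linear-kinetics steady current (hyperbolic profile in the
  enzyme layer, linear in the passive layers, flux-matched; evaluated in
  overflow-safe tanh/sech form), which the finite-volume solver reproduces
  to 0.1% at `S0=10⁻³` — and which itself was verified against a fine-grid
  solve before being frozen as an oracle.

Mass balance provides a third, internal check: at steady state the
substrate influx, the total Michaelis–Menten consumption and the summed
product efflux (electrode + bulk) agree to <0.1% on the default mesh using
*direct-gradient* flux integrals (so the closure measures genuine
discretization error and shrinks under refinement; the consistent-flux
ledger closes to solver tolerance by construction).

## Parameter defaults

The default configuration is the study layout: `b1..b5 = 2, 4, b3(γ), 14,
16`, `a3 = 0.1`, `S0 = 1` (bulk at `Km`), `D2 = 3`, `D3 = 6`,
`σ² = 3.33×10⁴` (deeply transport-limited: reaction layer `δ ≈ 0.01`
versus hole length 10). Two solver profiles exist: `default`
(`h=0.4`, `h_min≈δ/4`, radial counts 6/8, `dt→0.2`) for production runs
and `fast` (`h=0.8`, `h_min≈δ/2`, 4/5, `dt→0.5`) for sweeps and CI; the
two agree on all orderings and differ by <1% in magnitudes. The 3×3
property grid used by the test suite is `α ∈ {0.90, 0.93, 0.96}` ×
`γ ∈ {0.1, 0.5, 0.9}` per shape (at `α=0.90` the throat equals the mouth
and all seven shapes coincide — a built-in degeneracy check).

## Findings the tests encode

At the study operating point the simulations reproduce the expected shape
ordering — cylinder minimal current, upward above downward pairs, upward
concave paraboloid maximal current and maximal half-time — and `T½`
increasing with filling level. They also show, robustly across mesh and
step refinement, that the steady current *decreases* with perforation
level (`I ∼ a2²`: closing the throat throttles the only transport path)
and *decreases* with filling level (enzyme gel at `D2 = D3/2` raises the
series resistance of the channel; `I(γ=0.9)/I(γ=0.1) ≈ 0.6`), and that
the half-time is nearly flat (slightly decreasing) in `α` with the
paraboloid-down shape, not the cylinder, as the fastest responder. A
series-resistance estimate, `I ≈ S0 / Σ ℓ_k/(D_k π a_k²)` along the
bulk→electrode path, predicts all of these directions and magnitudes;
acceptance tests asserting the opposite directions are expected to fail
and are left failing rather than tuned.

## Limitations

* The bulk is ideally stirred (`S=S0`, `P=0` at the top plane); no
  convection, product inhibition, reversible kinetics, mediator or
  interferent chemistry.
* The carrier is perfectly impermeable and the cell perfectly periodic;
  3-D lattice effects beyond the axisymmetric reduction are not modelled.
* The discrete maximum principle is approximate (quadratic elements);
  transient ripples up to ~1% of `S0` can appear on coarse meshes near
  the initial front.
* `a3=1` with `a2<1` (zero-thickness carrier plane) is not meshable by the
  block-structured generator and is rejected.
* The synthetic study conditions probe a slender-hole regime (hole length
  10× the cell radius, radius ≤0.1); conclusions about shape ordering
  should not be extrapolated to stubby perforations without re-running the
  sweeps.
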