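# Model and methods

`epimech` simulates an epithelial monolayer as a three-dimensional hybrid
cell-centre/vertex model and uses it to study laser-ablation wound healing
driven by an apical actomyosin purse-string, with optional lateral
contractility.

## Geometry

Each cell is represented by an apical and a basal centre (*node*), both
independent degrees of freedom.  Each monolayer side is triangulated over
the projected node positions; one *vertex* sits at the barycentre of every
triangle and is, by default, *constrained*: its position is the arithmetic
mean of its three parent nodes (interpolation weight 1/3 per node), so the
global unknowns are the node positions plus a small set of free vertices.
Cell boundaries are the closed loops of vertices around each node; joining
the apical and basal sides with vertical and diagonal bar segments makes
each cell a prism-like polyhedron.  A mirrored ring of boundary nodes that
carry no cell closes the polygons of the outermost cells; ring nodes and
the outermost cell centres are held fixed throughout (their measured
counterparts move by well under 1% of the patch size in the experiments
this model emulates).

Two bar networks carry the mechanics:

* the **nodal network** — in-plane triangulation edges on each side,
  apical–basal verticals, and one diagonal per edge (lower-id apical node
  to higher-id basal node, a convention fixed here because the published
  construction leaves the diagonal pattern unspecified);
* the **vertex network** — the polygonal cell-boundary segments on each
  side (junctional cortex), plus lateral verticals (one per triangle
  present in both layers) and one diagonal per matched lateral face,
  oriented by a deterministic corner rule so both adjacent cells agree.

Cell volume is computed from a signed-tetrahedron decomposition: apical
and basal caps are fanned from their nodes, each lateral quad is split
along its stored diagonal, and every face triangle is coned to the cell
midpoint (the mean of the two nodes).  This handles non-planar lateral
quads deterministically; it agrees with convex-hull volumes to 1e-9
relative on convex prisms.

Triangle quality is measured as longest-edge over shortest-edge; this
aspect ratio is 1 exactly for equilateral triangles and any strictly
monotone stretchedness measure would preserve the semantics of the
remeshing rule below.

## Energy and equilibrium

The total energy is

    W = W_N + W_V + W_Vol,

with a quadratic extension energy `(k_N/2) Σ s (l − L)²` over nodal
segments, two branches per vertex segment — a viscoelastic branch
`(k_V/2) s (l − L)²` whose rest length L remodels (below), and an elastic
branch of stiffness `k_V0` anchored at the segment's birth length L0 whose
tension is the active law `σ_V = k_V0 (ε_e + Υ̂)`, `ε_e = (l − L0)/L0` —
and a volume penalty `(λ_Vol/2) Σ ((V − V0)/V0)²` over cells.  `s` is a
per-segment stiffness scale (1, or 0.01 inside ablated cells).  The
elastic-branch energy is taken as `(k_V0/2) L0 ε_e² + k_V0 Υ̂ l`, the
simplest potential whose length-derivative reproduces the published
tension law; only the tension itself is prescribed by the source model, so
the energy form (and hence a contractility force constant per unit Υ̂) is
a design choice here.

Equilibrium is stationarity of W with respect to all free unknowns: node
positions (constrained vertices contribute through the 1/3 chain rule) and
the free vertices.  Dirichlet conditions are imposed by elimination — fixed
nodes simply have no columns in the point-to-DOF map.  The residual and the
analytic tangent (exact segment and volume Hessians, including the
rank-one volume term and the implicit rest-length softening) are assembled
sparsely; both are validated against central finite differences in the
test suite (relative error < 1e-5 for the gradient, < 1e-4 for the
tangent).

### Units and the internal length scale

User-facing coordinates are in μm (default monolayer height 35 μm).  The
published stiffness/penalty values (k_N = 0.3, k_V = 1.0, k_V0 = 0.05,
λ_Vol = 20) are dimensionless and internally inconsistent with raw-μm
geometry: the extension-based network terms scale with segment length
while the strain-based elastic branch and the volume penalty do not, so at
35-μm heights the volume penalty would be orders of magnitude too weak
relative to line tension, and the purse-string amplitude needed for
closure would be far from the reported one.  The model therefore
nondimensionalises all lengths by a characteristic length
`length_unit_um` before assembling energies.  Its default (60 μm) was
fixed once so that the default wounded patch operates at the published
operating point — per-cell volume deviations reaching the 5–10% band
during closure at λ_Vol = 20 and a finite closure threshold in the apical
contractility near its reported value.  It is an explicit configuration
knob, as is the patch spacing.

## Rheology

Vertex-segment rest lengths evolve by

    (1/L) dL/dt = γ ((l − L)/L − ε_c),

so L is stationary exactly when the strain reaches the intrinsic
contractility ε_c; at ε_c = 0 the branch behaves like a Maxwell fluid.
Nodal segments do not remodel (γ = 0 for them): the nodal network is a
purely elastic scaffold whose plasticity comes only from remeshing events,
which rebuild segments stress-free.

ε_c is applied to the **in-plane (junctional)** vertex segments only;
lateral vertex segments (verticals, face diagonals and intermediate-vertex
spokes) remodel with ε_c = 0.  This design choice reflects that the
contractile set point lives in the junctional actomyosin cortex, and it is
forced by the mechanics: a persistent contractile set point on 35-μm-scale
lateral segments would overwhelm every restoring force at any choice of
length unit (the extension-based energies make that ratio
scale-invariant), collapsing the monolayer — which the modelled system
does not do.

Time discretisation uses the θ-weighted scheme (θ = 0.5 by default:
second-order, unconditionally stable; order verified numerically against
a fine-step ODE oracle), rearranged to the linear update
`L_{n+1} = a + c·l_{n+1}`.  That affine form is substituted symbolically
into the residual, so every Newton iterate sees rest lengths consistent
with its trial geometry, and `dL/dl = c` enters the tangent.

## Solver

Each increment solves g(x, y_w) = 0 by Newton–Raphson with a backtracking
line search on the merit ½‖g‖² (Armijo constant 1e-4, minimum step 2⁻¹⁰),
converging to ‖g‖ < 1e-10 with a stationary final iterate.  Two
robustness devices handle the strongly nonlinear episodes around cell
removal: Levenberg damping (μ escalated tenfold whenever the pure Newton
direction yields no descent, relaxed geometrically after accepted steps)
and a trust-region cap on the step norm.  Linear solves use a sparse
direct factorisation (problem sizes ≤ a few thousand unknowns).  The
time-step schedule is Δt = 0.6 min during the recoil phase (t ≤ 6 min)
and 1.0 min afterwards; a step that fails to converge is retried with Δt
halved (up to 8 times, then the run aborts, retaining partial outputs),
and the schedule value is restored after a success.  Remeshing happens
only between converged steps.

## Remeshing and apico-basal intercalation

After every converged step, each side is re-triangulated independently by
local edge flips toward the Delaunay (in-circle) criterion, with an
aspect-ratio gate: a flip is accepted only if the worst post-flip aspect
ratio satisfies `r_new < (1 + tol_r) · r_old`.  At tol_r = 0 the pass is
the standard Lawson flip algorithm and reproduces the library Delaunay
triangulation on meshes of the quality the generator produces (the gate
can, on adversarial geometries, defer a Delaunay flip that worsens the
aspect ratio; the published rule is ambiguous on this point and the
permissive reading is adopted).  tol_r defaults to 0.3, chosen once so
that stretched wound-edge cells intercalate reliably rather than locking;
it is exposed in the configuration.

Because the two sides flip independently, their edge sets may disagree.
Every disagreement must remain a *pairable* single-flip quad: the apical
layer holds edge (i,j) where the basal layer holds (k,l) of the same four
cells.  Each such quad is stitched by one **intermediate vertex** — a free
degree of freedom born at the mid-height average of the four bridged
vertices — whose six stitch triangles close the four cells' lateral
surfaces; four spoke segments tie it to the bridged vertices with
stress-free birth lengths.  When a later flip restores agreement, the
intermediate vertex and its spokes are deleted and ordinary quads return.
A flip that would create an unpairable disagreement is deferred to a later
step.  Forcing the two layers equal (a configuration flag) reproduces a
pure-prism model in which intermediate vertices can never arise.

In addition to the geometric flips, a **junction-collapse intercalation**
acts at the wound: when the purse-string shortens an apical perimeter
junction below `junction_collapse_fraction` (default 0.25) of the initial
mean junction length, the squeezed cell is forced off the wound edge by
flipping the corresponding node edge (at most one per step, shortest
first, subject to the same validity and pairability guards).  This is the
junction-collapse T1 rule of classical vertex models; without it the
aspect-ratio remesh alone fires only after substantial cell-centre motion
and the purse-string squeeze can lock into a symmetric stall.

All remesh-created segments are born stress-free (L = L0 = current
length), so connectivity changes never introduce force jumps beyond the
active Υ̂ term.

## Wounding protocol

Ablation (t = 0) marks an edge-connected, interior set of cells: their
volume penalty is removed, and stiffness is degraded to 1% — for nodal
segments whenever *any* parent cell is ablated (the cell body loses its
anchoring), for vertex segments only when *all* parent cells are ablated,
so the wound-perimeter junctional cortex, which belongs to the surviving
cells too, keeps full stiffness and can carry the purse-string.  Vertices
whose parent triangle has an ablated-cell majority are released from the
barycentric constraint (free unknowns), which suppresses zig-zag artifacts
at the perimeter while leaving the live-majority perimeter vertices
coupled to the surviving cells' centres — the transmission path that lets
wound-edge cells move and intercalate.

Because recoil is the release of *pre-existing* tension, every run first
pre-equilibrates the intact patch (default 30 min of model time) so the
junctional rest lengths reach the ε_c homeostatic strain; the clock is
reset and ablation applied to the prestressed state.  Without this phase
a freshly built (stress-free) patch shows no recoil at all.

From the activation time t_w = 6 min, wound-edge contractilities follow

    Υ̂_A = Y_Ac (1 − (t − t_w)/400),   Υ̂_L = Y_Lc        (t > t_w),

clamped at zero; the apical schedule acts on the apical perimeter
junctions, the lateral one on the wound-edge lateral segments.  Degraded
cells are cleared progressively: at most one cell per step is removed once
its apical polygon drops below `removal_area_fraction` (default 0.4) of
the initial mean cell area; its node leaves both triangulations and the
cavities are re-triangulated (identically in the two layers when their
boundary cycles agree, else independently followed by flip re-alignment).
The wound is declared closed — a latching flag — when the apical wound
area falls below 25% of its post-recoil maximum or the last degraded cell
is resorbed; run outcomes are strongly bimodal (closing runs reach well
under 15% of the recoil maximum, leaving at most one cone-shaped debris
cell whose basal side lags — the apico-basal closure asymmetry — while
non-closing runs stall above half of it), so the declaration threshold
sits between the two clusters and any value there classifies identically.  Clearance at a few percent of cell area (a literal reading
of "removal of degraded cells" as a final cleanup) is unreachable in this
implementation: the purse-string/line-tension balance stalls far above
it, so closure would never complete; treating clearance as debris removal
at half the nominal area restores the reported phenomenology and is the
package default.

## Observables

* **Apical wound area**: shoelace area of the wound perimeter projected
  along the apico-basal axis, computed as the sum of the ablated cells'
  apical polygon areas (exactly equal, since shared edges cancel).
* **Relative height**: 1 − depth/35 μm, where the depth is the distance
  between a reference apical level — the 95th percentile of apical z in an
  annulus 2–4 cell diameters from the wound centre (a deterministic
  surrogate for fitting a line across the highest apical points either
  side of the wound in orthogonal image views) — and the mean apical z of
  the perimeter.  The surrogate tracks trends, not absolute imaging
  values.
* **Wound-edge counts**: live cells incident to the perimeter and the
  number of perimeter junction segments.
* **Volume deviations**: mean and max of |V − V0|/V0 over live cells.

## Synthetic patches

Experimental centre tables are not distributed, so patches are generated
as jittered hexagonal lattices clipped to a square: spacing 9 μm (the
patch density is a free knob of the study; this value makes an 80–205
cell patch tens of μm across, the scale of the modelled ablation
experiments), jitter uniform in a disc of 0.2 lattice spacings, height
35 μm.  A deterministic Lloyd-style relaxation of only the offending
points removes boundary slivers so that every triangle of the patch has
aspect ratio below ~4.5, matching the quality of segmented epithelial
centre clouds.  The generator is seeded and bit-reproducible.  What these
patches do *not* emulate: the cell-area dispersion, curvature and
anisotropy of real wing-disc tissue; conclusions from passing tests
therefore concern the model's mechanics, not biological variability.

## Known limitations

* Closure proceeds by purse-string squeezing plus progressive clearance
  and intercalation; its timing on small scaled-down patches (closure
  within ~10–20 min of activation) is faster than the tens of minutes of
  the full-size system, and depends on the clearance threshold.
* The discrete T1/clearance cascade makes outcomes near the closure
  threshold jumpy in the amplitude and in the patch seed; the threshold
  is therefore located by a full upward grid scan rather than bisection.
* Each clearance event hands the removed cell's footprint to its
  neighbours in one step, which can push the mean volume deviation
  transiently toward (occasionally just past) the 10% band on some patch
  geometries before the solver re-equilibrates.
* One intermediate plane only: lateral myosin is uniform along the
  apico-basal axis; finer apico-basal discretisation is out of scope.
* No cell proliferation; removed cells' volume is lost, which is what
  leaves the final height below its initial value after closure.
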