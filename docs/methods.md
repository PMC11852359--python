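# Methods

`cytomech` simulates the mechanics of epithelial-like cells embedded in an
extracellular-matrix (ECM) gel under a small external pressure, and asks how
the stress carried by each cellular component changes when the gel is stiff
(alginate-like, E = 56,200 Pa) versus soft (medium-like, E = 30 Pa). The
model follows the classic tensegrity picture of the cytoskeleton: a
continuous network of pre-tensioned actin cables balanced against
discontinuous compressed microtubule struts, coupled to continuum
representations of cytoplasm, nucleus, the bounding membranes, and the gel.

## Model

**Geometry.** Each cell is two nested spheres — cytoplasm of radius 10 µm
bounded by a cortex membrane, nucleus of radius 5 µm bounded by a nuclear
membrane — with a 6-strut / 24-tendon tensegrity whose twelve nodes are tied
to cortex mesh nodes. Cells sit inside an axis-aligned ECM box: a single
cell centred in a 40 µm cube, or eighteen cells in two horizontal 3×3
layers on a regular 25 µm grid (75×75×50 µm box). The model is continuous:
the cortex is the shared interface surface between cytoplasm and ECM
tetrahedra, the nuclear membrane between nucleus and cytoplasm, with no
duplicated nodes and no contact conditions. An affine `shape_transform`
(e.g. an oblate squash) is available to deviate from sphericity; the
default is spherical, so absolute stress values are not expected to match
measurements on imaged, irregular cells — only orderings and orders of
magnitude are meaningful.

**Tensegrity form.** The regular icosahedron admits no self-stress state
for the 6-strut network: a prestressed cable net built on it simply relaxes
its own tension. The builder therefore uses the network's self-equilibrated
icosahedral configuration — three mutually perpendicular 2:1 rectangles,
vertices the cyclic permutations of (0, ±2, ±1)/√5·r, all on the sphere of
radius r. In that form equal tendon tensions t balance strut compressions
of −√6·t exactly, which the free-standing relaxation reproduces to machine
precision.

**Elements and kinematics.** Total-Lagrangian, geometrically nonlinear
throughout (the soft gel reaches ~20 % nominal strain at 6 Pa): 4-node
tetrahedra for ECM/cytoplasm/nucleus, 3-node plane-stress membranes without
bending for the two membranes, and 2-node truss members for the
cytoskeleton. The strain increment is the Green–Lagrange split
ΔE = Δe + Δη, with Δe the symmetric displacement-gradient increment and Δη
the quadratic term; the constitutive law is St. Venant–Kirchhoff on E (a
linear elastic law in the finite-strain measure). Tangents carry the
geometric (initial-stress) stiffness. Reported solid stresses are Cauchy
(push-forward at centroids); membranes report the plane Cauchy tensor in
the deformed element frame; cytoskeleton members report uniaxial stress
S11 = N/A, tension positive.

**Prestress.** Tendon prestress is rest-length controlled: an imposed
natural-length shortening ε₀, parameterized by the equivalent force
P₀ = EA·ε₀, ramped over the first solution step. A constant-force prestress
was rejected because a free (or softly embedded) network then contracts by
P/EA and sheds its own tension, leaving no self-stressed state. P₀ is the
single parameter with no agreed literature value; the default 2.0×10⁻¹² N
puts tendon stresses at ~10⁵ Pa, the order expected for prestressed actin
networks, and every acceptance ordering is verified across a 10× range
around it (`analysis/06_prestress_sensitivity.py`).

**Loads, boundary conditions, solution.** The top box face carries a 6.0 Pa
dead-load pressure on the undeformed surface (displacements are ≤4 % of the
box height even in the soft gel, so follower effects are negligible). Side
faces roll (normal displacement fixed), the bottom face is fixed
vertically. The solution has two steps — prestress ramped in 2 increments
with no pressure, then pressure ramped in 6 increments — each increment
solved by Newton iteration to a relative force residual of 1e-8 (the
factorized tangent is reused within an increment and rebuilt whenever the
residual contraction stalls; converged states are identical to full
Newton). An absolute residual floor of 1e-18 N lets load-free increments
terminate at round-off. A small-strain mode (`geometric_nonlinearity:
false`) exists for linear verification problems.

## Meshing

The mesher is structured and fully deterministic: cubed-sphere shells
radiate from the cell centre (centre fan → nucleus shells → cytoplasm
shells → ECM shells interpolated onto the cell's axis-aligned sub-box).
Prisms between shells are split into tetrahedra with quad diagonals chosen
through the minimum global node id, which makes the splitting conforming
across shared faces — including the faces between neighbouring cells'
sub-boxes in the group scene, so the 18-cell mesh is conforming by
construction. Tensegrity nodes snap to the nearest cortex mesh nodes
(attachment by shared node; an option ties them to the nuclear membrane
instead). `validate_mesh` checks orientation, element quality, interface
conformity, attachment, and boundary tagging, and every scenario mesh must
pass it before solving.

Discretization is controlled by a target edge length (default 2.5 µm,
surface grid n = ⌈2R/h⌉ per cube-face edge) or by explicit surface/layer
counts. **The scenario matrix uses identical per-cell discretization in the
single-cell and group scenes** — same surface grid (n = 4), same radial
layers in the cell, and the same ECM layer thickness adjacent to the cortex
(1.25 µm) — because per-component *maxima* are compared across layouts and
are discretization-sensitive at desk scale (the single-cell stiff-ECM
maximum moves between ~9 and ~13 Pa across mesh variants). With the matched
rule the scenes have ≈6.5k (single) and ≈55k (group) tetrahedra and a
scenario solves in seconds to tens of seconds on one CPU; finer meshes are
config knobs.

## Numerical choices and caveats

- **Near-incompressibility.** The ECM Poisson ratio 0.4777 with linear
  displacement tetrahedra is volumetrically stiff (no element-level remedy
  exists for constant-strain tets: mean-dilatation projection is the
  identity). The uniform patch test is exact regardless, and the
  stiff/soft orderings — driven by a 1,900× modulus contrast — are robust
  to it, but absolute ECM stress concentrations are somewhat underestimated.
- **Patch test.** The small-strain solver reproduces the linear confined
  compression closed form (σ_z = −p, HMH = p(1−2ν)/(1−ν)) to ≤1e-6 on any
  mesh. The nonlinear default is instead verified against the finite-strain
  closed form obtained from λ·C₁₁·(λ²−1)/2 = −p, to the same tolerance.
- **Stress maxima** are element-centroid values (exact for constant-strain
  elements); no nodal averaging, which would bias maxima downward.
- **Symmetry.** For a centred spherical cell the continuum solution is
  invariant under quarter turns about z. The structured mesh's id-based
  diagonal choices and the tensegrity (which has no 4-fold axis) leave
  localized asymmetry at the faceted cortex; the test suite checks median
  and 90th-percentile symmetry of the nodal displacement field rather than
  pointwise equality.
- **Log-scale output.** VTU exports carry a decimal-log HMH channel clamped
  below at a configurable floor (default 1e-12 Pa).
- **Determinism.** Meshing is structured (no randomness) and the solver is
  sequential, so a fixed configuration reproduces byte-identical CSV
  exports; the seed field is carried through for provenance.

## What the synthetic scenes do and do not show

The generator emulates the study *conditions* of the modeled system — the material
table (actin E = 2.6 GPa, A = 18×10⁻¹⁸ m²; microtubules 1.2 GPa,
190×10⁻¹⁸ m²; cytoplasm 100 Pa, ν 0.37; nucleus 400 Pa, ν 0.37; both
membranes 1 kPa, ν 0.3, 6 nm; ECM ν 0.4777 with the stiff/soft moduli),
the 6 Pa load, the two-step 2+6 increment schedule, and the single/18-cell
layouts — but not cell shapes derived from microscopy, a measured prestress
magnitude, or production-scale (multi-million-element) meshes. Passing
tests therefore demonstrate the *directional* mechanobiology: every cell
component (cortex, cytoplasm, nucleus, nuclear membrane) carries one to
two orders of magnitude more stress in the soft gel, the gel itself is
more stressed when stiff, the 18-cell group concentrates more ECM stress
than the lone cell, and cytoskeleton stresses and displacements are larger
in the soft gel. Absolute maxima at desk scale land in the same orders of
magnitude as experimental-scale estimates but carry no claim of numerical
agreement with any particular measured cell.

## Known limitations

- Linear tetrahedra with near-incompressible ECM (above).
- No viscoelasticity, poroelasticity, active contractility, growth, or
  contact; cells interact only through the shared elastic medium.
- The 18-cell arrangement (regular grid, 25 µm spacing) is an idealized
  layout, not a measured one; the group/single
  ECM ratio in particular depends on cell packing.
- Membranes have no bending stiffness; compressive membrane states that
  would wrinkle physically are represented by their plane-stress state.
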