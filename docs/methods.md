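# Methods

This note records the modelling assumptions, numerical choices and
limitations of `hipdea`, in the spirit of a model-description appendix.

## Contact model

Bones are rigid; each cartilage layer is a bed of independent
one-dimensional springs normal to the articular surface ("elastic
foundation"): local pressure depends only on local compression, shear and
tangential coupling between neighbouring springs are neglected, and
springs carry compression only.  The femoral body has three translational
degrees of freedom and no rotation, matching the loading conditions the
model is meant for (a prescribed joint reaction force, no moment balance).

**Strain partition.** A spring at node *i* spans both cartilage layers:
its own layer of thickness `l_i` and the opposing layer interpolated at
the contact point, together `h_i`.  With equal moduli on both sides, two
series springs share the total approach `Δd_i` in proportion to their
thickness, so each layer compresses by `Δd_i · l/h` and both carry the
identical strain `ε_i = Δd_i / h_i` and force.  One equivalent spring per
node therefore represents the two-layer stack exactly; the per-layer
quantities are recoverable from `l_i` and `h_i`.

**Constitutive laws.** Linear: stress `k ε` with the constrained modulus
`k = E(1−ν)/((1−2ν)(1+ν))`; defaults E = 11.85 MPa, ν = 0.45
(k = 44.948 MPa), literature values for human hip cartilage under fast
loading.  Non-linear: stress `H_A0 (1 − ε + 3(1+4β)/2 · ε²) ε` with
H_A0 = 0.40 MPa, β = 0.35 from experimental stress–strain data; with
β = 0.35 the quadratic coefficient is 3.6 and the law is strictly
monotone on ε ∈ [0, 1).  Poisson ratios within 10⁻³ of the
incompressible pole (ν ≥ 0.499) are rejected rather than allowed to
produce arbitrarily stiff springs.

**Strain clamp.** The foundation model is meaningless near full
compression of the layer; strains at or above 0.95 raise an error (the
solver treats such states as infeasible during the search).  The clamp is
a modelling guard, not a tuning parameter.

## Contact kinematics: node-paired gaps

Springs are anchored at the acetabular articular vertices with directions
`n_i` (unit normals toward the femur), tributary areas `S_i` by the
one-third rule on the articular surface, and a signed gap to the femoral
articular surface.  When the two surfaces share a template correspondence
— which is exactly what a statistical-shape-model pipeline provides, and
what the synthetic generator produces — the opposing point of vertex *i*
is the corresponding femoral vertex, and the gap under a rigid femoral
translation `t` is exactly linear:

    g_i(t) = (v_fem,i − v_acet,i) · n_i + t · n_i .

This small-displacement kinematics is chosen deliberately over
re-raycasting the opposing faceted surface at every iterate, for three
reasons.  First, consistency: the closed-form verification solution
assumes radial-only displacement with compression `δ0 cos θ`, which is
precisely the projected-translation kinematics; the exact surface
intersection differs from it only at O(δ²/R) ≈ 10⁻³ relative for hip-like
approaches (δ ≈ 0.2 mm, R ≈ 20 mm).  Second, discretization noise: a ray
hitting the interior of a triangle on a faceted sphere lands below the
true surface by the chordal sag, up to e²/8R ≈ 6 µm at 1 mm edges — which
the stiffness k/h ≈ 11 MPa/mm turns into spurious nodal stress noise of
order 0.05 MPa, an order of magnitude above the benchmark's
discretization error.  Node-paired gaps have no sag.  Third, the choice
of which surface anchors an exact-intersection gap is arbitrary
(acetabular-anchored and femoral-anchored measurements bracket the
continuum answer symmetrically at the same O(δ²/R)); the linear pairing
is the unbiased middle.  Raycasting (KD-tree candidate pre-filter plus
vectorized Möller–Trumbore, exhaustive fallback) remains available as
`pairing="raycast"` for surfaces without shared connectivity, and rays
that miss the opposing surface mark their springs permanently inactive
(peripheral nodes).  An explicit correspondence array covers partially
corresponded meshes (e.g. a truncated socket).

## Equilibrium solver

The residual is the Euclidean norm of the 3-vector force imbalance
`‖Σ F_i(t) − load‖`, where `load` is the joint reaction on the femoral
side; the vector norm (rather than a scalar sum of magnitudes) is the
only residual that determines all three translation components.  The
initial iterate advances along the load axis to first contact (computed
in closed form from the gap rates) and then by doubling steps while the
residual falls.  Each iteration evaluates a central finite-difference
Jacobian of the imbalance (step 10⁻⁴ mm), tries the Gauss–Newton step —
exact wherever the contact active set does not change, because spring
forces are piecewise linear in `t` there — and falls back to steepest
descent with an Armijo backtracking line search when the Gauss–Newton
step fails to reduce the residual.  Convergence: residual ≤ rel_tol ·
‖load‖, default rel_tol = 10⁻³, max 500 iterations.  Typical fixtures
converge in 1–5 iterations; the verification driver uses rel_tol = 10⁻⁶
since the deterministic benchmark costs nothing extra at that tolerance.
Loads that would drive peak strain past the clamp (e.g. a soft non-linear
layer asked to carry more than its saturation load) have no admissible
equilibrium and surface as a convergence error carrying the last iterate;
loads pointing out of the socket raise a dislocation error before the
search starts.

## Verification benchmark

Rigid concentric hemispheres of 20 and 24 mm with a 4 mm conformal
elastic layer under 2000 N.  The one-layer configuration assigns the full
4 mm to the shell (sliding contact at the ball surface, 20 mm); the
two-layer configuration splits it 2 + 2 mm (contact at the mid interface,
22 mm).  The analytic elastic-foundation solution gives
`p(θ) = p0 cos θ`, `p0 = 3W/(2πR²(1 − cos³θ_c))` over a cap of half-angle
θ_c (full hemisphere: `p0 = 3W/2πR²`) and central approach
`δ0 = h p0 / k`; its equilibrium integral is cross-checked by quadrature
in the tests.  RMSE between DEA nodal stresses and the profile is taken
over contacting nodes with θ ≤ 85°, excluding the free-boundary ring.
Because peak pressure scales as 1/R², the one-layer peak exceeds the
two-layer peak by (22/20)² − 1 = 21.0 % in this kinematics; the
acceptance script reproduces that value to float precision (reported at
one-decimal precision) together with a DEA-vs-analytic RMSE of
0.0019 MPa at 1.0 mm edges, falling monotonically with refinement
(0.0052 / 0.0034 / 0.0019 MPa at 2.0 / 1.5 / 1.0 mm).

## Mesh generation

Spherical caps are triangulated by latitude rings at uniform polar
spacing with per-ring azimuthal counts matched to the target edge length
(default 1.5 mm, the resolution of typical shape-model meshes;
verification runs use 1.0 mm), stitched by merging the ring angle
sequences; the pole is always an exact vertex, so θ = 0 is sampled.
Concentric caps (ball/shell, or all subjects of a population) share one
template triangulation sized at a common reference radius, which puts
them in exact vertex correspondence.  Generated caps carry analytic
radial normals: discretely estimated vertex normals are biased at the
free boundary, and the extrusion artifacts they cause are spurious for a
surface whose true normals are known.  Tributary areas use the one-third
barycentric rule, which conserves total area exactly.

## Cartilage predictors and the thickness map

Spherical-method thickness is measured radially from each bone's own fit
center to the joint sphere `R = (R_a + R_f)/2` — the only construction
consistent with a spherical interface; where bone already crosses the
joint sphere the thickness clamps to zero with a warning.  The
population-averaged map normalizes nodal thickness by the femoral head
radius on both sides (the femoral radius is the natural single scale of
the joint; an acetabular-radius normalization would differ only through
joint-space variation).  Leave-one-out validation is per-subject (k = n).
Prediction error is the node-to-node distance between predicted and
reference articular surfaces on the shared template; a nearest-neighbour
correspondence (deterministic lowest-index tie-break) covers
non-corresponded comparisons.

## Contact summaries

Contact area is the sum of tributary areas of contacting nodes —
consistent with the stress normalization, so that average stress ×
contact area equals transmitted force when the average is area-weighted.
The triangle-based alternative (areas of triangles all of whose vertices
touch) gives slightly smaller areas on patch boundaries.  Average stress
is area-weighted by default with a plain nodal mean as an option, since
either convention appears in the literature.  Bland–Altman agreement
reports bias ± 1.96 SD limits plus the regression of difference on pair
mean with t-based 95 % limits (n − 2 degrees of freedom).

## Synthetic data

The population generator emulates the output of a correspondence
(shape-model) pipeline: per-subject spherical femoral heads
(R_f ~ N(25, 1.5²) mm) with concentric sockets, a population-shared
smooth thickness field that scales with head radius (mean 2.0 mm, spatial
RMS 0.3 mm at the mean radius, low-order polar harmonics of degree ≤ 4 —
structure the 1.5 mm mesh can represent), and subject-specific smooth
perturbations of RMS 0.1 mm.  Fields are floored at 0.2 mm to keep the
articulating region strictly positive.  The generator is deterministic
under a seed.  The edge-case fixture truncates the socket at a chosen
coverage angle and tilts the load axis, driving the contact patch against
the rim as in dysplastic edge loading; the anisotropic compliance of the
truncated spring bed tilts the equilibrium translation beyond the applied
load axis, which is what puts the stress peak on the rim ring.

What the synthetic data does **not** emulate: real acetabular anatomy
(lunate surface, fovea, horns), aspherical bone, the labrum,
correspondence error of a real shape model, segmentation noise, or
realistic in-vivo load histories.  Tests passing on these fixtures
demonstrate the correctness of the mechanics and of the
prediction/validation machinery — not the anatomical accuracy of the
thickness map on real hips, which requires imaging data.

## Known limitations

* No shear or tangential coupling between springs and no Poisson
  expansion: equilibrium translations differ from soft-tissue FE
  solutions at the ~0.1 mm scale even when stresses agree.
* No rotational equilibrium; applied moments are not representable.
* Plain gradient-based descent on a piecewise-smooth residual: loads very
  close to the saturation capacity of a soft non-linear layer may stall
  before the tolerance and are reported as non-converged rather than
  silently accepted.
* The thickness map applies only to anatomies in the template
  correspondence of the population it was built from.
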