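# Methods

This note documents the models implemented in `footform`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer should know about. Units are fixed
throughout: mm, N, kPa (pressures), MPa (stresses/moduli), g/cm³
(densities), days (remodelling time).

## Synthetic archetypes

The three foot conditions — normal (NF), half-bound (HB), full-bound
(FB) — are generated parametrically so the whole pipeline runs offline with
known ground truth.

**Bones.** Nine bones (calcaneus, talus, tibia, fibula, five metatarsals)
are superellipsoid primitives: an icosphere is mapped radially onto
`Σ|uᵢ|^ε = 1`, scaled by per-bone half-axes expressed as fractions of foot
length L and width W, and posed by two archetype parameters — the arch
height ratio (metatarsal centroids sit at `arch·0.18 L` above the ground)
and the calcaneal inclination (the calcaneus pitches up anteriorly; 20° NF,
35° HB, 55° FB, encoding the progressively vertical calcaneus of the bound
foot). The assembly is scaled anisotropically in x/y so the bounding box
equals the subject-specific foot width and length exactly. A small seeded
jitter (2% radii, 5% exponent) de-symmetrises the shapes; every generator
is a pure function of (parameters, seed). Fidelity is topological/metric —
bone counts, dimensions, arch, inclination — not anatomical; conclusions
about real anatomy require real geometries, which these stand-ins
deliberately do not provide.

**Lattice tet meshing.** Tetrahedral meshes are built on a structured cube
lattice (Freudenthal six-tet subdivision, conforming across cubes), not by
Delaunay meshing of the surface. Each cube's inside fraction is estimated on
a 3×3×3 subsample of the solid's implicit function, and the fullest cubes
are kept until the summed-fraction volume target is met (a volume-matched
staircase: exact for box-aligned solids, within ~1% for a sphere at 5 cells
per radius). Because nodes are exact lattice points with near-unit aspect
ratio, the scaled Jacobian of every element exceeds the 0.3 quality gate by
construction; the FE module still checks it. Target edge lengths are
recorded in mesh metadata. The full foot model adds a flat-bottomed
soft-tissue envelope (superellipse footprint with a dome height field) and a
shank column up to 0.55 L, then classifies elements as bone/soft by
centroid-in-primitive tests; node sets mark the fixed shank top, the plantar
surface, the Achilles insertion (six boundary nodes nearest the
posterior-superior calcaneus), and five fascia anchor pairs (calcaneal notch
to each metatarsal base).

**Plantar pressure.** One stance phase at 50 Hz on a 16×6 sensor grid that
tiles the foot bounding box exactly (cell size = dimensions/shape, so
normalisation by foot length/width is exact and the small FB foot does not
leave half the grid dead; a fixed physical cell size is easily obtained by
passing a different grid shape). Per-region spatial kernels are Gaussians
about the region centroid; per-band temporal windows roll the load from
heel (peak activation 22% stance) through midfoot and forefoot to toes
(84%). The instantaneous force integral follows a two-Gaussian stance
template with both peaks at 1.1 body weight — a typical walking value,
chosen because no GRF magnitudes are printed for these subjects — and a
fixed-point share correction makes the regional time integrals proportional
to the configured regional load shares. Regions absent from an archetype's
scheme (toes and midfoot for HB/FB, hallux additionally for FB) carry
identically zero pressure. Stance duration is a free parameter (default 51
frames ≈ 1 s); the study subjects' stance times were not controlled or
reported. Default load shares encode the qualitative pattern: even rollover
in NF (47% rearfoot), rearfoot-focused HB (65%), rearfoot-dominated FB
(70%).

What the generator does **not** emulate: sensor noise and drop-out,
subject-to-subject anatomical variation beyond global dimensions, soft
tissue hyperelasticity, dynamic joint articulation, CT imaging physics.
Passing tests therefore demonstrate correctness of the *methods* under
controlled conditions, not clinical validity on real feet.

## Gait analytics

GRF is the exact cell sum `Σ p·a` (1 kPa·mm² = 1e-3 N). The CoP is the
pressure-weighted centroid of cell centers, undefined (masked) below a
10 N force threshold — a conventional value; none is stated in the source
protocols. Stance is detected as the first/last frame above that threshold.
CoP trajectories are normalised per trial to subject foot width/length,
resampled to 101 %-stance points by linear interpolation, then averaged
across trials (normalise-then-average; the alternative order is not
distinguishable from published materials). Regional statistics are the max
(peak) and the time-and-area-weighted mean over stance, zeros included, so
mean ≤ peak holds structurally.

**Curve comparison.** The two-group comparison of 1-D stance curves uses a
cluster-based permutation test: point-wise pooled-variance t statistics,
two-tailed threshold at the nominal α, contiguous supra-threshold runs
scored by summed |t| (cluster mass), and a null distribution of the maximum
cluster mass over group relabelings — exhaustive when at most 500
relabelings exist, otherwise 500 seeded Monte-Carlo draws with the
`(1+count)/(1+n)` convention. In the exhaustive branch the observed
labelling counts once and other relabelings only when strictly more extreme;
since the complement labelling always ties, the minimum attainable p with
3+3 trials is 1/20 = 0.05. This convention is marginally anti-conservative
at such tiny group sizes (the tied pair shares one rank); at the 10+10
trials used for operating-characteristic checks the effect is negligible,
and the measured false-positive rate sits at the nominal α.

## Shape comparison

Registration is rigid only (Kabsch updates on nearest-neighbour
correspondences); the analysis compares absolute bone sizes in mm, so scale
is never normalised. ICP is initialised by centroid shift plus
principal-axes alignment under the four proper sign disambiguations, keeping
the best converged result — plain ICP stalls in shallow minima on smooth,
near-symmetric bone surfaces. The rms is non-increasing by construction and
iteration stops when the improvement drops below 1e-8 mm. Note the
superellipsoid archetype bones are exactly symmetric under 180° flips, so a
recovered transform can differ from the generating one by a shape symmetry
while being geometrically equivalent.

Correspondence maps each template vertex to its exact closest point on the
target surface (Voronoi-region point-triangle projection with a KD-tree
candidate search over triangle centroids; the candidate radius is the
current best distance plus the largest triangle radius, so the result equals
the brute-force scan). The corresponded shapes share the template topology;
per-bone alignment is used throughout (whether bones should be aligned as an
articulated complex is an open modelling choice; per-bone is the more
conservative default). A regression-based (partial-least-squares) fit is not
used: with three specimens it is under-determined, and the downstream
outputs (error maps, Hausdorff statistics, PCA) are unchanged by this
substitution.

Signed error maps use the convention **outward positive**: a morphed vertex
outside the reference surface reads as bone growth, inside as resorption
(sign from a generalized-winding-number containment test, magnitude from the
exact surface distance). Unsigned maps are available for meshes without
shared topology. Hausdorff distances are maxima of exact per-vertex
point-to-surface distances in both directions; the "Gaussian fit" reported
alongside is the sample mean/sd of the pooled per-vertex distances. The SSM
is a PCA of stacked 3V coordinate vectors about their mean (sample
covariance, ddof = 1); modes are orthonormal, variances non-increasing, and
reconstruction with all modes is exact to machine precision.

## Finite elements

Constant-strain 4-node tetrahedra, isotropic linear elasticity, small
strains, direct sparse LU solves. Materials: bone E = 7300 MPa, ν = 0.3;
lumped soft tissue E = 0.15 MPa, ν = 0.45 — both linear elastic, so no
hyperelastic branch exists. Loads: regional mean stance pressures applied as
consistent nodal forces (p·A/3 per face node along the inward normal) on
plantar boundary faces assigned to regions by centroid; five axial spring
connectors of 200 N/mm between the calcaneal notch and the metatarsal bases
(plantar fascia); an Achilles force of 0.5 body weight distributed in equal
shares over the insertion node set, directed along the vertical tibia axis
(magnitude is prescribed by the study setup; direction and distribution are
this package's documented geometric rule). The tibia/fibula top surface is
fully fixed. Mean pressure is used as the boundary condition because peak
pressure represents a small region and instant of stance.

The solver supports per-dof constraints with prescribed values, which is
what the verification suite uses: a patch test (linear boundary
displacement reproduced with constant strain to 1e-8), the analytic
uniaxial bar (7.3 MPa on E = 7300 MPa gives strain exactly 1.0e-3), global
force balance to 1e-6 relative, and a cantilever that converges
monotonically to Euler–Bernoulli theory, within 5% at ~10 elements through
the thickness (CST elements are stiff in bending; this is their expected
convergence behaviour, not a defect). Element stresses are constant per
element; nodal fields are volume-weighted averages for visualisation only.
Contact, ligaments beyond the five fascia springs, and transient dynamics
are out of scope — the model examines one pose under mean stance load.

Note the soft-tissue layer experiences strains of order one under
physiological pressures (0.1 MPa pressure on a 0.15 MPa modulus); within
the linear small-strain model this is an accepted simplification inherited
from the material choices, and bone stresses — the quantities of interest —
are insensitive to it.

## Remodelling

The density-adaptation law is the standard daily-stress-stimulus
formulation: tissue-level effective stress `σ̄ = σ_vm (ρ_max/ρ)²`, stimulus
`ψ = n^(1/m) σ̄` with n = 10 000 cycles/day and m = 4 (prefactor 10), lazy
zone of half-width w = 0.1 about the setpoint ψ*, rate constant
c_r = 0.002 (g/cm³)/(MPa/day)/day, explicit Euler with dt = 1 day, a per-step
density cap of 0.05 g/cm³ for stability, and clamping to
[0.05, 1.8] g/cm³. The modulus follows Carter-type coupling `E = B ρ^β`
with B = 3790 MPa and β = 3, chosen so that E at a physiological cortical
density of 1.24 g/cm³ is ≈ 7222 MPa, within 2% of the uniform bone modulus
used in the FE stage. **This functional form is a documented stand-in**: the
source framework's exact equations live in supplementary material that is
not redistributed here, so the package implements the standard
continuum-damage-inspired law from the same lineage with all constants
exposed in `RemodelParams`.

The pipeline's default setpoint convention is homeostatic: ψ* is the median
day-0 stimulus of the bone elements (`setpoint: auto`), so the model starts
in equilibrium on average and adaptation redistributes density from
stress-shielded regions to overloaded ones — cortical shell and talar
articulation densify while the core resorbs, the pattern expected of a
calcaneus under rearfoot-dominated load. A numeric setpoint can be given
instead. Initial density is uniform (1.24 g/cm³) across cortical and
trabecular bone. The FE problem is re-solved every day by default;
`resolve_every: k` reuses the stress field for k days at a time (the bundled
analyses use k ≤ 2, which changes terminal densities by less than the
convergence tolerance on the bundled meshes). Convergence is declared when
the largest daily density change falls below 1e-4 g/cm³.

Analytic anchors: for a statically determinate bar the continuum stress is
modulus-independent, so the fixed point solving `n^(1/m) σ (ρ_max/ρ*)² = ψ*`
is exact; without a lazy zone the simulation lands on it to well under 1%.
With a lazy zone the trajectory stops at the zone edge `ρ*/√(1±w)` (about
5% from ρ* at w = 0.1) — the 1%-accuracy check therefore runs with w = 0,
and the zone-edge behaviour is asserted separately, with a stopping slack of
`tol/c_r` in stimulus units from the convergence criterion. Anisotropic
fabric-tensor remodelling, damage accumulation and Hounsfield-to-density
calibration are out of scope.

## Problem sizes and determinism

The bundled analyses run at desk scale: archetype FE models of roughly
5–8 × 10³ tetrahedra (target edge 8–9 mm), bone surfaces of 642 vertices per
bone, 60-day remodelling with FE re-solves every 1–2 days, and 500-draw
permutation nulls. These sizes resolve every qualitative pattern the
package asserts while keeping the full test suite and the acceptance script
in the minutes range on one CPU; finer lattices sharpen the stress fields
but do not change the orderings. All stages are deterministic given the
configuration seed; reruns reproduce summaries bitwise.

## Known limitations

- Synthetic geometry is not anatomy; morphological findings transfer to
  real bones only in their qualitative orderings.
- CST elements are stiff in bending; peak stresses at point-load
  application sites (Achilles nodes, fixed surface) are mesh-dependent
  concentrations and should be read comparatively, not absolutely.
- The remodelling law is a standard stand-in (see above), and the
  homeostatic-setpoint convention makes predicted density *changes*
  meaningful relative to the initial state rather than absolutely.
- The permutation test's exhaustive branch is marginally anti-conservative
  at very small group sizes (documented minimum p of 0.05 with 3+3 trials).
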