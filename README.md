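# footform

Form-and-function analysis of the human foot under altered loading, built
around the contrast between a typically developed foot (NF) and the two
historical Chinese bound-foot conditions: the half-bound (HB) and full-bound
(FB) foot. The package is aimed at musculoskeletal biomechanists who want a
fully scripted, testable version of the classic pipeline

1. **gait loading** — regional plantar-pressure statistics, vertical ground
   reaction force (GRF), and normalised center-of-pressure (CoP)
   trajectories from stance-phase pressure-insole recordings;
2. **bone shape** — rigid ICP registration, closest-point correspondence,
   centroid alignment and principal-component statistical shape models
   (SSM), with signed error maps and Hausdorff summaries;
3. **finite elements** — quasi-static linear elasticity on 4-node
   tetrahedra (bone E = 7300 MPa, ν = 0.3; lumped soft tissue E = 0.15 MPa,
   ν = 0.45), mean stance plantar pressure as the boundary condition, five
   200 N/mm plantar-fascia spring connectors, an Achilles pull of 0.5 body
   weight, and the tibia/fibula top surface fixed;
4. **bone remodelling** — a strain-adaptive density law with a lazy zone,
   iterated daily over FE solves for 60 simulated days.

Because the underlying subject data are not redistributable, the package
ships a **parametric synthetic foot generator**: superellipsoid-based bone
assemblies, lattice tetrahedral meshes with guaranteed element quality, and
stance pressure series for all three archetypes, with the measured foot
lengths/widths and body masses of the three study conditions as defaults
(NF 214.06 × 84.17 mm, HB 202.81 × 67.14 mm, FB 165.86 × 65.25 mm). Every
stage is exercised end-to-end with known ground truth, offline.

## The core quantities

* Vertical GRF per frame: `F = Σ_cells p·a` (kPa·mm² → N), with a two-peak
  stance template peaking at ≈ 1.1 BW.
* CoP: pressure-weighted centroid of cell centers, reported as a percentage
  of subject foot width (medial–lateral, x) and length
  (anterior–posterior, y), resampled to 101 points of % stance.
* Curve comparison: non-parametric cluster-based permutation test on
  point-wise two-sample t statistics (supra-threshold clusters scored by
  mass; label permutations, exhaustive when ≤ 500 exist).
* von Mises stress per element:
  `σ_vm = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)²] + 3(σ₁₂²+σ₂₃²+σ₃₁²))`.
* Remodelling: daily stimulus `ψ = n^(1/m)·σ_vm·(ρ_max/ρ)²`; density rate
  `dρ/dt = c_r(ψ − ψ*(1±w))` outside the lazy zone `[ψ*(1−w), ψ*(1+w)]`,
  zero inside; modulus coupling `E = B·ρ^β` (defaults B = 3790 MPa, β = 3,
  m = 4, n = 10 000 cycles/day, w = 0.1).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from footform import synthetic, gait
from footform.types import ARCHETYPES

params = ARCHETYPES["FB"]                       # full-bound foot defaults
series = synthetic.generate_pressure_series(params)
regions = gait.RegionMap.for_archetype("FB", series.grid_shape,
                                       params.foot_length, params.foot_width)
print(gait.regional_stats(series, regions).round(1))
grf = gait.compute_grf(series)
print(f"GRF peak: {grf.max():.1f} N ({grf.max()/params.body_weight:.2f} BW)")
traj = gait.normalize_cop(series, params.foot_length, params.foot_width)
print(f"CoP range: ML {traj.x_pct.max()-traj.x_pct.min():.1f}% of width, "
      f"AP {traj.y_pct.max()-traj.y_pct.min():.1f}% of length")
```

prints

```
                  peak_kpa  mean_kpa
region
medial_forefoot      218.4      20.5
lateral_forefoot     327.6      30.7
medial_rearfoot      341.0      46.5
lateral_rearfoot     361.0      49.2
GRF peak: 509.5 N (1.09 BW)
CoP range: ML 2.9% of width, AP 40.5% of length
```

The FB scheme has no toe or midfoot regions (those areas never contact the
ground), the rearfoot carries most of the load, the GRF peak is the 1.1 BW
walking template, and the medial–lateral CoP excursion is only a few percent
of foot width — the rigid, rearfoot-dominated rollover that characterises
the full-bound foot. The CoP excursion of the normal foot is several times
larger.

## Command line

```bash
footform simulate-data --archetype FB --seed 0 --out fb_run   # STL + .inp + CSV
footform gait --pressure fb_run/pressure_trial0.csv --regions FB \
        --foot-length 165.86 --foot-width 65.25
footform shape --reference nf/calcaneus.stl --targets fb_run/calcaneus.stl
footform fe --archetype NF --out nf_fe                        # mean-stance FE
footform remodel --archetype NF --out nf_remodel --days 60
footform pipeline --archetype FB --seed 0 --out fb_full       # all stages
```

Exit codes: 0 success, 2 configuration error, 1 runtime error. The pipeline
writes a machine-readable `summary.json` (regional stats, CoP ranges,
Hausdorff summaries, peak von Mises per bone, terminal density per
calcaneal region), plus VTK/PLY/CSV artifacts for external viewers.

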