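"""Parametric synthetic foot archetypes with known ground truth.

Generates the three study conditions — normal (NF), half-bound (HB) and
full-bound (FB) feet — as superellipsoid-based bone assemblies, lattice
tetrahedral meshes with the node/element sets the FE stage needs, stance-phase
plantar-pressure series, and CT-like density phantoms. The geometric fidelity
target is topological/metric (bone counts, overall dimensions, arch height,
calcaneal inclination), which is sufficient to exercise every downstream
stage; the bones are not anatomically faithful reconstructions.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .types import (
    ArchetypeParams,
    DensityField,
    ParameterError,
    PressureSeries,
    SurfaceMesh,
    TetMesh,
    TopologyError,
)

#: Labels of the nine bones each archetype carries.
BONE_LABELS = (
    "calcaneus",
    "talus",
    "tibia",
    "fibula",
    "met1",
    "met2",
    "met3",
    "met4",
    "met5",
)

GRAVITY = 9.81  # m/s^2

ShapeSet = dict[str, SurfaceMesh]


# ---------------------------------------------------------------------------
# Superellipsoid primitive
# ---------------------------------------------------------------------------

@dataclass
class Superellipsoid:
    """Axis-aligned superellipsoid |u|^e <= 1 in a rotated local frame.

    ``exponent`` = 2 gives an ellipsoid; larger values approach a box.
    The global anisotropic scale applied when the foot is sized to its exact
    length/width is stored so the implicit inside test matches the meshes.
    """

    center: np.ndarray         # (3,) mm, pre-scale
    radii: np.ndarray          # (3,) mm half-axes
    exponent: float
    rotation: np.ndarray       # (3, 3) local -> world
    scale: np.ndarray | None = None   # (3,) global scale factors
    scale_origin: np.ndarray | None = None

    def _to_local(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        if self.scale is not None:
            p = self.scale_origin + (p - self.scale_origin) / self.scale
        return (p - self.center) @ self.rotation / self.radii

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Implicit value; <= 1 inside."""
        u = np.abs(self._to_local(points))
        return np.sum(u ** self.exponent, axis=1)

    def inside(self, points: np.ndarray) -> np.ndarray:
        return self.implicit(points) <= 1.0

    def mesh(self, subdivisions: int = 3, label: str = "") -> SurfaceMesh:
        """Watertight triangulation by radially mapping an icosphere."""
        ico = trimesh.creation.icosphere(subdivisions=subdivisions)
        v = np.asarray(ico.vertices, float)
        # radial map of the unit sphere onto |u|^e = 1 (exact, star-shaped)
        norm = np.sum(np.abs(v) ** self.exponent, axis=1) ** (1.0 / self.exponent)
        u = v / norm[:, None]
        world = self.center + (u * self.radii) @ self.rotation.T
        if self.scale is not None:
            world = self.scale_origin + (world - self.scale_origin) * self.scale
        return SurfaceMesh(world, np.asarray(ico.faces), label=label)


def _rot_x(deg: float) -> np.ndarray:
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# Bone layout
# ---------------------------------------------------------------------------

def _foot_primitives(params: ArchetypeParams) -> dict[str, Superellipsoid]:
    """Unscaled bone primitives for one archetype.

    Proportions are fractions of foot length L and width W so all three
    archetypes stay self-similar apart from arch height and calcaneal
    inclination. A small seeded jitter de-symmetrises the shapes.
    """
    L, W = params.foot_length, params.foot_width
    arch = params.arch_height_ratio
    rng = np.random.default_rng(params.seed)
    h_arch = 0.18 * L  # arch apex height scale

    prims: dict[str, Superellipsoid] = {}

    def add(label, center, radii, exponent, rot=None):
        jr = 1.0 + 0.02 * rng.standard_normal(3)
        je = float(np.clip(exponent * (1.0 + 0.05 * rng.standard_normal()), 2.0, 4.0))
        prims[label] = Superellipsoid(
            center=np.asarray(center, float),
            radii=np.asarray(radii, float) * jr,
            exponent=je,
            rotation=np.eye(3) if rot is None else rot,
        )

    # hindfoot: calcaneus tilts up anteriorly by the inclination angle
    add(
        "calcaneus",
        (0.0, 0.14 * L, 0.0),  # z fixed below so its base sits on the ground
        (0.15 * W, 0.12 * L, 0.07 * L),
        2.5,
        rot=_rot_x(params.calcaneal_inclination),
    )
    add("talus", (0.0, 0.30 * L, 0.26 * L), (0.12 * W, 0.08 * L, 0.05 * L), 2.5)
    # shank: tibia medial, fibula lateral, both vertical columns
    add("tibia", (0.06 * W, 0.30 * L, 0.38 * L), (0.09 * W, 0.07 * L, 0.15 * L), 3.0)
    add("fibula", (-0.20 * W, 0.29 * L, 0.38 * L), (0.045 * W, 0.05 * L, 0.13 * L), 3.0)
    # metatarsals fan out anteriorly; their centroids sit at the arch height
    for i in range(5):
        x = W * (0.28 - 0.14 * i)
        rx = 0.06 * W if i == 0 else 0.05 * W
        add(
            f"met{i + 1}",
            (x, 0.62 * L, arch * h_arch),
            (rx, 0.10 * L, 0.03 * L),
            2.2,
        )

    # drop the calcaneus so its lowest surface point is at z = 0
    cal = prims["calcaneus"]
    zmin = cal.mesh(subdivisions=3).vertices[:, 2].min()
    cal.center = cal.center - np.array([0.0, 0.0, zmin])
    return prims


def generate_foot_bones(
    params: ArchetypeParams, subdivisions: int = 3
) -> ShapeSet:
    """Generate the labelled bone surfaces of one archetype.

    The assembly is anisotropically scaled in x and y so the overall bounding
    box matches ``foot_width`` and ``foot_length`` exactly. Deterministic
    given ``params.seed``; all surfaces are watertight with outward normals.
    """
    prims = _foot_primitives(params)
    meshes = {lbl: p.mesh(subdivisions, label=lbl) for lbl, p in prims.items()}

    allv = np.vstack([m.vertices for m in meshes.values()])
    lo, hi = allv.min(axis=0), allv.max(axis=0)
    scale = np.array(
        [
            params.foot_width / (hi[0] - lo[0]),
            params.foot_length / (hi[1] - lo[1]),
            1.0,
        ]
    )
    origin = np.array([0.5 * (lo[0] + hi[0]), lo[1], 0.0])  # keep z untouched
    for lbl, m in meshes.items():
        m.vertices = origin + (m.vertices - origin) * scale
        m.metadata["archetype"] = params.name
        m.metadata["seed"] = params.seed
        prims[lbl].scale = scale
        prims[lbl].scale_origin = origin
        m.metadata["primitive"] = prims[lbl]
        m.validate()
    return meshes


# ---------------------------------------------------------------------------
# Lattice tetrahedral meshing (Freudenthal/Kuhn subdivision)
# ---------------------------------------------------------------------------

# 6 tets per cube around the (0,0,0)-(1,1,1) diagonal; conforming across
# neighbouring cubes because every cube uses the same diagonal.
_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))


def _kuhn_offsets() -> np.ndarray:
    """(6, 4, 3) corner offsets of the six cube tets, positively oriented."""
    tets = []
    for perm in _PERMS:
        v = [np.zeros(3, int)]
        acc = np.zeros(3, int)
        for axis in perm[:2]:
            acc = acc.copy()
            acc[axis] = 1
            v.append(acc)
        v.append(np.ones(3, int))
        v = np.array(v)
        e = v[1:] - v[0]
        if np.linalg.det(e.astype(float)) < 0:
            v[[2, 3]] = v[[3, 2]]
        tets.append(v)
    return np.array(tets)


_KUHN = _kuhn_offsets()


def lattice_tet_mesh(
    lo: np.ndarray,
    hi: np.ndarray,
    n_cells: tuple[int, int, int],
    inside_fn,
) -> TetMesh:
    """Structured tet mesh of the region where ``inside_fn`` holds.

    The box [lo, hi] is divided into ``n_cells`` cubes per axis. Each cube's
    inside fraction is estimated on a 3x3x3 subsample of ``inside_fn``; the
    fullest cubes are kept until the summed-fraction volume target is met (a
    volume-matched staircase), and each kept cube is split into six
    conforming tetrahedra. Node coordinates are exact lattice points, so
    element quality is guaranteed by construction for near-isotropic spacing.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    n = np.asarray(n_cells, int)
    if np.any(n < 1):
        raise ParameterError("need at least one cell per axis")
    spacing = (hi - lo) / n

    ii, jj, kk = np.meshgrid(
        np.arange(n[0]), np.arange(n[1]), np.arange(n[2]), indexing="ij"
    )
    cells = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    sub = 3
    q = (np.arange(sub) + 0.5) / sub
    frac = np.zeros(len(cells))
    for ox in q:
        for oy in q:
            for oz in q:
                pts = lo + (cells + [ox, oy, oz]) * spacing
                frac += np.asarray(inside_fn(pts), float)
    frac /= sub**3
    n_keep = int(round(frac.sum()))
    order = np.argsort(-frac, kind="stable")
    keep_idx = order[:n_keep]
    keep = np.zeros(len(cells), bool)
    keep[keep_idx[frac[keep_idx] > 0]] = True
    cells = cells[keep]
    if len(cells) == 0:
        raise TopologyError("no lattice cell center lies inside the solid")

    dims = n + 1

    def node_id(ijk):
        return np.ravel_multi_index((ijk[..., 0], ijk[..., 1], ijk[..., 2]), dims)

    # (n_cells, 6, 4) global lattice node ids
    corner = cells[:, None, None, :] + _KUHN[None, :, :, :]
    gids = node_id(corner).reshape(-1, 4)

    used, inv = np.unique(gids, return_inverse=True)
    tets = inv.reshape(-1, 4)
    ijk = np.column_stack(np.unravel_index(used, dims))
    nodes = lo + ijk * spacing

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        element_sets={"all": np.arange(len(tets))},
        metadata={"spacing": spacing, "lattice_lo": lo, "lattice_n": n},
    )
    if np.any(mesh.volumes() <= 0):  # pragma: no cover - construction guard
        raise TopologyError("lattice produced inverted tetrahedra")
    return mesh


def generate_tet_mesh(surface: SurfaceMesh, target_edge: float) -> TetMesh:
    """Tetrahedralise the interior of a watertight surface on a lattice.

    The boundary approximates the surface to within the lattice spacing and
    every element passes the scaled-Jacobian > 0.3 quality gate (Freudenthal
    cubes at near-unit aspect ratio).
    """
    if target_edge <= 0 or not np.isfinite(target_edge):
        raise ParameterError("target_edge must be positive")
    if not surface.is_watertight():
        raise TopologyError("surface must be watertight for tetrahedralisation")
    from .geometry import contains

    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    n = np.maximum(1, np.round((hi - lo) / target_edge).astype(int))
    return lattice_tet_mesh(lo, hi, tuple(n), lambda pts: contains(surface, pts))


# ---------------------------------------------------------------------------
# Full foot FE model
# ---------------------------------------------------------------------------

def _envelope_inside(params: ArchetypeParams):
    """Implicit soft-tissue envelope: flat-bottomed dome over a superellipse
    footprint, plus a shank column enclosing tibia/fibula up to the fixation
    plane."""
    L, W = params.foot_length, params.foot_width
    p = 2.5
    z_top = 0.55 * L
    r_leg = 0.30 * W

    def inside(pts):
        pts = np.atleast_2d(pts)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        s2 = np.abs(2 * x / W) ** p + np.abs(2 * (y - 0.5 * L) / L) ** p
        height = (0.55 - 0.25 * y / L) * W
        dome = np.clip(1.0 - s2, 0.0, None) ** (1.0 / p)
        h = height * (0.35 + 0.65 * dome)
        env = (s2 <= 1.0) & (z >= 0.0) & (z <= h)
        leg = (
            ((x / r_leg) ** 2 + ((y - 0.30 * L) / r_leg) ** 2 <= 1.0)
            & (z >= 0.0)
            & (z <= z_top)
        )
        return env | leg

    return inside, z_top


def generate_foot_model(
    params: ArchetypeParams,
    target_edge: float = 8.0,
    subdivisions: int = 3,
) -> TetMesh:
    """Complete archetype FE model: lattice tet mesh with bone/soft element
    sets and the node sets the FE stage needs (fixed shank top, plantar
    surface, Achilles insertion, fascia anchor pairs).

    Target edge lengths are recorded in the mesh metadata as provenance.
    """
    bones = generate_foot_bones(params, subdivisions=subdivisions)
    prims = {lbl: m.metadata["primitive"] for lbl, m in bones.items()}
    inside_env, z_top = _envelope_inside(params)

    L, W = params.foot_length, params.foot_width
    lo = np.array([-0.55 * W, 0.0, 0.0])
    hi = np.array([0.55 * W, L, z_top])

    def inside(pts):
        mask = inside_env(pts)
        for p in prims.values():
            mask |= p.inside(pts)
        return mask

    n = np.maximum(2, np.round((hi - lo) / target_edge).astype(int))
    mesh = lattice_tet_mesh(lo, hi, tuple(n), inside)
    spacing = mesh.metadata["spacing"]

    # element classification by centroid, first matching bone wins
    cent = mesh.element_centroids()
    owner = np.full(len(cent), -1)
    for b, lbl in enumerate(BONE_LABELS):
        free = owner < 0
        hit = free & prims[lbl].inside(cent)
        owner[hit] = b
    for b, lbl in enumerate(BONE_LABELS):
        ids = np.flatnonzero(owner == b)
        if ids.size == 0:
            # guarantee at least one element per bone on coarse lattices
            target = prims[lbl].center
            if prims[lbl].scale is not None:
                target = prims[lbl].scale_origin + (
                    target - prims[lbl].scale_origin
                ) * prims[lbl].scale
            free = np.flatnonzero(owner < 0)
            ids = free[[np.argmin(np.linalg.norm(cent[free] - target, axis=1))]]
            owner[ids] = b
        mesh.element_sets[lbl] = ids
    mesh.element_sets["bone"] = np.flatnonzero(owner >= 0)
    mesh.element_sets["soft"] = np.flatnonzero(owner < 0)

    # node sets ------------------------------------------------------------
    z = mesh.nodes[:, 2]
    bfaces, _ = mesh.boundary_faces_with_elements()
    bnodes = np.unique(bfaces)
    mesh.node_sets["fixed_proximal"] = np.flatnonzero(z > z.max() - 0.5 * spacing[2])
    mesh.node_sets["plantar"] = bnodes[z[bnodes] < 0.5 * spacing[2]]

    cal = prims["calcaneus"]
    cal_c = cal.scale_origin + (cal.center - cal.scale_origin) * cal.scale
    cal_ry = cal.radii[1] * cal.scale[1]
    # Achilles insertion: boundary nodes nearest the posterior-superior
    # aspect of the calcaneus
    anchor = cal_c + np.array([0.0, -cal_ry, 0.6 * cal.radii[2]])
    d = np.linalg.norm(mesh.nodes[bnodes] - anchor, axis=1)
    mesh.node_sets["achilles"] = bnodes[np.argsort(d)[:6]]

    # plantar fascia anchors: calcaneus notch (anterior-inferior) and the
    # base of each metatarsal
    notch = np.array([cal_c[0], cal_c[1] + cal_ry, 0.3 * cal.radii[2]])
    cal_node = int(np.argmin(np.linalg.norm(mesh.nodes - notch, axis=1)))
    met_nodes = []
    for i in range(5):
        m = prims[f"met{i + 1}"]
        c = m.scale_origin + (m.center - m.scale_origin) * m.scale
        base = c - np.array([0.0, m.radii[1] * m.scale[1], 0.0])
        met_nodes.append(int(np.argmin(np.linalg.norm(mesh.nodes - base, axis=1))))
    mesh.node_sets["fascia_cal"] = np.array([cal_node])
    mesh.node_sets["fascia_met"] = np.array(met_nodes)
    mesh.metadata["fascia_pairs"] = [(cal_node, m) for m in met_nodes]
    mesh.metadata["target_edge"] = {"bone": target_edge, "soft": target_edge}
    mesh.metadata["archetype"] = params.name
    mesh.metadata["foot_length"] = L
    mesh.metadata["foot_width"] = W

    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Plantar pressure series
# ---------------------------------------------------------------------------

#: Stance-phase activation window (center, width; fractions of stance) of each
#: anterior-posterior band: heel strikes first, load rolls forward, toes last.
_BAND_WINDOWS = {
    "rearfoot": (0.22, 0.20),
    "midfoot": (0.45, 0.20),
    "forefoot": (0.70, 0.16),
    "toes": (0.84, 0.12),
}

SAMPLING_HZ = 50.0
PEAK_BW_FACTOR = 1.1  # typical walking vertical GRF peak, in body weights


def _band_of(region: str) -> str:
    if region in ("hallux", "other_toes"):
        return "toes"
    for band in _BAND_WINDOWS:
        if region.endswith(band):
            return band
    raise KeyError(region)


def grf_template(t: np.ndarray, body_weight: float) -> np.ndarray:
    """Two-peaked vertical GRF template over normalised stance time t in [0,1].

    Weight-acceptance and push-off peaks of ``PEAK_BW_FACTOR`` body weights at
    25% and 75% of stance.
    """
    g1 = np.exp(-(((t - 0.25) / 0.13) ** 2))
    g2 = np.exp(-(((t - 0.75) / 0.13) ** 2))
    return PEAK_BW_FACTOR * body_weight * (g1 + g2)


def generate_pressure_series(
    params: ArchetypeParams,
    n_frames: int = 51,
    grid_shape: tuple[int, int] = (16, 6),
    noise_rel: float = 0.0,
    trial_seed: int | None = None,
) -> PressureSeries:
    """Synthesize one stance of plantar pressure at 50 Hz.

    The sensor grid tiles the foot bounding box exactly (rows along the foot
    length, columns across the width). The instantaneous force integral
    follows the two-peak stance template; regional time integrals are
    proportional to ``params.regional_load_shares``. Regions absent from the
    archetype's scheme (toes/midfoot in HB/FB) carry identically zero
    pressure. ``noise_rel`` adds a seeded multiplicative perturbation of the
    regional weighting for multi-trial studies; the total force template is
    unaffected.
    """
    from .gait import RegionMap  # local import to avoid a cycle

    if n_frames < 10:
        raise ParameterError("need at least 10 stance frames")
    rows, cols = grid_shape
    if rows < 4 or cols < 4:
        raise ParameterError("sensor grid must be at least 4x4")

    L, W = params.foot_length, params.foot_width
    dy, dx = L / rows, W / cols
    regions = RegionMap.for_archetype(params.name, grid_shape, L, W)
    rng = np.random.default_rng(
        params.seed if trial_seed is None else (params.seed, trial_seed)
    )

    shares = dict(params.regional_load_shares)
    if noise_rel > 0:
        for r in shares:
            shares[r] *= max(0.0, 1.0 + noise_rel * rng.standard_normal())
        tot = sum(shares.values())
        shares = {r: v / tot for r, v in shares.items()}

    t = np.arange(n_frames) / (n_frames - 1)
    times = np.arange(n_frames) / SAMPLING_HZ
    total_force = grf_template(t, params.body_weight)  # N

    # temporal activation windows per region (small floor keeps the
    # normalising denominator positive at every frame)
    windows = {}
    for r in shares:
        c, wdt = _BAND_WINDOWS[_band_of(r)]
        if noise_rel > 0:
            c += 0.3 * noise_rel * rng.standard_normal()
        windows[r] = np.exp(-(((t - c) / wdt) ** 2)) + 0.05

    # fixed-point correction so regional time integrals of force match the
    # requested shares despite the shared two-peak total
    names = list(shares)
    s = np.array([shares[r] for r in names])
    wmat = np.vstack([windows[r] for r in names])
    target = s.copy()
    for _ in range(200):
        alpha = (s[:, None] * wmat) / np.sum(s[:, None] * wmat, axis=0, keepdims=True)
        integ = np.sum(alpha * total_force[None, :], axis=1)
        integ /= integ.sum()
        if np.max(np.abs(integ - target)) < 1e-6:
            break
        s *= np.where(integ > 0, target / np.maximum(integ, 1e-12), 1.0)
        s /= s.sum()
    region_force = alpha * total_force[None, :]  # (R, F) newtons

    # spatial kernels: Gaussian about each region's cell-centroid
    yc, xc = np.meshgrid(
        dy * (np.arange(rows) + 0.5), dx * (np.arange(cols) + 0.5) - W / 2,
        indexing="ij",
    )
    pressures = np.zeros((n_frames, rows, cols))
    area = dy * dx  # mm^2
    for ri, r in enumerate(names):
        mask = regions.labels == r
        if not mask.any():
            continue
        cy, cx = yc[mask].mean(), xc[mask].mean()
        sy = max(yc[mask].std(), 0.5 * dy)
        sx = max(xc[mask].std(), 0.5 * dx)
        k = np.exp(-0.5 * (((yc - cy) / sy) ** 2 + ((xc - cx) / sx) ** 2))
        k = np.where(mask, k, 0.0)
        k /= k.sum()
        # p [kPa] = F [N] * weight / area [mm^2] * 1e3
        pressures += region_force[ri][:, None, None] * k[None] / area * 1e3

    return PressureSeries(
        times=times,
        pressures=pressures,
        cell_size=(dy, dx),
        origin=(0.0, -W / 2),
        metadata={
            "archetype": params.name,
            "foot_length": L,
            "foot_width": W,
            "body_mass": params.body_mass,
            "seed": params.seed,
            "trial_seed": trial_seed,
        },
    )


# ---------------------------------------------------------------------------
# Fixture helpers
# ---------------------------------------------------------------------------

def perturb_shape(
    mesh: SurfaceMesh,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SurfaceMesh:
    """Rigidly transform (about the centroid) and optionally noise a copy.

    The ground-truth transform ``v' = R v + t`` is stored in
    ``metadata['true_rotation']`` / ``metadata['true_translation']`` for
    recovery tests.
    """
    R = Rotation.from_euler("xyz", rotation, degrees=True).as_matrix()
    t = np.asarray(translation, float)
    c = mesh.centroid()
    t_eff = c - R @ c + t
    v = mesh.vertices @ R.T + t_eff
    if noise_sd > 0:
        v = v + noise_sd * np.random.default_rng(seed).standard_normal(v.shape)
    out = SurfaceMesh(v, mesh.triangles.copy(), mesh.label, dict(mesh.metadata))
    out.metadata["true_rotation"] = R
    out.metadata["true_translation"] = t_eff
    return out


def make_density_phantom(
    mesh: TetMesh,
    pattern: str,
    *,
    value: float = 1.0,
    rho_min: float = 0.05,
    rho_max: float = 1.8,
    rho_trab: float = 0.6,
    axis: int = 2,
) -> DensityField:
    """CT-like reference density field on a tet mesh.

    Patterns: ``uniform`` (all ``value``), ``cortical_shell`` (``rho_max`` for
    elements owning a boundary face — the dense cortex — and ``rho_trab`` in
    the lumped trabecular interior), ``gradient`` (linear ``rho_min`` →
    ``rho_max`` along ``axis``).
    """
    if pattern == "uniform":
        return DensityField(np.full(mesh.n_elements, float(value)))
    if pattern == "cortical_shell":
        _, owners = mesh.boundary_faces_with_elements()
        rho = np.full(mesh.n_elements, rho_trab)
        rho[np.unique(owners)] = rho_max
        return DensityField(rho)
    if pattern == "gradient":
        c = mesh.element_centroids()[:, axis]
        span = c.max() - c.min()
        frac = (c - c.min()) / span if span > 0 else np.zeros_like(c)
        return DensityField(rho_min + frac * (rho_max - rho_min))
    raise ParameterError(f"unknown density pattern {pattern!r}")
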