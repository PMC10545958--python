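"""Core data containers shared by all pipeline stages.

Conventions: the foot sits in a right-handed frame with ``y`` running from the
heel (y=0) towards the toes (anterior +), ``x`` medial–lateral (medial +, left
foot) and ``z`` vertical (up +). Coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import trimesh


class ParameterError(ValueError):
    """Raised for invalid user-supplied parameters."""


class TopologyError(ValueError):
    """Raised when a mesh violates a topological precondition."""


# ---------------------------------------------------------------------------
# Plantar region schemes
# ---------------------------------------------------------------------------

#: Region labels per foot type. The normal foot uses the full 8-region mask;
#: the bound feet lose the regions that no longer contact the ground (toes and
#: midfoot collapse under the binding, the full-bound foot also loses hallux
#: contact).
REGION_SCHEMES: dict[str, tuple[str, ...]] = {
    "NF": (
        "hallux",
        "other_toes",
        "medial_forefoot",
        "lateral_forefoot",
        "medial_midfoot",
        "lateral_midfoot",
        "medial_rearfoot",
        "lateral_rearfoot",
    ),
    "HB": (
        "hallux",
        "medial_forefoot",
        "lateral_forefoot",
        "medial_rearfoot",
        "lateral_rearfoot",
    ),
    "FB": (
        "medial_forefoot",
        "lateral_forefoot",
        "medial_rearfoot",
        "lateral_rearfoot",
    ),
}

#: Anterior–posterior band occupied by each region group, as fractions of foot
#: length measured from the heel.
REGION_BANDS: dict[str, tuple[float, float]] = {
    "rearfoot": (0.00, 0.30),
    "midfoot": (0.30, 0.60),
    "forefoot": (0.60, 0.85),
    "toes": (0.85, 1.00),
}


def region_band(region: str) -> tuple[float, float]:
    """Anterior-posterior band (fractions of foot length) of a region label."""
    if region in ("hallux", "other_toes"):
        return REGION_BANDS["toes"]
    for group, band in REGION_BANDS.items():
        if region.endswith(group):
            return band
    raise KeyError(region)


# ---------------------------------------------------------------------------
# Archetype parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of a synthetic foot archetype.

    Defaults for the three archetypes (NF/HB/FB) carry the measured foot
    lengths, widths and body masses of the three study participants; see
    :data:`ARCHETYPES`.
    """

    name: str
    foot_length: float          # mm
    foot_width: float           # mm
    arch_height_ratio: float    # 0 = flat arch, 1 = extreme dome
    calcaneal_inclination: float  # degrees from horizontal
    body_mass: float            # kg
    regional_load_shares: Mapping[str, float]  # fraction per region, sums to 1
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.foot_length, self.foot_width, self.body_mass)
        if not all(np.isfinite(dims)):
            raise ParameterError("foot dimensions and mass must be finite")
        if not self.foot_length > self.foot_width > 0:
            raise ParameterError(
                f"need foot_length > foot_width > 0, got "
                f"{self.foot_length} / {self.foot_width}"
            )
        if not 0.0 <= self.arch_height_ratio <= 1.0:
            raise ParameterError("arch_height_ratio must lie in [0, 1]")
        shares = np.asarray(list(self.regional_load_shares.values()), float)
        if shares.size == 0 or np.any(shares < 0) or not np.all(np.isfinite(shares)):
            raise ParameterError("regional_load_shares must be nonnegative and finite")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"regional_load_shares must sum to 1, got {shares.sum():.12f}"
            )
        if self.name not in REGION_SCHEMES:
            raise ParameterError(f"unknown archetype scheme {self.name!r}")
        extra = set(self.regional_load_shares) - set(REGION_SCHEMES[self.name])
        if extra:
            raise ParameterError(f"shares name regions outside the {self.name} scheme: {extra}")

    @property
    def body_weight(self) -> float:
        """Body weight in newtons (g = 9.81 m/s^2)."""
        return self.body_mass * 9.81

    def replace(self, **kw) -> "ArchetypeParams":
        from dataclasses import replace

        return replace(self, **kw)


def _shares(d: dict[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


#: Default archetypes. Lengths/widths/masses are the three participants'
#: measurements; load shares encode the qualitative regional patterns (even
#: rollover in NF, rearfoot-focused loading that intensifies from HB to FB,
#: no toe or midfoot contact in the bound feet).
ARCHETYPES: dict[str, ArchetypeParams] = {
    "NF": ArchetypeParams(
        name="NF",
        foot_length=214.06,
        foot_width=84.17,
        arch_height_ratio=0.25,
        calcaneal_inclination=20.0,
        body_mass=52.2,
        regional_load_shares=_shares(
            {
                "hallux": 0.08,
                "other_toes": 0.05,
                "medial_forefoot": 0.12,
                "lateral_forefoot": 0.13,
                "medial_midfoot": 0.07,
                "lateral_midfoot": 0.08,
                "medial_rearfoot": 0.23,
                "lateral_rearfoot": 0.24,
            }
        ),
    ),
    "HB": ArchetypeParams(
        name="HB",
        foot_length=202.81,
        foot_width=67.14,
        arch_height_ratio=0.45,
        calcaneal_inclination=35.0,
        body_mass=49.1,
        regional_load_shares=_shares(
            {
                "hallux": 0.08,
                "medial_forefoot": 0.12,
                "lateral_forefoot": 0.15,
                "medial_rearfoot": 0.32,
                "lateral_rearfoot": 0.33,
            }
        ),
    ),
    "FB": ArchetypeParams(
        name="FB",
        foot_length=165.86,
        foot_width=65.25,
        arch_height_ratio=0.75,
        calcaneal_inclination=55.0,
        body_mass=47.5,
        regional_load_shares=_shares(
            {
                "medial_forefoot": 0.12,
                "lateral_forefoot": 0.18,
                "medial_rearfoot": 0.34,
                "lateral_rearfoot": 0.36,
            }
        ),
    ),
}


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A labelled triangulated surface (mm)."""

    vertices: np.ndarray          # (V, 3) float64
    triangles: np.ndarray         # (T, 3) int
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise TopologyError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise TopologyError("triangles must be (T, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise TopologyError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def centroid(self) -> np.ndarray:
        """Vertex-mean centroid (mm)."""
        return self.vertices.mean(axis=0)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def validate(self, min_area: float = 1e-9) -> None:
        """Check watertightness, degenerate triangles, outward orientation."""
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise TopologyError(f"{self.label or 'mesh'} is not watertight")
        if np.any(self.triangle_areas() <= min_area):
            raise TopologyError(f"{self.label or 'mesh'} has degenerate triangles")
        if tm.volume <= 0:
            raise TopologyError(f"{self.label or 'mesh'} has inward orientation")

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.triangles.copy(), self.label,
            dict(self.metadata),
        )


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with named element and node sets.

    Internal node/element ids are 0-based; on-disk Abaqus-style ids are
    1-based (handled by the .inp reader/writer).
    """

    nodes: np.ndarray                         # (N, 3) float64, mm
    tets: np.ndarray                          # (M, 4) int
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.element_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.element_sets.items()}
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (mm^3); positive for correctly ordered elements."""
        x = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            x[:, 1] - x[:, 0],
            np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]),
        ) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """(F, 3) node triples of faces used by exactly one tet, outward-ordered."""
        faces, _ = self.boundary_faces_with_elements()
        return faces

    def boundary_faces_with_elements(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary faces plus the owning element id of each face.

        Face vertex order is chosen so the right-hand-rule normal points out
        of the mesh (faces of a positively oriented tet, viewed from outside).
        """
        t = self.tets
        # the four faces of tet (a,b,c,d), outward for positive volume
        f = np.concatenate(
            [
                t[:, [0, 2, 1]],
                t[:, [0, 1, 3]],
                t[:, [1, 2, 3]],
                t[:, [0, 3, 2]],
            ]
        )
        owner = np.tile(np.arange(len(t)), 4)
        key = np.sort(f, axis=1)
        order = np.lexsort(key.T[::-1])
        key_sorted = key[order]
        # faces whose sorted vertex triple occurs exactly once are boundary
        diff_prev = np.ones(len(key_sorted), bool)
        diff_prev[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
        diff_next = np.ones(len(key_sorted), bool)
        diff_next[:-1] = diff_prev[1:]
        unique = diff_prev & diff_next
        sel = order[unique]
        return f[sel], owner[sel]

    def validate(self) -> None:
        vols = self.volumes()
        if np.any(vols <= 0):
            raise TopologyError(f"{np.sum(vols <= 0)} tets with non-positive volume")
        if self.tets.size and self.tets.max() >= self.n_nodes:
            raise TopologyError("tet index out of range")
        for name, ids in self.element_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_elements):
                raise TopologyError(f"element set {name!r} id out of range")
        for name, ids in self.node_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise TopologyError(f"node set {name!r} id out of range")
        for required in ("fixed_proximal", "plantar"):
            if required in self.node_sets and self.node_sets[required].size == 0:
                raise TopologyError(f"node set {required!r} is empty")


# ---------------------------------------------------------------------------
# Plantar pressure
# ---------------------------------------------------------------------------

@dataclass
class PressureSeries:
    """Stance-phase plantar pressure on a rectangular sensor grid.

    ``pressures[f, i, j]`` is the pressure (kPa) of cell row ``i`` (heel→toe,
    along y) and column ``j`` (lateral→medial, along x) at frame ``f``.
    """

    times: np.ndarray             # (F,) seconds
    pressures: np.ndarray         # (F, R, C) kPa
    cell_size: tuple[float, float]  # (dy, dx) mm
    origin: tuple[float, float] = (0.0, 0.0)  # (y0, x0) of grid lower corner
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.pressures = np.asarray(self.pressures, dtype=np.float64)
        if self.pressures.ndim != 3:
            raise ParameterError("pressures must be (frames, rows, cols)")
        if len(self.times) != self.pressures.shape[0]:
            raise ParameterError("times and pressures disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.pressures.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pressures.shape[1:]

    @property
    def cell_area(self) -> float:
        """Sensor cell area in mm^2."""
        return self.cell_size[0] * self.cell_size[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) center coordinates (mm) as arrays of shape (R,), (C,)."""
        rows, cols = self.grid_shape
        dy, dx = self.cell_size
        y = self.origin[0] + dy * (np.arange(rows) + 0.5)
        x = self.origin[1] + dx * (np.arange(cols) + 0.5)
        return y, x


@dataclass
class DensityField:
    """Per-element apparent density (g/cm^3)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def copy(self) -> "DensityField":
        return DensityField(self.values.copy())
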