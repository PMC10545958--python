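"""Quasi-static linear-elastic finite elements on 4-node tetrahedra.

Constant-strain tetrahedra (CST), isotropic linear elasticity, sparse direct
solves. Loads supported: regional plantar pressure applied as consistent
nodal forces on boundary faces, axial spring "connectors" (plantar fascia),
and distributed point loads (Achilles tendon). Displacements in mm, forces in
N, stresses and moduli in MPa (1 MPa = 1 N/mm^2, consistent with mm/N units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .types import ParameterError, TetMesh

log = logging.getLogger(__name__)


class MeshQualityError(ValueError):
    """Raised for inverted or unacceptably distorted elements."""


class SingularSystemError(ValueError):
    """Raised when the constrained stiffness is singular (rigid modes left)."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (MPa)."""

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ParameterError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ParameterError("Poisson's ratio must lie in (-1, 0.5)")


#: Bone and lumped soft tissue defaults (linear elastic).
BONE = Material(youngs_modulus=7300.0, poisson_ratio=0.3)
SOFT_TISSUE = Material(youngs_modulus=0.15, poisson_ratio=0.45)

#: Plantar fascia connector stiffness (N/mm) and Achilles load fraction of
#: body weight.
FASCIA_STIFFNESS = 200.0
ACHILLES_BW_FRACTION = 0.5


def material_arrays(
    mesh: TetMesh, materials: dict[str, Material]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (E, nu) arrays from an element-set -> material mapping."""
    E = np.full(mesh.n_elements, np.nan)
    nu = np.full(mesh.n_elements, np.nan)
    for name, mat in materials.items():
        ids = mesh.element_sets[name]
        E[ids] = mat.youngs_modulus
        nu[ids] = mat.poisson_ratio
    if np.any(np.isnan(E)):
        missing = int(np.isnan(E).sum())
        raise ParameterError(f"{missing} elements have no material assigned")
    return E, nu


# ---------------------------------------------------------------------------
# Mesh quality
# ---------------------------------------------------------------------------

_CORNERS = ((0, 1, 2, 3), (1, 0, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0))


def scaled_jacobian(mesh: TetMesh) -> np.ndarray:
    """Per-element scaled Jacobian: min over corners of det(e1,e2,e3) scaled
    by the corner edge lengths, normalised so a regular tetrahedron scores 1
    and degenerate/inverted elements score <= 0."""
    x = mesh.nodes[mesh.tets]
    worst = np.full(mesh.n_elements, np.inf)
    for c, a, b, d in _CORNERS:
        e1 = x[:, a] - x[:, c]
        e2 = x[:, b] - x[:, c]
        e3 = x[:, d] - x[:, c]
        det = np.einsum("ij,ij->i", e1, np.cross(e2, e3))
        norm = (
            np.linalg.norm(e1, axis=1)
            * np.linalg.norm(e2, axis=1)
            * np.linalg.norm(e3, axis=1)
        )
        worst = np.minimum(worst, det / np.maximum(norm, 1e-300))
    return worst * np.sqrt(2.0)


@dataclass
class QualityReport:
    """Element quality summary; the gate is scaled Jacobian > 0.3."""

    scaled_jacobian: np.ndarray
    flagged: np.ndarray      # elements with 0 < J <= 0.3
    inverted: np.ndarray     # elements with J <= 0 (hard failures)
    passed: bool


def check_mesh_quality(mesh: TetMesh, threshold: float = 0.3) -> QualityReport:
    """Scaled-Jacobian quality gate; inverted elements are listed separately."""
    sj = scaled_jacobian(mesh)
    inverted = np.flatnonzero(sj <= 0.0)
    flagged = np.flatnonzero((sj > 0.0) & (sj <= threshold))
    return QualityReport(
        scaled_jacobian=sj,
        flagged=flagged,
        inverted=inverted,
        passed=bool(len(flagged) == 0 and len(inverted) == 0),
    )


# ---------------------------------------------------------------------------
# Stiffness assembly
# ---------------------------------------------------------------------------

def _element_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (M, 4, 3) and element volumes (mm^3)."""
    x = mesh.nodes[mesh.tets]
    J = x[:, 1:] - x[:, 0:1]                       # (M, 3, 3) edge matrix
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise MeshQualityError(
            f"{np.sum(detJ <= 0)} inverted elements; fix node ordering first"
        )
    Jinv = np.linalg.inv(J)
    grads = np.empty((mesh.n_elements, 4, 3))
    # grad N_i (i=1..3) is the i-th column of J^-1; N_0 closes partition of unity
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, detJ / 6.0


def _elastic_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """(M, 6, 6) isotropic elasticity matrices in Voigt order
    (xx, yy, zz, xy, yz, zx) with engineering shear strains."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """(M, 6, 12) CST strain-displacement matrices."""
    M = grads.shape[0]
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def assemble_stiffness(
    mesh: TetMesh, E: np.ndarray | float, nu: np.ndarray | float
) -> sparse.csr_matrix:
    """Global stiffness (N/mm) from constant-strain tetrahedra.

    Symmetric positive semi-definite with exactly six rigid-body zero-energy
    modes before constraints. ``E``/``nu`` may be scalars or per-element
    arrays.
    """
    E = np.broadcast_to(np.asarray(E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, float), (mesh.n_elements,))
    grads, vol = _element_gradients(mesh)
    B = _b_matrices(grads)
    D = _elastic_matrix(E, nu)
    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol, optimize=True)

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return K.tocsr()


def element_stresses(
    mesh: TetMesh, u: np.ndarray, E: np.ndarray | float, nu: np.ndarray | float
) -> np.ndarray:
    """(M, 6) element stress tensors (Voigt: xx, yy, zz, xy, yz, zx) in MPa."""
    E = np.broadcast_to(np.asarray(E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, float), (mesh.n_elements,))
    grads, _ = _element_gradients(mesh)
    B = _b_matrices(grads)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", B, ue)
    D = _elastic_matrix(E, nu)
    return np.einsum("mij,mj->mi", D, strain)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress of Voigt tensors (xx,yy,zz,xy,yz,zx)."""
    s = np.atleast_2d(np.asarray(stress, float))
    sxx, syy, szz, sxy, syz, szx = s.T
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    return vm if stress.ndim > 1 else float(vm[0])


# ---------------------------------------------------------------------------
# Loads
# ---------------------------------------------------------------------------

def plantar_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Boundary faces all of whose nodes belong to the 'plantar' node set,
    with owning element ids."""
    faces, owners = mesh.boundary_faces_with_elements()
    plantar = set(mesh.node_sets["plantar"].tolist())
    sel = np.array([all(n in plantar for n in f) for f in faces], bool)
    return faces[sel], owners[sel]


def assign_plantar_faces(
    mesh: TetMesh, region_map, foot_length: float, foot_width: float
) -> dict[str, np.ndarray]:
    """Assign each plantar boundary face to the anatomical region its
    centroid falls into, keyed by region name. Faces outside every active
    region (toe/midfoot cells of bound feet) map to the key ''."""
    faces, _ = plantar_faces(mesh)
    cent = mesh.nodes[faces].mean(axis=1)
    rows, cols = region_map.labels.shape
    dy = foot_length / rows
    dx = foot_width / cols
    i = np.clip((cent[:, 1] // dy).astype(int), 0, rows - 1)
    j = np.clip(((cent[:, 0] + foot_width / 2) // dx).astype(int), 0, cols - 1)
    labels = region_map.labels[i, j]
    out: dict[str, np.ndarray] = {}
    for name in np.unique(labels):
        out[str(name)] = np.flatnonzero(labels == name)
    return out


def apply_plantar_pressure(
    mesh: TetMesh,
    face_regions: dict[str, np.ndarray],
    pressures: dict[str, float],
    faces: np.ndarray | None = None,
) -> np.ndarray:
    """Consistent nodal forces (N) from regional plantar pressures (kPa).

    Each boundary face contributes pressure x area / 3 to each of its nodes,
    directed along the inward face normal (pressure pushes into the body).
    Every face must be assigned a region; unassigned-region faces ('' key)
    are allowed and carry zero pressure.
    """
    if faces is None:
        faces, _ = plantar_faces(mesh)
    known = set(face_regions)
    covered = np.zeros(len(faces), bool)
    for ids in face_regions.values():
        covered[ids] = True
    if not covered.all():
        raise ParameterError(
            f"{np.sum(~covered)} plantar faces have no region assignment"
        )
    unknown = set(pressures) - known - {""}
    if unknown:
        raise ParameterError(f"pressures name unassigned regions: {unknown}")

    f = np.zeros(3 * mesh.n_nodes)
    v = mesh.nodes
    for region, ids in face_regions.items():
        p = float(pressures.get(region, 0.0))
        if p == 0.0 or len(ids) == 0:
            continue
        tri = faces[ids]
        # outward-ordered boundary faces: area vector then flipped inward
        cr = np.cross(v[tri[:, 1]] - v[tri[:, 0]], v[tri[:, 2]] - v[tri[:, 0]])
        inward = -0.5 * cr                       # area-weighted inward normal
        per_node = p * 1e-3 * inward / 3.0       # kPa*mm^2 -> N
        for k in range(3):
            np.add.at(f.reshape(-1, 3), tri[:, k], per_node)
    return f


def achilles_load(
    mesh: TetMesh,
    magnitude: float,
    direction: np.ndarray = (0.0, 0.0, 1.0),
    node_set: str = "achilles",
) -> np.ndarray:
    """Achilles tendon pull as equal point loads over the insertion node set.

    Default direction is the (vertical) tibia axis; ``magnitude`` in N.
    """
    nodes = mesh.node_sets[node_set]
    if len(nodes) == 0:
        raise ParameterError("empty Achilles node set")
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    f = np.zeros(3 * mesh.n_nodes)
    f.reshape(-1, 3)[nodes] += magnitude * d / len(nodes)
    return f


def add_connectors(
    K: sparse.spmatrix,
    mesh: TetMesh,
    pairs: list[tuple[int, int]],
    k: float,
) -> sparse.csr_matrix:
    """Add axial springs of stiffness ``k`` (N/mm) between node pairs.

    Each spring acts along the current pair direction (geometry at assembly
    time); symmetry of the operator is preserved. ``k = 0`` returns K
    unchanged.
    """
    if k == 0.0 or not pairs:
        return K.tocsr()
    rows, cols, vals = [], [], []
    for i, j in pairs:
        d = mesh.nodes[j] - mesh.nodes[i]
        length = np.linalg.norm(d)
        if length < 1e-12:
            raise ParameterError(f"coincident nodes in connector pair ({i}, {j})")
        n = d / length
        kb = k * np.outer(n, n)
        block = np.block([[kb, -kb], [-kb, kb]])
        dof = np.concatenate([3 * i + np.arange(3), 3 * j + np.arange(3)])
        rows.append(np.repeat(dof, 6))
        cols.append(np.tile(dof, 6))
        vals.append(block.ravel())
    Ks = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=K.shape,
    )
    return (K + Ks).tocsr()


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

@dataclass
class FESolution:
    """Result of one quasi-static load case."""

    displacements: np.ndarray     # (N, 3) mm
    stresses: np.ndarray          # (M, 6) MPa, Voigt
    von_mises: np.ndarray         # (M,) MPa
    reactions: np.ndarray         # (N, 3) N; nonzero only at fixed nodes
    residual: float               # ||K u - f|| / ||f|| on free dofs
    metadata: dict = field(default_factory=dict)


def solve(
    K: sparse.spmatrix,
    f: np.ndarray,
    fixed_nodes: np.ndarray | None,
    mesh: TetMesh,
    E: np.ndarray | float,
    nu: np.ndarray | float,
    fixed_dofs: np.ndarray | None = None,
    fixed_values: np.ndarray | None = None,
) -> FESolution:
    """Direct sparse solve with Dirichlet constraints.

    ``fixed_nodes`` pins all three dofs of each listed node; alternatively
    (or additionally) ``fixed_dofs`` pins individual dofs, with optional
    prescribed ``fixed_values`` (default zero). Reactions are recovered from
    the full operator. Raises :class:`SingularSystemError` when constraints
    leave rigid-body modes (singular or grossly inaccurate factorisation).
    """
    n_dof = K.shape[0]
    dofs = []
    if fixed_nodes is not None and len(np.atleast_1d(fixed_nodes)):
        fn = np.asarray(fixed_nodes, int)
        dofs.append((3 * fn[:, None] + np.arange(3)).ravel())
    vals_map = {}
    if fixed_dofs is not None and len(fixed_dofs):
        fd = np.asarray(fixed_dofs, int)
        dofs.append(fd)
        if fixed_values is not None:
            vals_map = dict(zip(fd.tolist(), np.asarray(fixed_values, float)))
    if not dofs:
        raise SingularSystemError(
            "no constraints: stiffness retains 6 rigid-body modes"
        )
    con = np.unique(np.concatenate(dofs))
    u_con = np.array([vals_map.get(int(d), 0.0) for d in con])
    free = np.setdiff1d(np.arange(n_dof), con)
    Kcsr = K.tocsr()
    Kff = Kcsr[free][:, free].tocsc()
    ff = f[free] - Kcsr[free][:, con] @ u_con
    try:
        lu = splu(Kff)
        uf = lu.solve(ff)
    except RuntimeError as exc:  # singular factorisation
        raise SingularSystemError(
            "constrained stiffness is singular; the fixed node set does not "
            "suppress all rigid-body modes"
        ) from exc
    denom = np.linalg.norm(ff)
    residual = float(np.linalg.norm(Kff @ uf - ff) / denom) if denom > 0 else 0.0
    if not np.all(np.isfinite(uf)) or (denom > 0 and residual > 1e-6):
        raise SingularSystemError(
            f"solve failed (residual {residual:.2e}); rigid-body modes "
            "(translations/rotations) are likely unconstrained"
        )
    u = np.zeros(n_dof)
    u[free] = uf
    u[con] = u_con
    fixed_dofs = con
    r = K @ u - f
    reactions = np.zeros(n_dof)
    reactions[fixed_dofs] = r[fixed_dofs]
    stresses = element_stresses(mesh, u, E, nu)
    return FESolution(
        displacements=u.reshape(-1, 3),
        stresses=stresses,
        von_mises=von_mises(stresses),
        reactions=reactions.reshape(-1, 3),
        residual=residual,
    )


def strain_energy(
    mesh: TetMesh, u: np.ndarray, E: np.ndarray | float, nu: np.ndarray | float
) -> np.ndarray:
    """Per-element strain energy (N*mm): 1/2 sigma : eps * V."""
    E = np.broadcast_to(np.asarray(E, float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, float), (mesh.n_elements,))
    grads, vol = _element_gradients(mesh)
    B = _b_matrices(grads)
    ue = np.asarray(u).reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", B, ue)
    stress = np.einsum("mij,mj->mi", _elastic_matrix(E, nu), strain)
    # engineering shear convention: sigma:eps = sum over all 6 Voigt pairs
    return 0.5 * np.einsum("mi,mi->m", stress, strain) * vol


def nodal_von_mises(mesh: TetMesh, vm: np.ndarray) -> np.ndarray:
    """Volume-weighted nodal average of element von Mises values (for
    visualisation only; the element field is the primary output)."""
    vol = np.abs(mesh.volumes())
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for k in range(4):
        np.add.at(num, mesh.tets[:, k], vm * vol)
        np.add.at(den, mesh.tets[:, k], vol)
    return num / np.maximum(den, 1e-300)
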