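"""Strain-adaptive bone-density remodelling with a lazy zone.

Iterates quasi-static FE solves with a daily-stress-stimulus adaptation law:
the tissue-level effective stress of each bone element drives its apparent
density up or down whenever the stimulus leaves a "lazy zone" around the
homeostatic setpoint, and the element modulus follows the density through a
Carter-type power law E = B rho^beta. Defaults reproduce the study's uniform
bone modulus (7300 MPa) at physiological cortical density within a few
percent: B = 3790 MPa, beta = 3 gives E(1.24 g/cm^3) ~ 7222 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .types import DensityField, ParameterError, TetMesh
from . import fe


@dataclass(frozen=True)
class RemodelParams:
    """Parameters of the adaptation law.

    setpoint_stimulus (MPa/day) is the homeostatic daily stimulus psi*;
    lazy_zone_halfwidth w is a fraction of psi* within which no adaptation
    occurs; rate_constant (g/cm^3 per MPa/day per day) scales the density
    rate; modulus follows E = B rho^beta (MPa, rho in g/cm^3); density is
    clamped to [rho_min, rho_max]; n_cycles load cycles per day enter the
    stimulus as n^(1/m).
    """

    setpoint_stimulus: float = 20.0       # MPa/day
    lazy_zone_halfwidth: float = 0.1      # fraction of setpoint
    rate_constant: float = 0.002          # (g/cm^3)/(MPa/day)/day
    modulus_coefficient: float = 3790.0   # MPa (g/cm^3)^-beta
    modulus_exponent: float = 3.0
    stimulus_exponent: float = 4.0        # m
    n_cycles: float = 10_000.0            # load cycles per day
    rho_min: float = 0.05                 # g/cm^3
    rho_max: float = 1.8                  # g/cm^3
    dt: float = 1.0                       # day
    n_days: float = 60.0
    max_step: float = 0.05                # |d rho| cap per step, g/cm^3
    convergence_tol: float = 1e-4         # g/cm^3 per day

    def __post_init__(self) -> None:
        if not self.setpoint_stimulus > 0:
            raise ParameterError("setpoint stimulus must be positive")
        if not 0.0 <= self.lazy_zone_halfwidth < 1.0:
            raise ParameterError("lazy zone halfwidth must lie in [0, 1)")
        if not self.rho_min < self.rho_max:
            raise ParameterError("need rho_min < rho_max")
        if not self.dt > 0:
            raise ParameterError("dt must be positive")

    def replace(self, **kw) -> "RemodelParams":
        return replace(self, **kw)


def daily_stimulus(
    vm: np.ndarray, rho: DensityField | np.ndarray, params: RemodelParams
) -> np.ndarray:
    """Daily stress stimulus psi = n^(1/m) * sigma_bar (MPa/day).

    The tissue-level effective stress sigma_bar = sigma_vm (rho_max/rho)^2
    amplifies the continuum stress in porous (low-density) bone, making psi
    strictly decreasing in density for fixed continuum stress.
    """
    rho = rho.values if isinstance(rho, DensityField) else np.asarray(rho, float)
    if np.any(rho <= 0):
        raise ParameterError("density must be positive")
    prefactor = params.n_cycles ** (1.0 / params.stimulus_exponent)
    return prefactor * np.asarray(vm, float) * (params.rho_max / rho) ** 2


def update_density(
    rho: DensityField | np.ndarray, psi: np.ndarray, params: RemodelParams
) -> DensityField:
    """One explicit Euler step of the adaptation law.

    d rho/dt = c (psi - psi*(1+w)) above the lazy zone, c (psi - psi*(1-w))
    below it, zero inside; the step is capped at ``max_step`` and the result
    clamped to [rho_min, rho_max].
    """
    rho = rho.values if isinstance(rho, DensityField) else np.asarray(rho, float)
    hi = params.setpoint_stimulus * (1.0 + params.lazy_zone_halfwidth)
    lo = params.setpoint_stimulus * (1.0 - params.lazy_zone_halfwidth)
    rate = np.where(
        psi > hi,
        params.rate_constant * (psi - hi),
        np.where(psi < lo, params.rate_constant * (psi - lo), 0.0),
    )
    step = np.clip(rate * params.dt, -params.max_step, params.max_step)
    return DensityField(np.clip(rho + step, params.rho_min, params.rho_max))


def modulus_from_density(
    rho: DensityField | np.ndarray, params: RemodelParams
) -> np.ndarray:
    """Carter-type modulus-density coupling E = B rho^beta (MPa)."""
    rho = rho.values if isinstance(rho, DensityField) else np.asarray(rho, float)
    return params.modulus_coefficient * rho ** params.modulus_exponent


def analytic_bar_fixed_point(sigma_vm: float, params: RemodelParams) -> float:
    """Equilibrium density of a statically determinate member at constant
    continuum stress: solve n^(1/m) sigma (rho_max/rho)^2 = psi*."""
    pre = params.n_cycles ** (1.0 / params.stimulus_exponent)
    return params.rho_max * np.sqrt(pre * sigma_vm / params.setpoint_stimulus)


@dataclass
class RemodelHistory:
    """Daily density trajectory of a remodelling run."""

    days: np.ndarray                     # (S,) simulated day of each snapshot
    snapshots: list[DensityField]        # density per snapshot (S entries)
    bone_mass: np.ndarray                # (S,) total bone mass, g
    converged: bool
    final_solution: fe.FESolution | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def initial(self) -> DensityField:
        return self.snapshots[0]

    @property
    def final(self) -> DensityField:
        return self.snapshots[-1]


def run_remodelling(
    mesh: TetMesh,
    f: np.ndarray,
    fixed_nodes: np.ndarray,
    rho0: DensityField,
    params: RemodelParams,
    *,
    remodel_elements: np.ndarray | None = None,
    base_E: np.ndarray | float | None = None,
    base_nu: np.ndarray | float = 0.3,
    connector_pairs: list[tuple[int, int]] | None = None,
    connector_stiffness: float = 0.0,
    resolve_every: int = 1,
    fixed_dofs: np.ndarray | None = None,
) -> RemodelHistory:
    """Iterate FE solve -> stimulus -> density update for ``n_days`` days.

    ``rho0`` holds a density for every element; only ``remodel_elements``
    (default: element set 'bone' if present, else all) adapt and have their
    modulus slaved to density, the rest keep ``base_E``. ``resolve_every``
    re-solves the FE problem every k-th day and reuses the last stress field
    in between (k = 1 re-solves daily). Convergence is declared when the
    largest density change per day drops below ``convergence_tol``.
    """
    if remodel_elements is None:
        remodel_elements = mesh.element_sets.get(
            "bone", np.arange(mesh.n_elements)
        )
    remodel_elements = np.asarray(remodel_elements, int)
    n_steps = int(round(params.n_days / params.dt))

    E = np.broadcast_to(
        np.asarray(
            params.modulus_coefficient if base_E is None else base_E, float
        ),
        (mesh.n_elements,),
    ).copy()
    nu = np.broadcast_to(np.asarray(base_nu, float), (mesh.n_elements,)).copy()

    rho = rho0.copy()
    days = [0.0]
    snapshots = [rho.copy()]
    vol_cm3 = np.abs(mesh.volumes()) * 1e-3  # mm^3 -> cm^3
    bone_mass = [float(np.sum(rho.values[remodel_elements] * vol_cm3[remodel_elements]))]
    converged = False
    solution = None
    vm = None

    for step in range(n_steps):
        if step % max(1, resolve_every) == 0 or vm is None:
            E[remodel_elements] = modulus_from_density(
                DensityField(rho.values[remodel_elements]), params
            )
            K = fe.assemble_stiffness(mesh, E, nu)
            if connector_pairs and connector_stiffness > 0:
                K = fe.add_connectors(K, mesh, connector_pairs, connector_stiffness)
            solution = fe.solve(K, f, fixed_nodes, mesh, E, nu, fixed_dofs=fixed_dofs)
            vm = solution.von_mises
        psi = daily_stimulus(
            vm[remodel_elements], rho.values[remodel_elements], params
        )
        new_sub = update_density(rho.values[remodel_elements], psi, params)
        new = rho.copy()
        new.values[remodel_elements] = new_sub.values
        max_change = float(
            np.max(np.abs(new.values - rho.values)) / params.dt
        )
        rho = new
        days.append((step + 1) * params.dt)
        snapshots.append(rho.copy())
        bone_mass.append(
            float(np.sum(rho.values[remodel_elements] * vol_cm3[remodel_elements]))
        )
        if max_change < params.convergence_tol:
            converged = True
            break

    return RemodelHistory(
        days=np.asarray(days),
        snapshots=snapshots,
        bone_mass=np.asarray(bone_mass),
        converged=converged,
        final_solution=solution,
        metadata={"remodel_elements": remodel_elements},
    )


# ---------------------------------------------------------------------------
# Region-level comparison against reference density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityComparison:
    """Region-level agreement between predicted and reference density."""

    region_means: dict[str, tuple[float, float]]   # name -> (predicted, reference)
    rank_correlation: float                        # Spearman over region means
    same_ranking: bool
    degenerate: bool                               # reference constant


def compare_density_maps(
    predicted: DensityField,
    reference: DensityField,
    regions: dict[str, np.ndarray],
) -> DensityComparison:
    """Compare predicted vs reference density per anatomical region.

    Reports each region's mean predicted and reference density, the Spearman
    rank correlation of the region means, and whether the two rankings agree
    exactly. A constant reference makes the correlation undefined and is
    flagged instead.
    """
    if len(predicted.values) != len(reference.values):
        raise ParameterError("density fields live on different meshes")
    means = {}
    for name, ids in regions.items():
        ids = np.asarray(ids, int)
        means[name] = (
            float(predicted.values[ids].mean()),
            float(reference.values[ids].mean()),
        )
    pred = np.array([m[0] for m in means.values()])
    ref = np.array([m[1] for m in means.values()])
    degenerate = bool(np.allclose(ref, ref[0]) or np.allclose(pred, pred[0]))
    if degenerate:
        return DensityComparison(means, np.nan, False, True)
    rho_s = float(stats.spearmanr(pred, ref).statistic)
    same = bool(np.array_equal(np.argsort(pred), np.argsort(ref)))
    return DensityComparison(means, rho_s, same, False)


def calcaneus_regions(mesh: TetMesh) -> dict[str, np.ndarray]:
    """Geometric anatomical regions of the calcaneus element set.

    Returns element-id sets for the Achilles insertion (posterior-superior
    band), the talar articulation (superior band facing the talus), the
    cortical shell (elements owning a boundary face of the bone region) and
    the trabecular core (everything else).
    """
    cal = np.asarray(mesh.element_sets["calcaneus"], int)
    cent = mesh.element_centroids()[cal]
    lo, hi = cent.min(axis=0), cent.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    yf = (cent[:, 1] - lo[1]) / span[1]   # 0 posterior -> 1 anterior
    zf = (cent[:, 2] - lo[2]) / span[2]   # 0 inferior -> 1 superior

    achilles = cal[(yf <= 0.35) & (zf >= 0.5)]
    talar = cal[(yf > 0.35) & (zf >= 0.6)]

    # shell: calcaneus elements with a face not shared by another calcaneus tet
    sub = TetMesh(nodes=mesh.nodes, tets=mesh.tets[cal])
    _, owners = sub.boundary_faces_with_elements()
    shell = cal[np.unique(owners)]
    interior = np.setdiff1d(cal, np.concatenate([achilles, talar, shell]))
    return {
        "achilles_insertion": achilles,
        "talar_articulation": talar,
        "shell": shell,
        "core": interior if interior.size else cal,
    }
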