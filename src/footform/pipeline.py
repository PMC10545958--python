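"""Umbrella pipeline: synthetic data -> gait -> shape -> FE -> remodelling.

A validated YAML/dict config drives the stages in order and a machine-readable
``summary.json`` collects the headline numbers of each stage (regional
pressure statistics, CoP ranges, Hausdorff summaries, peak von Mises per
bone, terminal density per calcaneal region). Reruns with the same config and
seed reproduce all numeric outputs bitwise: every stage is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__, fe, gait, io, remodel, shape, synthetic
from .types import ARCHETYPES, DensityField, ParameterError

log = logging.getLogger(__name__)

STAGES = ("simulate", "gait", "shape", "fe", "remodel")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    archetype: str = "NF"
    seed: int = 0
    out: str = "footform_run"
    stages: tuple[str, ...] = STAGES
    n_trials: int = 3
    n_frames: int = 51
    grid_shape: tuple[int, int] = (16, 6)
    noise_rel: float = 0.02
    target_edge: float = 8.0
    n_days: float = 60.0
    resolve_every: int = 1
    setpoint: str | float = "auto"
    reference_archetype: str = "NF"
    write_files: bool = True

    _GROUPS = {
        "gait": {"n_trials", "n_frames", "grid_shape", "noise_rel"},
        "fe": {"target_edge"},
        "remodel": {"n_days", "resolve_every", "setpoint"},
        "shape": {"reference_archetype"},
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build and validate a config from a (possibly nested) dict.

        Stage parameter blocks (``gait:``, ``fe:``, ``remodel:``, ``shape:``)
        are flattened; unknown keys anywhere are rejected.
        """
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        flat: dict = {}
        for key, value in raw.items():
            if key in cls._GROUPS:
                if not isinstance(value, dict):
                    raise ConfigError(f"stage block {key!r} must be a mapping")
                for k, v in value.items():
                    if k not in cls._GROUPS[key]:
                        raise ConfigError(f"unknown key {key}.{k!r}")
                    flat[k] = v
            else:
                flat[key] = value
        known = set(cls.__dataclass_fields__) - {"_GROUPS"}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**flat)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {self.archetype!r}")
        if self.reference_archetype not in ARCHETYPES:
            raise ConfigError(f"unknown reference archetype {self.reference_archetype!r}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.target_edge <= 0:
            raise ConfigError("target_edge must be positive")
        if isinstance(self.setpoint, str) and self.setpoint != "auto":
            raise ConfigError("setpoint must be a number or 'auto'")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    summary: dict
    out_dir: str | None
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order and write the run summary."""
    t_start = time.time()
    params = ARCHETYPES[config.archetype].replace(seed=config.seed)
    out = config.out if config.write_files else None
    if out:
        os.makedirs(out, exist_ok=True)

    summary: dict = {
        "archetype": config.archetype,
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.digest(),
    }
    artifacts: dict = {"params": params}
    timers: dict[str, float] = {}

    bones = model = trials = stats_df = None
    mean_pressures: dict[str, float] = {}

    for stage in config.stages:
        t0 = time.time()
        log.info("stage %s ...", stage)
        if stage == "simulate":
            bones = synthetic.generate_foot_bones(params)
            model = synthetic.generate_foot_model(params, config.target_edge)
            trials = [
                synthetic.generate_pressure_series(
                    params,
                    n_frames=config.n_frames,
                    grid_shape=config.grid_shape,
                    noise_rel=config.noise_rel,
                    trial_seed=i,
                )
                for i in range(config.n_trials)
            ]
            artifacts.update(bones=bones, model=model, trials=trials)
            lengths = np.vstack([m.vertices for m in bones.values()])
            summary["simulate"] = {
                "bones": list(bones),
                "bbox_length_mm": float(
                    lengths[:, 1].max() - lengths[:, 1].min()
                ),
                "n_elements": model.n_elements,
                "n_nodes": model.n_nodes,
                "n_trials": len(trials),
            }
            if out:
                for lbl, m in bones.items():
                    io.write_stl(m, os.path.join(out, f"{lbl}.stl"))
                io.write_inp(model, os.path.join(out, "model.inp"))
                for i, tr in enumerate(trials):
                    io.write_pressure_csv(
                        tr, os.path.join(out, f"pressure_trial{i}.csv")
                    )
        elif stage == "gait":
            if trials is None:
                raise ParameterError("gait stage requires the simulate stage")
            regions = gait.RegionMap.for_archetype(
                params.name, config.grid_shape, params.foot_length, params.foot_width
            )
            per_trial = [gait.regional_stats(tr, regions) for tr in trials]
            stats_df = sum(per_trial[1:], per_trial[0]) / len(per_trial)
            cops = [
                gait.normalize_cop(tr, params.foot_length, params.foot_width)
                for tr in trials
            ]
            x_mean = np.mean([c.x_pct for c in cops], axis=0)
            y_mean = np.mean([c.y_pct for c in cops], axis=0)
            grf = np.mean([gait.compute_grf(tr) for tr in trials], axis=0)
            mean_pressures = stats_df["mean_kpa"].to_dict()
            summary["gait"] = {
                "regional_stats_kpa": {
                    r: {
                        "peak": float(stats_df.loc[r, "peak_kpa"]),
                        "mean": float(stats_df.loc[r, "mean_kpa"]),
                    }
                    for r in stats_df.index
                },
                "grf_peak_n": float(grf.max()),
                "grf_peak_bw": float(grf.max() / params.body_weight),
                "cop_ml_range_pct_width": float(x_mean.max() - x_mean.min()),
                "cop_ap_range_pct_length": float(y_mean.max() - y_mean.min()),
            }
            artifacts.update(regions=regions, cop_x=x_mean, cop_y=y_mean, grf=grf)
            if out:
                stats_df.to_csv(os.path.join(out, "regional_stats.csv"))
                np.savetxt(
                    os.path.join(out, "cop_trajectory.csv"),
                    np.column_stack([cops[0].stance_pct, x_mean, y_mean]),
                    delimiter=",",
                    header="stance_pct,x_pct_width,y_pct_length",
                    comments="",
                )
        elif stage == "shape":
            if bones is None:
                raise ParameterError("shape stage requires the simulate stage")
            ref_params = ARCHETYPES[config.reference_archetype].replace(
                seed=config.seed
            )
            ref_bones = (
                bones
                if config.reference_archetype == config.archetype
                else synthetic.generate_foot_bones(ref_params)
            )
            shape_block = {}
            error_maps = {}
            for lbl in synthetic.BONE_LABELS:
                morphed, errs, summary_d = shape.compare_bones(
                    ref_bones[lbl], bones[lbl]
                )
                error_maps[lbl] = errs
                shape_block[lbl] = {
                    "hausdorff_mm": summary_d.symmetric,
                    "distance_mean_mm": summary_d.mean,
                    "distance_sd_mm": summary_d.sd,
                    "mean_signed_error_mm": float(np.mean(errs)),
                }
                if out:
                    io.write_error_map_csv(
                        os.path.join(out, f"errormap_{lbl}.csv"), errs
                    )
                    io.write_ply(
                        morphed, os.path.join(out, f"errormap_{lbl}.ply"), errs
                    )
            summary["shape"] = shape_block
            artifacts["error_maps"] = error_maps
        elif stage == "fe":
            if model is None:
                raise ParameterError("fe stage requires the simulate stage")
            solution, E, nu, f, fixed = _solve_stance(
                model, params, mean_pressures, config
            )
            energy = fe.strain_energy(model, solution.displacements, E, nu)
            bone_ids = model.element_sets["bone"]
            cent_y = model.element_centroids()[:, 1]
            rear = bone_ids[cent_y[bone_ids] < 0.35 * params.foot_length]
            bone_energy = float(energy[bone_ids].sum())
            peak_vm = {
                lbl: float(solution.von_mises[model.element_sets[lbl]].max())
                for lbl in synthetic.BONE_LABELS
            }
            summary["fe"] = {
                "peak_von_mises_mpa": peak_vm,
                "rearfoot_energy_share": float(energy[rear].sum() / bone_energy)
                if bone_energy > 0
                else 0.0,
                "residual": solution.residual,
            }
            artifacts.update(solution=solution, fe_E=E, fe_nu=nu, fe_load=f, fe_fixed=fixed)
            if out:
                io.write_vtk(
                    model,
                    os.path.join(out, "fe_results.vtk"),
                    cell_data={"von_mises_mpa": solution.von_mises},
                    point_data={
                        "displacement_mm": np.linalg.norm(
                            solution.displacements, axis=1
                        )
                    },
                )
        elif stage == "remodel":
            if model is None:
                raise ParameterError("remodel stage requires the simulate stage")
            history, rparams = _run_remodel(model, params, mean_pressures, config)
            regions_cal = remodel.calcaneus_regions(model)
            rho0 = history.initial
            rho_end = history.final
            summary["remodel"] = {
                "n_days": float(history.days[-1]),
                "converged": history.converged,
                "setpoint_mpa_per_day": rparams.setpoint_stimulus,
                "terminal_density_g_cm3": {
                    name: float(rho_end.values[ids].mean())
                    for name, ids in regions_cal.items()
                },
                "density_gain_g_cm3": {
                    name: float(
                        (rho_end.values[ids] - rho0.values[ids]).mean()
                    )
                    for name, ids in regions_cal.items()
                },
                "bone_mass_g": float(history.bone_mass[-1]),
            }
            artifacts.update(history=history, calcaneus_regions=regions_cal)
            if out:
                io.write_vtk(
                    model,
                    os.path.join(out, "remodel_density.vtk"),
                    cell_data={"density_g_cm3": rho_end.values},
                )
        timers[stage] = time.time() - t0

    summary["timers_s"] = {k: round(v, 3) for k, v in timers.items()}
    summary["elapsed_s"] = round(time.time() - t_start, 3)
    if out:
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(os.path.join(out, "run.log"), "w") as fh:
            fh.write(
                f"footform {__version__}\nseed {config.seed}\n"
                f"config_hash {config.digest()}\n"
                f"numpy {np.__version__}\n"
            )
    return PipelineResult(summary=summary, out_dir=out, artifacts=artifacts)


# ---------------------------------------------------------------------------
# Stage helpers (also used directly by tests and the acceptance script)
# ---------------------------------------------------------------------------

def _default_pressures(params) -> dict[str, float]:
    """Fallback regional mean stance pressures when the gait stage was
    skipped: share-weighted split of the mean stance GRF over region areas."""
    series = synthetic.generate_pressure_series(params)
    regions = gait.RegionMap.for_archetype(
        params.name, series.grid_shape, params.foot_length, params.foot_width
    )
    return gait.regional_stats(series, regions)["mean_kpa"].to_dict()


def _solve_stance(model, params, mean_pressures, config):
    """Assemble and solve the mean-stance load case for one archetype."""
    if not mean_pressures:
        mean_pressures = _default_pressures(params)
    E, nu = fe.material_arrays(
        model, {"bone": fe.BONE, "soft": fe.SOFT_TISSUE}
    )
    K = fe.assemble_stiffness(model, E, nu)
    K = fe.add_connectors(
        K, model, model.metadata["fascia_pairs"], fe.FASCIA_STIFFNESS
    )
    regions = gait.RegionMap.for_archetype(
        params.name, config.grid_shape, params.foot_length, params.foot_width
    )
    faces, _ = fe.plantar_faces(model)
    face_regions = fe.assign_plantar_faces(
        model, regions, params.foot_length, params.foot_width
    )
    f = fe.apply_plantar_pressure(model, face_regions, mean_pressures, faces=faces)
    f += fe.achilles_load(
        model, fe.ACHILLES_BW_FRACTION * params.body_weight
    )
    fixed = model.node_sets["fixed_proximal"]
    solution = fe.solve(K, f, fixed, model, E, nu)
    return solution, E, nu, f, fixed


def _run_remodel(model, params, mean_pressures, config):
    """Remodelling run with the pipeline's homeostatic-setpoint convention.

    ``setpoint='auto'`` takes the median day-0 stimulus of the bone elements
    as the homeostatic setpoint (the model starts in equilibrium on average),
    so adaptation redistributes density from shielded to overloaded regions.
    """
    solution, E, nu, f, fixed = _solve_stance(model, params, mean_pressures, config)
    bone_ids = model.element_sets["bone"]
    rparams = remodel.RemodelParams(n_days=config.n_days)
    rho0 = DensityField(np.full(model.n_elements, 1.24))
    if config.setpoint == "auto":
        psi0 = remodel.daily_stimulus(
            solution.von_mises[bone_ids], rho0.values[bone_ids], rparams
        )
        rparams = rparams.replace(
            setpoint_stimulus=max(float(np.median(psi0)), 1e-6)
        )
    else:
        rparams = rparams.replace(setpoint_stimulus=float(config.setpoint))
    history = remodel.run_remodelling(
        model,
        f,
        fixed,
        rho0,
        rparams,
        remodel_elements=bone_ids,
        base_E=E,
        base_nu=nu,
        connector_pairs=model.metadata["fascia_pairs"],
        connector_stiffness=fe.FASCIA_STIFFNESS,
        resolve_every=config.resolve_every,
    )
    return history, rparams
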