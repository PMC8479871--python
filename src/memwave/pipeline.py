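"""Run orchestration: simulate -> reconstruct -> map -> dfa -> phase ->
kinematics from a single config, with a JSON summary report.

The config is a TOML file mirroring the CLI flags; one ``[stage_name]`` table
per requested stage, executed in dependency order.  Re-running with the same
config and seed reproduces identical outputs (all stochastic stages are keyed
by the global seed).
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .reconstruction import (
    StackMetadata,
    detect_contact_perimeter,
    load_cell,
    sample_signal,
    save_cell,
    locate_membrane,
    triangulate_surface,
)
from .synthetic_cell import SceneSpec, make_scene, save_scene, voxelize, write_stack

log = logging.getLogger("memwave")

STAGES = ("simulate", "reconstruct", "map", "dfa", "phase", "kinematics")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    stages: list[str]
    out: Path
    seed: int = 0
    params: dict = field(default_factory=dict)  # per-stage parameter blocks

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as f:
            doc = tomllib.load(f)
        stages = doc.get("stages", list(STAGES))
        for s in stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid: {STAGES}")
        out = Path(doc.get("out", "memwave_run"))
        seed = int(doc.get("seed", 0))
        params = {s: doc.get(s, {}) for s in stages}
        return cls(stages=stages, out=out, seed=seed, params=params)

    def __post_init__(self) -> None:
        order = {s: i for i, s in enumerate(STAGES)}
        for s in self.stages:
            if s not in order:
                raise ConfigError(f"unknown stage {s!r}; valid: {STAGES}")
        self.stages = sorted(set(self.stages), key=order.__getitem__)


def run(config: RunConfig) -> dict:
    """Execute the configured stages on one (synthetic or provided) cell.

    Returns the report dict (also written to <out>/report.json).  Any stage
    error aborts with the stage name; artifacts of completed stages remain.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": config.stages, "params": config.params}
    mesh = signal = truth = None
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            p = dict(config.params.get("simulate", {}))
            p.setdefault("seed", config.seed)
            spec = SceneSpec(**p)
            mesh, signal, truth = make_scene(spec)
            save_scene(out / "scene", spec, mesh, signal, truth)
            report["simulate"] = {"pattern": spec.pattern, "n_nodes": mesh.n_nodes,
                                  "n_frames": signal.n_times,
                                  "mean_node_area_um2": mesh.mean_node_area}

        if "reconstruct" in config.stages:
            stage = "reconstruct"
            p = dict(config.params.get("reconstruct", {}))
            stack_path = p.pop("stack", None)
            meta = StackMetadata(dx=p.pop("dx", 0.2666), dy=p.pop("dy", 0.2666),
                                 dz=p.pop("dz", 0.5), dt=p.pop("dt", 10.0))
            if stack_path is not None:
                from .synthetic_cell import read_stack
                stack = read_stack(stack_path)
            else:
                if mesh is None or signal is None:
                    raise ConfigError("reconstruct needs a stack path or a simulate stage")
                stack, meta = voxelize(mesh, signal, meta,
                                       psf_sd=p.pop("psf_sd", 0.3))
                write_stack(out / "stack.tif", stack, meta)
            points = locate_membrane(stack, meta,
                                     n_directions=int(p.pop("n_directions", 1000)))
            mesh = triangulate_surface(points, target_node_area=p.pop("node_area", 0.3))
            mesh = detect_contact_perimeter(mesh, flatness_tol=p.pop("flatness_tol", 0.5))
            signal = sample_signal(stack, mesh, meta)
            save_cell(out / "cell.h5", mesh, signal)
            report["reconstruct"] = {"n_nodes": mesh.n_nodes,
                                     "mean_node_area_um2": mesh.mean_node_area,
                                     "R_eff_um": mesh.effective_radius,
                                     "theta_adh": mesh.theta_adh}

        if mesh is None or signal is None:
            cell_path = config.params.get("cell")
            if cell_path:
                mesh, signal = load_cell(cell_path)
            else:
                raise ConfigError("no upstream stage produced a cell and no 'cell' input given")

        if "map" in config.stages:
            stage = "map"
            from .mapping import extract_kymograph, render_map

            p = dict(config.params.get("map", {}))
            t_idx = int(p.get("time_index", signal.n_times // 2))
            grid, _ = render_map(mesh, signal.values[:, t_idx],
                                 png_path=out / "signal_map.png",
                                 title=f"signal, t = {signal.times[t_idx]:.0f} s")
            np.save(out / "signal_map.npy", grid)
            sections = ["center", "top"] + (["bottom"] if mesh.adherent.any() else [])
            for sec in sections:
                kymo = extract_kymograph(signal, mesh, sec)
                np.savetxt(out / f"kymograph_{sec}.csv", kymo, delimiter=",")
            report["map"] = {"time_index": t_idx, "sections": sections}

        if "dfa" in config.stages:
            stage = "dfa"
            from .fluctuation import DfaConfig, alpha_map, alpha_profile

            p = dict(config.params.get("dfa", {}))
            cfg = DfaConfig(t_max=p.get("t_max", 180.0), order=int(p.get("order", 1)))
            amap = alpha_map(signal, mesh, cfg)
            prof = alpha_profile(amap, mesh, poly_order=int(p.get("poly_order", 4)))
            np.savetxt(out / "alpha.csv",
                       np.column_stack([mesh.theta, mesh.phi, amap.alpha, amap.r_squared]),
                       delimiter=",", header="theta,phi,alpha,r2", comments="")
            report["dfa"] = {"alpha_min": prof.alpha_min, "alpha_adh": prof.alpha_adh,
                             "delta_alpha": prof.delta_alpha,
                             "alpha_mean": float(np.nanmean(amap.alpha)),
                             "n_flagged": int(amap.flagged.sum())}
            with open(out / "alpha_profile.json", "w") as f:
                json.dump({"alpha_min": prof.alpha_min, "alpha_adh": prof.alpha_adh,
                           "delta_alpha": prof.delta_alpha,
                           "poly_coefficients": prof.coefficients.tolist()}, f, indent=1)

        if "phase" in config.stages:
            stage = "phase"
            from .phase import (WaveletConfig, find_singularities, phase_map,
                                track_and_classify)

            p = dict(config.params.get("phase", {}))
            cfg = WaveletConfig(t_min=p.get("t_min", 60.0), t_max=p.get("t_max", 330.0))
            pmap = phase_map(signal, mesh, cfg)
            rows = []
            per_frame = []
            for t in range(pmap.phase.shape[1]):
                try:
                    sings = find_singularities(pmap, mesh, t)
                except ValueError:
                    sings = []
                per_frame.append(sings)
            tracks = []
            if len(per_frame) >= 5:
                tracks = track_and_classify(per_frame, mesh,
                                            pin_dist=p.get("pin_dist", 1.0))
            for k, tr in enumerate(tracks):
                for t_i, pos, d in zip(tr.times, tr.positions, tr.dist_to_perimeter):
                    rows.append({"time_s": float(pmap.times[t_i]), "x": pos[0],
                                 "y": pos[1], "z": pos[2], "charge": tr.charge,
                                 "dist_to_perimeter_um": d, "track_id": k,
                                 "pinned": tr.pinned})
            import pandas as pd

            pd.DataFrame(rows, columns=["time_s", "x", "y", "z", "charge",
                                        "dist_to_perimeter_um", "track_id",
                                        "pinned"]).to_csv(out / "singularities.csv",
                                                          index=False)
            report["phase"] = {"n_tracks": len(tracks),
                               "n_pinned": sum(tr.pinned for tr in tracks),
                               "mean_period_s": float(np.nanmean(
                                   np.where(pmap.valid, pmap.period, np.nan)))
                               if pmap.valid.any() else float("nan")}

        if "kinematics" in config.stages:
            stage = "kinematics"
            from .kinematics import decompose_velocity, shape_descriptors, track_domain

            geom = shape_descriptors(mesh)
            report["kinematics"] = {"geometry": geom.as_dict()}
            try:
                track = track_domain(signal, mesh)
                vel = decompose_velocity(track, mesh)
                report["kinematics"]["velocity"] = vel.as_dict()
            except ValueError as exc:
                report["kinematics"]["velocity"] = None
                log.info("no trackable domain: %s", exc)

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, default=float)
    return report
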