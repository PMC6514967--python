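"""One-shot pipeline: initial metadynamics → walker seeding → multiwalker
run → FES + minimum → extraction → clustering → unbiased refinement →
report.

Every stage writes plain-text outputs into the run directory and records
them in ``manifest.json``; a rerun with ``resume=True`` reloads completed
stages from those files instead of recomputing, and ``stop_after`` truncates
the flow after a named stage.  All randomness derives from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mbio
from .binding_mode import (ExtractionParams, cluster_frames, extract_frames,
                           report_clusters, superpose_backbone)
from .dynamics import RunSpec, initial_state, run_multiwalker, run_segment
from .fes import locate_minimum, reconstruct_fes, read_fes, write_fes
from .frames import FrameSet
from .metadynamics import (MetaDParams, SharedHills, read_hills,
                           select_walker_seeds, write_colvar, write_hills)
from .restraints import FunnelParams, WallParams
from .toy_systems import (ToySystem, load_system, make_binding_system,
                          make_double_well, save_system)
from .refine import convergence_report, refine_representative

logger = logging.getLogger("metabind")

__all__ = ["PipelineConfig", "run_pipeline", "escape_guard", "STAGES"]

STAGES = ["system", "initial", "seeds", "multiwalker", "fes", "extract",
          "cluster", "refine", "report"]


@dataclass
class PipelineConfig:
    """Full configuration of one protocol run.

    Metadynamics defaults follow the published settings: the initial
    pathway-sampling run uses bias factor 50 and hill height 7 kJ/mol, the
    multiple-walker production run bias factor 20 and 5 kJ/mol, both with
    σ = 0.1 nm; 32 walkers; a 3 Å extraction window; five clusters.
    Run lengths are desk-scale defaults for the toy systems.
    """

    system: dict = field(default_factory=lambda: {"kind": "binding"})
    seed: int = 0
    outdir: str = "metabind_run"
    n_walkers: int = 32
    n_clusters: int = 5
    delta_cv: float = 0.3
    initial_metad: dict = field(default_factory=lambda: {
        "gamma": 50.0, "w0": 7.0, "sigma": 0.1, "stride": 500})
    multiwalker_metad: dict = field(default_factory=lambda: {
        "gamma": 20.0, "w0": 5.0, "sigma": 0.1, "stride": 500})
    walls: dict | None = None      # default: from the system metadata
    funnel: dict | None = None
    initial_steps: int = 100_000
    multiwalker_steps: int = 40_000
    refine_steps: int = 40_000
    dt: float = 0.005
    friction: float = 1.0
    output_stride: int = 100
    escape_threshold: float = 0.2
    rmsd_tol: float = 2.0
    flexible_sd: float = 1.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def escape_guard(config: PipelineConfig, trajectory: FrameSet,
                 pocket_entry_cv: float, walls: WallParams) -> WallParams:
    """Tighten the upper CV wall when the initial run under-samples the
    pocket.

    If fewer than ``escape_threshold`` of the initial-run frames have a CV
    below the pocket-entry CV, the ligand mostly escaped into the solvent
    and the upper wall is lowered to the pocket entry; otherwise the walls
    are returned unchanged.
    """
    if len(trajectory) == 0:
        return walls
    inside = float(np.mean(trajectory.cv < pocket_entry_cv))
    if inside < config.escape_threshold:
        logger.info("escape guard fired: %.1f%% of frames inside the pocket "
                    "(< %.1f%%); lowering z_up to %.3f nm",
                    100 * inside, 100 * config.escape_threshold,
                    pocket_entry_cv)
        return WallParams(z_low=walls.z_low, z_up=pocket_entry_cv,
                          kappa=walls.kappa)
    logger.info("escape guard not fired: %.1f%% of frames inside the pocket",
                100 * inside)
    return walls


def _build_system(config: PipelineConfig) -> ToySystem:
    src = dict(config.system)
    kind = src.pop("kind", "binding")
    if kind == "binding":
        src.setdefault("seed", config.seed)
        return make_binding_system(**src)
    if kind == "double_well":
        src.setdefault("delta_f", 10.0)
        src.setdefault("barrier", 15.0)
        src.setdefault("well_separation", 2.0)
        return make_double_well(**src)
    if kind == "file":
        return load_system(src["path"])
    raise ValueError(f"unknown system kind {kind!r}")


def _restraints(config: PipelineConfig, system: ToySystem):
    wall_dict = config.walls or system.metadata.get("walls")
    funnel_dict = config.funnel or system.metadata.get("funnel")
    walls = WallParams(**wall_dict) if wall_dict else None
    funnel = FunnelParams(**funnel_dict) if funnel_dict else None
    return walls, funnel


def run_pipeline(config: PipelineConfig, stop_after: str | None = None,
                 resume: bool = False) -> dict:
    """Execute the protocol; returns the manifest dict.

    ``stop_after`` names the last stage to run (one of STAGES); with
    ``resume`` completed stages are reloaded from the run directory.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; stages: {STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (mbio.read_manifest(manifest_path)
                if resume and manifest_path.exists()
                else {"seed": config.seed, "stages": {}})
    manifest["config"] = asdict(config)
    stages = manifest["stages"]
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(STAGES, master.spawn(len(STAGES)))}

    def done(stage: str) -> bool:
        return resume and stage in stages and all(
            (out / f).exists() for f in stages[stage].get("outputs", []))

    def finish(stage: str, outputs: list[str], **info) -> None:
        stages[stage] = {"outputs": outputs, "seed": stage_seeds[stage], **info}
        mbio.write_manifest(manifest_path, manifest)
        logger.info("stage %s complete: %s", stage, ", ".join(outputs))

    def stop(stage: str) -> bool:
        return stop_after == stage

    # -- system -------------------------------------------------------------
    if done("system"):
        system = load_system(out / "system.yaml")
    else:
        system = _build_system(config)
        save_system(system, out / "system.yaml")
        finish("system", ["system.yaml"], name=system.name)
    walls, funnel = _restraints(config, system)
    if stop("system"):
        return manifest

    # -- initial pathway-sampling metadynamics ------------------------------
    initial_metad = MetaDParams(temperature=system.temperature,
                                **config.initial_metad)
    init_spec = RunSpec(n_steps=config.initial_steps, dt=config.dt,
                        friction=config.friction,
                        temperature=system.temperature,
                        seed=stage_seeds["initial"],
                        output_stride=config.output_stride, biased=True,
                        walls=walls, funnel=funnel, metad=initial_metad)
    if done("initial"):
        init_frames = mbio.read_xyz(out / "initial_traj.xyz")
        guard_fired = stages["initial"].get("escape_guard_fired", False)
    else:
        rng = np.random.default_rng(init_spec.seed)
        state = initial_state(system, init_spec, rng=rng)
        traj, colvar, hills = run_segment(system, state, init_spec, rng=rng)
        pocket_entry = float(system.metadata.get("pocket_entry_cv", np.inf))
        adjusted = escape_guard(config, traj, pocket_entry, walls) if walls \
            else walls
        guard_fired = adjusted is not walls and adjusted != walls
        frames_pool = [traj]
        if guard_fired:
            # rerun from the pocket entry under the tightened wall and merge
            # the frame pools so seeding still spans the whole pathway
            entry_coords = system.coordinates.copy()
            shiftz = pocket_entry - system.reference_cv
            entry_coords[system.ligand_indices] = (
                system.reference_pose + np.array([0.0, 0.0, shiftz]))
            spec2 = replace(init_spec, walls=adjusted,
                            seed=(init_spec.seed + 1) % 2**31)
            rng2 = np.random.default_rng(spec2.seed)
            state2 = initial_state(system, spec2, entry_coords, rng=rng2)
            traj2, colvar2, hills2 = run_segment(system, state2, spec2,
                                                 rng=rng2)
            frames_pool.append(traj2)
        init_frames = FrameSet.concatenate(frames_pool)
        mbio.write_xyz(out / "initial_traj.xyz", init_frames)
        write_colvar(out / "initial_colvar.dat", [t for t, _ in colvar],
                     [c for _, c in colvar])
        write_hills(out / "initial_hills.dat", hills,
                    gamma=initial_metad.gamma)
        finish("initial", ["initial_traj.xyz", "initial_colvar.dat",
                           "initial_hills.dat"],
               escape_guard_fired=bool(guard_fired))
    if stop("initial"):
        return manifest

    # -- walker seeding -----------------------------------------------------
    if done("seeds"):
        seeds = mbio.read_xyz(out / "walker_seeds.xyz")
    else:
        seeds = select_walker_seeds(init_frames, config.n_walkers)
        mbio.write_xyz(out / "walker_seeds.xyz", seeds)
        finish("seeds", ["walker_seeds.xyz"],
               cv_range=[float(seeds.cv.min()), float(seeds.cv.max())])
    if stop("seeds"):
        return manifest

    # -- multiple-walker production metadynamics ----------------------------
    mw_metad = MetaDParams(temperature=system.temperature,
                           **config.multiwalker_metad)
    mw_spec = RunSpec(n_steps=config.multiwalker_steps, dt=config.dt,
                      friction=config.friction,
                      temperature=system.temperature,
                      seed=stage_seeds["multiwalker"],
                      output_stride=config.output_stride, biased=True,
                      walls=walls, funnel=funnel, metad=mw_metad)
    if done("multiwalker"):
        mw_frames = mbio.read_xyz(out / "multiwalker_traj.xyz")
        hills = SharedHills(read_hills(out / "multiwalker_hills.dat"))
    else:
        trajs, colvars, hills = run_multiwalker(system, seeds, mw_spec,
                                                config.n_walkers)
        mw_frames = FrameSet.concatenate(trajs)
        mbio.write_xyz(out / "multiwalker_traj.xyz", mw_frames)
        write_hills(out / "multiwalker_hills.dat", hills,
                    gamma=mw_metad.gamma)
        for w, colvar in enumerate(colvars):
            write_colvar(out / f"multiwalker_colvar.{w}.dat",
                         [t for t, _ in colvar], [c for _, c in colvar])
        finish("multiwalker",
               ["multiwalker_traj.xyz", "multiwalker_hills.dat"]
               + [f"multiwalker_colvar.{w}.dat"
                  for w in range(config.n_walkers)],
               n_hills=len(hills))
    if stop("multiwalker"):
        return manifest

    # -- free-energy profile and its minimum --------------------------------
    if done("fes"):
        profile = read_fes(out / "fes.dat")
        minimum_cv = profile.minimum_cv
    else:
        profile = reconstruct_fes(hills, mw_metad.gamma)
        minimum_cv = locate_minimum(profile)
        profile.minimum_cv = minimum_cv
        write_fes(out / "fes.dat", profile)
        finish("fes", ["fes.dat"], minimum_cv=minimum_cv)
    if stop("fes"):
        return manifest

    # -- extraction around the minimum --------------------------------------
    if done("extract"):
        extracted = mbio.read_xyz(out / "extracted_frames.xyz")
        fraction = stages["extract"]["fraction_pct"]
    else:
        extracted, fraction = extract_frames(
            mw_frames, minimum_cv, ExtractionParams(delta_cv=config.delta_cv))
        mbio.write_xyz(out / "extracted_frames.xyz", extracted)
        finish("extract", ["extracted_frames.xyz"],
               fraction_pct=float(fraction), n_frames=len(extracted))
    if stop("extract"):
        return manifest

    # -- backbone superposition + clustering --------------------------------
    reference = system.coordinates.copy()
    reference[system.ligand_indices] = system.reference_pose
    if done("cluster"):
        assignments = pd.read_csv(out / "cluster_assignments.csv")
        reps = mbio.read_xyz(out / "cluster_representatives.xyz")
        rep_coords = reps.coordinates
        cluster_table = pd.read_csv(out / "cluster_report.csv")
    else:
        fitted = superpose_backbone(extracted, reference)
        result = cluster_frames(fitted, config.n_clusters)
        cluster_table = report_clusters(result, fitted, reference)
        assignments = pd.DataFrame({
            "frame": np.arange(len(fitted)),
            "walker": fitted.walker_id,
            "time": fitted.time,
            "cv": fitted.cv,
            "cluster": result.labels,
        })
        assignments.to_csv(out / "cluster_assignments.csv", index=False)
        reps = fitted.subset(result.representative_indices)
        rep_coords = reps.coordinates
        mbio.write_xyz(out / "cluster_representatives.xyz", reps)
        cluster_table.to_csv(out / "cluster_report.csv", index=False)
        (out / "cluster_report.txt").write_text(
            cluster_table.to_string(index=False, float_format="%.2f") + "\n")
        finish("cluster", ["cluster_assignments.csv",
                           "cluster_representatives.xyz",
                           "cluster_report.csv", "cluster_report.txt"],
               populations=[float(p) for p in result.populations],
               truncated=bool(result.truncated))
    if stop("cluster"):
        return manifest

    # -- unbiased refinement ------------------------------------------------
    refine_spec = RunSpec(n_steps=config.refine_steps, dt=config.dt,
                          friction=config.friction,
                          temperature=system.temperature,
                          seed=stage_seeds["refine"],
                          output_stride=config.output_stride, biased=False)
    if done("refine"):
        refine_table = pd.read_csv(out / "refinement_report.csv")
        outcomes = None
        success = bool(stages["refine"]["success"])
        note = stages["refine"]["note"]
    else:
        outcomes = []
        streams = np.random.SeedSequence(stage_seeds["refine"]).spawn(
            len(rep_coords))
        for c, coords in enumerate(rep_coords, start=1):
            rng = np.random.default_rng(streams[c - 1])
            outcome = refine_representative(
                system, coords, refine_spec, cluster_id=c,
                rmsd_tol=config.rmsd_tol, flexible_sd=config.flexible_sd,
                rng=rng)
            pd.DataFrame({"time_ps": outcome.rmsd_series[:, 0],
                          "rmsd_A": outcome.rmsd_series[:, 1],
                          "cv_nm": outcome.cv_series[:, 1]}).to_csv(
                out / f"refine_cluster{c}.csv", index=False)
            outcomes.append(outcome)
        refine_table, success, note = convergence_report(outcomes)
        refine_table.to_csv(out / "refinement_report.csv", index=False)
        (out / "refinement_report.txt").write_text(
            refine_table.to_string(index=False) + f"\n\n{note}\n")
        finish("refine", ["refinement_report.csv", "refinement_report.txt"]
               + [f"refine_cluster{c}.csv"
                  for c in range(1, len(rep_coords) + 1)],
               success=bool(success), note=note)
    if stop("refine"):
        return manifest

    # -- final report -------------------------------------------------------
    summary = {
        "system": system.name,
        "reference_cv": float(system.reference_cv),
        "fes_minimum_cv": float(minimum_cv),
        "extracted_fraction_pct": float(fraction),
        "cluster_populations_pct": cluster_table["population_pct"].tolist(),
        "top_cluster_ligand_rmsd_A": (
            float(cluster_table["ligand_rmsd_A"].iloc[0])
            if "ligand_rmsd_A" in cluster_table else None),
        "refinement": refine_table.to_dict(orient="records"),
        "success": bool(success),
        "note": note,
    }
    mbio.write_manifest(out / "final_report.json", summary)
    finish("report", ["final_report.json"], **summary)
    return manifest
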