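"""End-to-end orchestration: QC → selection → estimation → decomposition → summary.

``run_pipeline`` drives the whole analysis from a single YAML config and
writes a deterministic directory layout:

    qc/              per-replicate metric CSVs and QC report JSONs
    fep/             per-pose free-energy estimates (JSON) + poses.csv
    decomposition/   per-residue contribution table (CSV)
    summary/         isoform binding free energies and ranking (CSV)
    run_log.json     package version, config hash, seed

``synthesize_inputs`` writes a complete synthetic input bundle (fepout
files, pair-energy CSV, multi-model PDB trajectories, config) with its
ground truth, so a full run needs nothing but this package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import IsoformSummary, PoseEstimate, isoform_binding_energy, rank_isoforms
from .decomposition import decomposition_table
from .estimators import RT_KCAL_MOL, total_free_energy
from .fep_io import LambdaSchedule, parse_fepout, parse_pair_energies, write_fepout, write_pair_energies
from .selection import QCThresholds, evaluate_replicate, rank_replicates
from .synthetic import (
    GaussianWorkSpec,
    ToyTrajectorySpec,
    gen_gaussian_work,
    gen_pair_energies,
    gen_toy_trajectory,
    write_trajectory_pdb,
)
from .traj_metrics import (
    com_displacement,
    hbond_metrics,
    helix_angle,
    lid_distance,
    ligand_rmsd,
    load_trajectory,
)

__all__ = ["PipelineStageError", "RunConfig", "run_pipeline", "synthesize_inputs"]

#: MDAnalysis selection strings matching the segment labels written by
#: :func:`hcnfep.synthetic.write_trajectory_pdb`.
_DEFAULT_SELECTIONS = {
    "ligand": "resname CMP",
    "sheet_ca": "segid SHE",
    "helixB_ca": "segid HXB",
    "helixC_ca": "segid HXC",
    "lid_pair": "segid LID",
}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration (see ``synthesize_inputs`` for the schema)."""

    raw: dict
    base_dir: Path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if raw.get("version") != 1:
            raise ValueError(f"{path}: unsupported or missing config version (expected 1)")
        for key in ("isoforms", "delta_g_solv"):
            if key not in raw:
                raise ValueError(f"{path}: missing required config key {key!r}")
        return cls(raw=raw, base_dir=path.parent)

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def schedule(self) -> LambdaSchedule:
        return LambdaSchedule(**self.raw.get("schedule", {}))

    @property
    def thresholds(self) -> QCThresholds:
        return QCThresholds(**self.raw.get("thresholds", {}))

    @property
    def rt(self) -> float:
        return float(self.raw.get("rt", RT_KCAL_MOL))


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path) -> Path:
    """Run all stages; returns the run directory.

    Any stage error aborts with :class:`PipelineStageError`; partial
    outputs are retained next to a ``FAILED`` marker naming the stage.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        schedule = config.schedule
        thresholds = config.thresholds
        rt = config.rt
        production_start = float(config.raw.get("production_start", 0.0))
        solv_value, solv_stderr = (float(v) for v in config.raw["delta_g_solv"])

        # ---- QC stage -------------------------------------------------
        stage = "qc"
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        chosen: dict[str, list[str]] = {}
        for isoform, iso_cfg in config.raw["isoforms"].items():
            reports = []
            for rep in iso_cfg.get("replicates", []):
                rep_id = str(rep["id"])
                traj = load_trajectory(
                    config.path(rep["topology"]),
                    selections={**_DEFAULT_SELECTIONS,
                                "hbond_triplets": rep.get("hbond_triplets", [])},
                )
                metrics = {
                    "com_displacement": com_displacement(traj),
                    "ligand_rmsd": ligand_rmsd(traj),
                    "lid_distance": lid_distance(traj),
                    "helix_angle": helix_angle(traj),
                }
                occupancy = None
                if traj.selections.get("hbond_triplets"):
                    hb_series, _, occ = hbond_metrics(
                        traj, thresholds.hbond_dist_max)
                    metrics["hbond_distance"] = hb_series[0]
                    occupancy = float(occ[0])
                report = evaluate_replicate(
                    metrics, thresholds, production_start,
                    replicate_id=f"{isoform}/{rep_id}",
                    hbond_occupancy=occupancy,
                )
                reports.append(report)
                pd.DataFrame(
                    {"time_ns": metrics["com_displacement"].frame_times}
                    | {name: m.values for name, m in metrics.items()}
                ).to_csv(qc_dir / f"{isoform}_{rep_id}_metrics.csv", index=False)
                (qc_dir / f"{isoform}_{rep_id}_report.json").write_text(
                    report.to_json() + "\n")
            if reports:
                stage = "selection"
                k = min(int(config.raw.get("select_k", len(reports))),
                        sum(r.overall for r in reports))
                if k < 1:
                    raise PipelineStageError(
                        "selection", f"{isoform}: no replicate passed QC")
                chosen[isoform] = rank_replicates(reports, k, thresholds)
                stage = "qc"
        (qc_dir / "chosen_replicates.json").write_text(
            json.dumps(chosen, sort_keys=True, indent=1) + "\n")

        # ---- FEP stage ------------------------------------------------
        stage = "fep"
        fep_dir = out / "fep"
        fep_dir.mkdir(exist_ok=True)
        pose_rows = []
        poses_by_isoform: dict[str, list[PoseEstimate]] = {}
        for isoform, iso_cfg in config.raw["isoforms"].items():
            pose_cfgs = iso_cfg.get("poses", [])
            if not pose_cfgs:
                raise PipelineStageError("fep", f"{isoform}: no fepout paths configured")
            for p, pose in enumerate(pose_cfgs, start=1):
                windows = parse_fepout(config.path(pose["fepout"]), schedule)
                est = total_free_energy(windows, rt=rt,
                                        schedule_n_windows=schedule.n_windows)
                pose_rows.append((isoform, p, est.delta_g, est.stderr))
                poses_by_isoform.setdefault(isoform, []).append(
                    PoseEstimate(isoform=isoform, pose_index=p,
                                 delta_g_protein=est.delta_g, stderr=est.stderr)
                )
                (fep_dir / f"{isoform}_pose{p}.json").write_text(json.dumps({
                    "isoform": isoform, "pose": p, "method": est.method,
                    "delta_g": est.delta_g, "stderr": est.stderr,
                    "per_window": [list(w) for w in est.per_window],
                }, sort_keys=True, indent=1) + "\n")
        pd.DataFrame(
            pose_rows, columns=["isoform", "pose", "delta_g_protein", "stderr"]
        ).to_csv(fep_dir / "poses.csv", index=False)

        # ---- decomposition stage --------------------------------------
        stage = "decomposition"
        dec_dir = out / "decomposition"
        dec_dir.mkdir(exist_ok=True)
        series_by_isoform = {}
        for isoform, iso_cfg in config.raw["isoforms"].items():
            if "pair_energies" in iso_cfg:
                series_by_isoform[isoform] = parse_pair_energies(
                    config.path(iso_cfg["pair_energies"]), schedule)
        if series_by_isoform:
            decomposition_table(series_by_isoform, rt=rt).to_csv(
                dec_dir / "per_residue.csv", index=False)

        # ---- summary stage --------------------------------------------
        stage = "summary"
        sum_dir = out / "summary"
        sum_dir.mkdir(exist_ok=True)
        summaries: list[IsoformSummary] = []
        for isoform, poses in sorted(poses_by_isoform.items()):
            summaries.append(isoform_binding_energy(poses, solv_value, solv_stderr))
        pd.DataFrame([
            {
                "isoform": s.isoform,
                "mean_delta_g_protein": round(s.mean_delta_g_protein, 3),
                "binding_delta_g": round(s.binding_delta_g, 3),
                "error": round(s.error, 3),
                "n_poses": s.n_poses,
            }
            for s in summaries
        ]).to_csv(sum_dir / "binding_free_energies.csv", index=False)
        if len(summaries) >= 2:
            ranked = rank_isoforms(summaries)
            pd.DataFrame([
                {"rank": i + 1, "isoform": s.isoform,
                 "binding_delta_g": round(s.binding_delta_g, 3),
                 "comparable_with": ",".join(sorted(comp))}
                for i, (s, comp) in enumerate(ranked)
            ]).to_csv(sum_dir / "ranking.csv", index=False)

        stage = "log"
        (out / "run_log.json").write_text(json.dumps({
            "package": "hcnfep",
            "version": __version__,
            "config_hash": _config_hash(config.raw),
            "seed": config.raw.get("seed"),
            "stages": ["qc", "selection", "fep", "decomposition", "summary"],
        }, sort_keys=True, indent=1) + "\n")
    except PipelineStageError:
        (out / "FAILED").write_text(stage + "\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(stage + "\n")
        raise PipelineStageError(stage, str(exc)) from exc
    return out


# ---------------------------------------------------------------------------
# synthetic bundle
# ---------------------------------------------------------------------------

def synthesize_inputs(
    out_dir: str | Path,
    seed: int = 0,
    isoforms: tuple[str, ...] = ("SYNA", "SYNB"),
    n_replicates: int = 3,
    n_poses: int = 2,
    n_frames: int = 40,
    n_samples_per_leg: int = 200,
    window_mu: float = 6.0,
    window_sigma: float = 0.8,
    delta_g_solv: float = 118.63,
    solv_stderr: float = 0.39,
    rt: float = RT_KCAL_MOL,
) -> tuple[Path, dict]:
    """Write a complete synthetic input bundle and its ground truth.

    Each isoform gets ``n_replicates`` toy trajectories (well-behaved
    ligand random walks), ``n_poses`` fepout files of Crooks-consistent
    Gaussian work (per-pose ground-truth totals recorded), and one
    pair-energy stream with a zero-variance closed-form ground truth.
    Returns (config path, ground-truth dict).
    """
    out = Path(out_dir)
    (out / "traj").mkdir(parents=True, exist_ok=True)
    (out / "fep").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    schedule = LambdaSchedule()
    truth: dict = {"poses": {}, "pair_dg": {}, "delta_g_solv": delta_g_solv}
    iso_cfgs = {}
    for iso_i, isoform in enumerate(isoforms):
        replicates = []
        for r in range(1, n_replicates + 1):
            spec = ToyTrajectorySpec(
                n_frames=n_frames,
                ligand_motion="random_walk",
                step_sigma=0.05,
                lid_schedule=7.0,
                helix_tilt_schedule=20.0,
                hbond_distance_schedule=2.8,
                hbond_deviation_schedule=5.0,
                seed=int(rng.integers(2**31)),
            )
            traj, _ = gen_toy_trajectory(spec)
            pdb = out / "traj" / f"{isoform}_rep{r}.pdb"
            write_trajectory_pdb(traj, pdb)
            triplet = [int(i) for i in traj.selections["hbond_triplets"][0]]
            replicates.append({
                "id": f"rep{r}",
                "topology": str(pdb.relative_to(out)),
                "hbond_triplets": [triplet],
            })
        poses = []
        for p in range(1, n_poses + 1):
            wspec = GaussianWorkSpec.uniform(
                mu=window_mu + 0.2 * iso_i,
                sigma=window_sigma,
                n_windows=schedule.n_windows,
                rt=rt,
                n_samples=n_samples_per_leg,
                seed=int(rng.integers(2**31)),
            )
            fwd, bwd, gt = gen_gaussian_work(wspec)
            fpath = out / "fep" / f"{isoform}_pose{p}.fepout"
            write_fepout([*fwd, *bwd], fpath)
            truth["poses"][f"{isoform}/pose{p}"] = gt
            poses.append({"id": f"pose{p}", "fepout": str(fpath.relative_to(out))})
        elec_means = rng.uniform(-3.0, 1.0, schedule.n_windows)
        vdw_means = rng.uniform(-2.0, 1.0, schedule.n_windows)
        series = gen_pair_energies(
            elec_means, vdw_means,
            samples_per_window=schedule.samples_per_window,
            residue_offset=47, rt=rt, seed=int(rng.integers(2**31)),
        )
        pair_path = out / f"{isoform}_pairs.csv"
        write_pair_energies([series], pair_path)
        truth["pair_dg"][isoform] = series.ground_truth_dg
        iso_cfgs[isoform] = {
            "replicates": replicates,
            "poses": poses,
            "pair_energies": str(pair_path.relative_to(out)),
        }
    config = {
        "version": 1,
        "seed": seed,
        "rt": rt,
        "delta_g_solv": [delta_g_solv, solv_stderr],
        "schedule": {},
        "thresholds": {},
        "production_start": 0.0,
        "select_k": min(2, n_replicates),
        "isoforms": iso_cfgs,
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    truth["binding"] = {
        iso: delta_g_solv - float(np.mean(
            [truth["poses"][f"{iso}/pose{p}"] for p in range(1, n_poses + 1)]
        ))
        for iso in isoforms
    }
    return config_path, truth
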