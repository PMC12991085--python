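"""Synthetic inputs with known ground truth.

Three generators stand in for the MD engine so the whole analysis runs
at desk scale:

* Crooks-consistent Gaussian work samples per λ window.  Forward work is
  drawn from N(μ, σ²) and backward (re-coupling) work from
  N(−μ + σ²/RT, σ²), which satisfies the Crooks fluctuation relation
  exactly in distribution with a per-window ground truth
  ΔG = μ − σ²/(2·RT).
* Gaussian per-residue energy streams; in zero-variance mode the
  decomposition has a closed form that is stored with the series.
* Toy CNBD-like trajectories: a rigid β-sheet Cα scaffold, two
  ideal-helix Cα rods at a scheduled relative tilt, a rigid multi-atom
  ligand following a motion model, a lid Cα pair following a distance
  schedule, and a donor–hydrogen–acceptor triplet following an H-bond
  geometry schedule.  The exact expected series for every metric is
  returned alongside the coordinates, so metric code is tested against
  construction, never against itself.

The geometry is deliberately minimal — no physics, no clash checking;
it exists to make the metric code falsifiable, not to look like a
protein.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .estimators import RT_KCAL_MOL
from .fep_io import LambdaSchedule, PairEnergySeries, WindowSamples
from .traj_metrics import MetricSeries, TrajectoryView, _helix_axis

__all__ = [
    "GaussianWorkSpec",
    "ToyTrajectorySpec",
    "gen_gaussian_work",
    "gen_pair_energies",
    "gen_toy_trajectory",
    "write_trajectory_pdb",
]


# ---------------------------------------------------------------------------
# Gaussian work
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianWorkSpec:
    """Per-window Gaussian work distributions with exact ground truth."""

    mu: tuple[float, ...]      # kcal/mol, one per window
    sigma: tuple[float, ...]   # kcal/mol, one per window (0 allowed: degenerate)
    rt: float = RT_KCAL_MOL
    n_samples: int = 100       # per leg per window
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))
        if len(self.mu) != len(self.sigma):
            raise ValueError("mu and sigma must have equal length")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.rt <= 0:
            raise ValueError("rt must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.mu)

    @property
    def per_window_ground_truth(self) -> np.ndarray:
        mu = np.array(self.mu)
        sig = np.array(self.sigma)
        return mu - sig * sig / (2.0 * self.rt)

    @property
    def ground_truth_total(self) -> float:
        return float(self.per_window_ground_truth.sum())

    @classmethod
    def uniform(cls, mu: float, sigma: float, n_windows: int = 20,
                rt: float = RT_KCAL_MOL, n_samples: int = 100,
                seed: int = 0) -> "GaussianWorkSpec":
        return cls(mu=(mu,) * n_windows, sigma=(sigma,) * n_windows,
                   rt=rt, n_samples=n_samples, seed=seed)


def gen_gaussian_work(
    spec: GaussianWorkSpec,
) -> tuple[list[WindowSamples], list[WindowSamples], float]:
    """Draw forward/backward window samples; returns (fwd, bwd, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    delta_lambda = 1.0 / spec.n_windows
    fwd: list[WindowSamples] = []
    bwd: list[WindowSamples] = []
    for i in range(spec.n_windows):
        mu, sig = spec.mu[i], spec.sigma[i]
        l0, l1 = i * delta_lambda, (i + 1) * delta_lambda
        wf = rng.normal(mu, sig, spec.n_samples) if sig > 0 else np.full(spec.n_samples, mu)
        mu_b = -mu + sig * sig / spec.rt
        wb = rng.normal(mu_b, sig, spec.n_samples) if sig > 0 else np.full(spec.n_samples, mu_b)
        fwd.append(WindowSamples(i + 1, l0, l1, wf, "forward"))
        bwd.append(WindowSamples(i + 1, l1, l0, wb, "backward"))
    return fwd, bwd, spec.ground_truth_total


# ---------------------------------------------------------------------------
# pair energies
# ---------------------------------------------------------------------------

def gen_pair_energies(
    elec_means: Sequence[float],
    vdw_means: Sequence[float],
    elec_sds: Sequence[float] | float = 0.0,
    vdw_sds: Sequence[float] | float = 0.0,
    samples_per_window: int = 25,
    residue_offset: int = 0,
    rt: float = RT_KCAL_MOL,
    seed: int = 0,
) -> PairEnergySeries:
    """Gaussian per-residue energy streams over the λ schedule.

    In zero-variance mode every window's equilibrium constant is
    exp(−s_i/RT) with s_i the scaled mean energy, so the decomposition
    ΔG equals Σ s_i exactly; that closed form is stored on the series as
    ``ground_truth_dg``.
    """
    from .decomposition import _scaled_energy  # avoid import cycle at module load

    n_windows = len(elec_means)
    if len(vdw_means) != n_windows:
        raise ValueError("elec_means and vdw_means must have equal length")
    e_sd = np.broadcast_to(np.asarray(elec_sds, dtype=float), (n_windows,))
    v_sd = np.broadcast_to(np.asarray(vdw_sds, dtype=float), (n_windows,))
    if np.any(e_sd < 0) or np.any(v_sd < 0):
        raise ValueError("negative variance requested")
    if samples_per_window < 1:
        raise ValueError("samples_per_window must be >= 1")
    rng = np.random.default_rng(seed)
    u_elec = np.empty((n_windows, samples_per_window))
    u_vdw = np.empty((n_windows, samples_per_window))
    for i in range(n_windows):
        u_elec[i] = rng.normal(elec_means[i], e_sd[i], samples_per_window) \
            if e_sd[i] > 0 else elec_means[i]
        u_vdw[i] = rng.normal(vdw_means[i], v_sd[i], samples_per_window) \
            if v_sd[i] > 0 else vdw_means[i]
    gt = None
    if np.all(e_sd == 0) and np.all(v_sd == 0):
        gt = float(sum(
            float(_scaled_energy(np.array([elec_means[i]]), np.array([vdw_means[i]]), i + 1)[0])
            for i in range(n_windows)
        ))
    return PairEnergySeries(
        residue_offset=residue_offset,
        u_elec=u_elec,
        u_vdw=u_vdw,
        n_windows=n_windows,
        ground_truth_dg=gt,
    )


# ---------------------------------------------------------------------------
# toy trajectory
# ---------------------------------------------------------------------------

def _resolve_schedule(value, n_frames: int, name: str) -> np.ndarray:
    """Scalar → constant series; (start, end) → linear ramp; array → as-is."""
    if np.isscalar(value):
        return np.full(n_frames, float(value))
    arr = np.asarray(value, dtype=float)
    if arr.shape == (2,):
        return np.linspace(arr[0], arr[1], n_frames)
    if arr.shape != (n_frames,):
        raise ValueError(
            f"{name}: schedule length {arr.shape} inconsistent with n_frames={n_frames}"
        )
    return arr


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Construction plan for a toy CNBD-like trajectory.

    Schedules accept a scalar (constant), a (start, end) pair (linear
    ramp over frames), or a length-``n_frames`` array.
    """

    n_frames: int = 50
    ligand_motion: str = "static"           # static | linear | random_walk
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Å/frame, linear mode
    step_sigma: float = 0.1                  # Å, random-walk mode
    lid_schedule: object = 7.0               # Å
    helix_tilt_schedule: object = 0.0        # degrees
    hbond_distance_schedule: object = 2.8    # Å (donor–acceptor)
    hbond_deviation_schedule: object = 5.0   # degrees from linearity
    frame_dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.ligand_motion not in ("static", "linear", "random_walk"):
            raise ValueError(f"unknown ligand motion model {self.ligand_motion!r}")


def _ideal_helix(n_res: int = 18, radius: float = 2.3, rise: float = 1.5,
                 twist_deg: float = 100.0) -> np.ndarray:
    """Cα positions of an ideal α-helix along z, centred at the origin."""
    k = np.arange(n_res)
    theta = np.radians(twist_deg) * k
    pts = np.stack([radius * np.cos(theta), radius * np.sin(theta), rise * k], axis=1)
    return pts - pts.mean(axis=0)


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle_rad).as_matrix()


def gen_toy_trajectory(
    spec: ToyTrajectorySpec,
) -> tuple[TrajectoryView, dict[str, MetricSeries]]:
    """Build the toy system and the exact expected series for every metric.

    The β-sheet scaffold is rigid, so superposition onto it is the
    identity and the scheduled ligand/lid/helix/H-bond ground truths hold
    exactly for the metric definitions in :mod:`hcnfep.traj_metrics`.
    """
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)
    times = np.arange(n) * spec.frame_dt_ns

    lid = _resolve_schedule(spec.lid_schedule, n, "lid_schedule")
    tilt = _resolve_schedule(spec.helix_tilt_schedule, n, "helix_tilt_schedule")
    hb_dist = _resolve_schedule(spec.hbond_distance_schedule, n, "hbond_distance_schedule")
    hb_dev = _resolve_schedule(spec.hbond_deviation_schedule, n, "hbond_deviation_schedule")

    # rigid β-sheet scaffold: 4 strands × 5 Cα in the z=0 plane
    sx, sy = np.meshgrid(np.arange(5) * 3.5, np.arange(4) * 4.8)
    sheet = np.stack([sx.ravel(), sy.ravel(), np.zeros(20)], axis=1)

    helix_template = _ideal_helix()
    axis0 = _helix_axis(helix_template)  # template's actual inertia axis
    # tilt axis exactly perpendicular to the template axis so the angle
    # between the two inertia axes equals the scheduled tilt exactly
    perp = np.array([0.0, 1.0, 0.0]) - axis0 * axis0[1]
    perp /= np.linalg.norm(perp)
    helix_b0 = helix_template + np.array([18.0, 0.0, 10.0])

    # rigid 5-atom ligand cluster (plus-sign shape)
    lig_local = np.array([
        [0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [-1.2, 0.0, 0.0],
        [0.0, 1.2, 0.0], [0.0, 0.0, 1.2],
    ])
    lig_start = np.array([6.0, 7.0, 5.0])
    if spec.ligand_motion == "static":
        centres = np.tile(lig_start, (n, 1))
    elif spec.ligand_motion == "linear":
        centres = lig_start + np.outer(np.arange(n), np.asarray(spec.drift, dtype=float))
    else:  # random walk
        steps = rng.normal(0.0, spec.step_sigma, (n, 3))
        steps[0] = 0.0
        centres = lig_start + np.cumsum(steps, axis=0)
    com_truth = np.linalg.norm(centres - centres[0], axis=1)

    frames = []
    for f in range(n):
        helix_c = helix_template @ _rotation_about(perp, np.radians(tilt[f])).T \
            + np.array([30.0, 0.0, 10.0])
        lid_pair = np.array([[-10.0, 0.0, 0.0], [-10.0, 0.0, lid[f]]])
        # D–H–A triplet: D at origin-offset, H 1 Å along +x; A placed so the
        # D–A distance and the deviation of D–H–A from 180° match the schedule
        dev = np.radians(hb_dev[f])
        d_da = hb_dist[f]
        r = -np.cos(dev) + np.sqrt(np.cos(dev) ** 2 - 1.0 + d_da ** 2)
        dpos = np.array([45.0, 0.0, 0.0])
        hpos = dpos + np.array([1.0, 0.0, 0.0])
        apos = hpos + r * np.array([np.cos(dev), np.sin(dev), 0.0])
        ligand = lig_local + centres[f]
        frames.append(np.concatenate([
            sheet, helix_b0, helix_c, ligand, lid_pair,
            dpos[None], hpos[None], apos[None],
        ]))
    coords = np.stack(frames)

    n_sheet, n_helix, n_lig = 20, len(helix_template), len(lig_local)
    i0 = 0
    sheet_idx = np.arange(i0, i0 + n_sheet); i0 += n_sheet
    hb_idx = np.arange(i0, i0 + n_helix); i0 += n_helix
    hc_idx = np.arange(i0, i0 + n_helix); i0 += n_helix
    lig_idx = np.arange(i0, i0 + n_lig); i0 += n_lig
    lid_idx = np.arange(i0, i0 + 2); i0 += 2
    dha = (i0, i0 + 1, i0 + 2); i0 += 3

    traj = TrajectoryView(
        coordinates=coords,
        selections={
            "ligand": lig_idx,
            "sheet_ca": sheet_idx,
            "helixB_ca": hb_idx,
            "helixC_ca": hc_idx,
            "lid_pair": lid_idx,
            "hbond_triplets": [dha],
        },
        frame_times=times,
    )
    tilt_folded = np.minimum(np.abs(tilt), 180.0 - np.abs(tilt))
    truth = {
        "com_displacement": MetricSeries("com_displacement", com_truth, times),
        "ligand_rmsd": MetricSeries("ligand_rmsd", com_truth.copy(), times),
        "lid_distance": MetricSeries("lid_distance", np.abs(lid), times),
        "helix_angle": MetricSeries("helix_angle", tilt_folded, times),
        "hbond_distance": MetricSeries("hbond_distance", hb_dist, times),
        "hbond_deviation": MetricSeries("hbond_deviation", hb_dev, times),
    }
    return traj, truth


_SEGMENTS = (
    ("sheet_ca", "SHE", "GLY"),
    ("helixB_ca", "HXB", "ALA"),
    ("helixC_ca", "HXC", "ALA"),
    ("ligand", "LIG", "CMP"),
    ("lid_pair", "LID", "GLY"),
)


def write_trajectory_pdb(traj: TrajectoryView, path: str | Path) -> None:
    """Write a toy trajectory as a multi-model PDB with segment labels.

    Atoms are emitted in coordinate order; selections are encoded via
    segid (SHE/HXB/HXC/LID/HBD) and resname (CMP for the ligand) so a
    round trip through :func:`hcnfep.traj_metrics.load_trajectory` can
    rebuild the named selections with standard selection strings.
    """
    n_atoms = traj.coordinates.shape[1]
    seg = ["UNK"] * n_atoms
    resname = ["UNK"] * n_atoms
    name = ["CA"] * n_atoms
    for sel_name, segid, rn in _SEGMENTS:
        for i in traj.selections.get(sel_name, []):
            seg[int(i)] = segid
            resname[int(i)] = rn
    for t, triplet in enumerate(traj.selections.get("hbond_triplets", [])):
        for j, atom_name in zip(triplet, ("D", "H", "A")):
            seg[int(j)] = "HBD"
            resname[int(j)] = "HBT"
            name[int(j)] = atom_name
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(n_atoms):
                x, y, z = traj.coordinates[f, a]
                fh.write(
                    f"ATOM  {a + 1:5d} {name[a]:>4s} {resname[a]:>3s} A{a + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
                    f"{seg[a]:<4s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
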