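"""Trajectory quality-control metrics for ligand-bound CNBD replicates.

Five per-frame metrics are computed from a trajectory with named atom
selections:

* ligand centre-of-mass displacement after β-sheet Cα superposition,
* ligand all-atom RMSD after the same superposition (no re-fitting on
  the ligand itself),
* "lid distance" — the Cα–Cα distance between a β-jelly-roll loop
  residue and a residue in the C/D-helix turn, a proxy for C-helix
  closure over the bound nucleotide,
* the angle between the principal (long) axes of helices B and C,
  obtained from the inertia tensor of their Cα atoms,
* donor–acceptor distance and D–H–A linearity for hydrogen-bond
  triplets, with occupancy under a 3.0 Å / 20° criterion.

Superposition uses the Kabsch algorithm on the β-sheet Cα set so that
drift of the whole domain is not counted as ligand motion.  Lid
distance, helix angle and H-bond geometry are frame-internal and need
no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TrajectoryView",
    "MetricSeries",
    "kabsch_superpose",
    "ligand_rmsd",
    "com_displacement",
    "lid_distance",
    "helix_angle",
    "hbond_metrics",
    "load_trajectory",
]


@dataclass
class TrajectoryView:
    """Topology-light view of a trajectory: coordinates plus named selections.

    ``coordinates`` is (n_frames, n_atoms, 3) in Å.  ``selections`` maps
    selection names (``ligand``, ``sheet_ca``, ``helixB_ca``,
    ``helixC_ca``, ``lid_pair``, ``hbond_triplets``) to atom-index
    arrays; ``hbond_triplets`` is a sequence of (donor, hydrogen,
    acceptor) index triples.  ``masses`` defaults to unit masses.
    """

    coordinates: np.ndarray
    selections: dict = field(default_factory=dict)
    frame_times: np.ndarray | None = None  # ns
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        n_atoms = self.coordinates.shape[1]
        for name, sel in self.selections.items():
            idx = np.asarray(sel).ravel()
            if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
                raise ValueError(f"selection {name!r} has out-of-range atom indices")
        lid = self.selections.get("lid_pair")
        if lid is not None and len(np.asarray(lid).ravel()) != 2:
            raise ValueError("lid_pair must contain exactly 2 atoms")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.masses is None:
            self.masses = np.ones(n_atoms)
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    def sel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.selections[name], dtype=int)
        except KeyError:
            raise KeyError(f"trajectory has no selection {name!r}") from None


@dataclass(frozen=True)
class MetricSeries:
    """One per-frame scalar metric (Å or degrees)."""

    metric: str
    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times length mismatch")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t, rmsd) with the proper rotation
    (det +1) minimising RMSD; apply as ``x @ R.T + t``.  The smallest
    singular direction's sign is flipped when the raw SVD solution is a
    reflection.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - mc, ref - rc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # rank-deficient (collinear) configurations have no unique rotation
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear or rank-deficient) atom configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    resid = p @ rot.T - q
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return rot, trans, rmsd


def _superpose_frames(traj: TrajectoryView, reference_frame: int) -> np.ndarray:
    """All frames rigidly fitted onto the reference frame via sheet Cα."""
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(
            f"reference_frame {reference_frame} outside [0, {traj.n_frames})"
        )
    sheet = traj.sel("sheet_ca")
    if sheet.size == 0:
        raise ValueError("empty sheet_ca selection")
    ref = traj.coordinates[reference_frame][sheet]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coordinates[f][sheet], ref)
        out[f] = traj.coordinates[f] @ rot.T + trans
    return out


def ligand_rmsd(traj: TrajectoryView, reference_frame: int = 0) -> MetricSeries:
    """All-atom ligand RMSD per frame after β-sheet Cα superposition.

    The ligand atoms themselves are not re-fitted, so the series reports
    genuine ligand motion relative to the β-jelly roll.
    """
    lig = traj.sel("ligand")
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    fitted = _superpose_frames(traj, reference_frame)
    ref = fitted[reference_frame][lig]
    diff = fitted[:, lig, :] - ref
    vals = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return MetricSeries("ligand_rmsd", vals, traj.frame_times)


def com_displacement(
    traj: TrajectoryView, reference_frame: int = 0, aligned: bool = True
) -> MetricSeries:
    """Distance of the ligand centre of mass from its starting position.

    With ``aligned`` (default) frames are first superposed on the β-sheet
    Cα set; with ``aligned=False`` raw coordinates are used.
    """
    lig = traj.sel("ligand")
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    w = traj.masses[lig]
    if w.sum() <= 0:
        raise ValueError("zero total ligand mass")
    coords = _superpose_frames(traj, reference_frame) if aligned else traj.coordinates
    if not aligned and not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference_frame {reference_frame} outside [0, {traj.n_frames})")
    com = np.einsum("fai,a->fi", coords[:, lig, :], w) / w.sum()
    vals = np.linalg.norm(com - com[reference_frame], axis=1)
    return MetricSeries("com_displacement", vals, traj.frame_times)


def lid_distance(traj: TrajectoryView) -> MetricSeries:
    """Per-frame Cα–Cα distance of the lid residue pair (no alignment)."""
    pair = traj.sel("lid_pair")
    a, b = traj.coordinates[:, pair[0], :], traj.coordinates[:, pair[1], :]
    return MetricSeries("lid_distance", np.linalg.norm(a - b, axis=1), traj.frame_times)


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Long axis of a helix from the inertia tensor of unit-mass Cα atoms.

    The smallest-moment eigenvector is the long axis; it is oriented from
    the first toward the last Cα by sequence.
    """
    if ca.shape[0] < 3:
        raise ValueError("helix selection needs >= 3 atoms")
    x = ca - ca.mean(axis=0)
    r2 = np.sum(x * x, axis=1)
    inertia = np.eye(3) * r2.sum() - x.T @ x
    evals, evecs = np.linalg.eigh(inertia)
    scale = max(abs(evals[-1]), 1e-300)
    if abs(evals[1] - evals[0]) <= 1e-9 * scale:
        raise ValueError("degenerate inertia tensor: smallest moment not unique")
    axis = evecs[:, 0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def helix_angle(traj: TrajectoryView, signed: bool = False) -> MetricSeries:
    """Per-frame angle between the principal axes of helices B and C.

    By default the angle is folded to [0°, 90°] via the absolute dot
    product; ``signed=True`` returns the full [0°, 180°] angle between
    the sequence-oriented axes.
    """
    hb, hc = traj.sel("helixB_ca"), traj.sel("helixC_ca")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            axis_b = _helix_axis(traj.coordinates[f][hb])
            axis_c = _helix_axis(traj.coordinates[f][hc])
        except ValueError as exc:
            raise ValueError(f"frame {f}: {exc}") from None
        dot = float(np.clip(np.dot(axis_b, axis_c), -1.0, 1.0))
        vals[f] = np.degrees(np.arccos(dot if signed else abs(dot)))
    return MetricSeries("helix_angle", vals, traj.frame_times)


def hbond_metrics(
    traj: TrajectoryView,
    dist_cutoff: float = 3.0,
    angle_cutoff: float = 20.0,
) -> tuple[list[MetricSeries], np.ndarray, np.ndarray]:
    """Hydrogen-bond geometry for every (donor, hydrogen, acceptor) triplet.

    A bond is present in a frame iff the donor–acceptor distance is
    ≤ ``dist_cutoff`` AND the deviation of the D–H–A angle from
    linearity (180°) is ≤ ``angle_cutoff`` — the angle convention of the
    common trajectory-viewer H-bond tools.

    Returns (per-triplet donor–acceptor distance series,
    present flags of shape (n_triplets, n_frames), per-triplet occupancy).
    """
    triplets = traj.selections.get("hbond_triplets")
    if not triplets:
        raise ValueError("no hbond_triplets selection")
    series: list[MetricSeries] = []
    flags = np.zeros((len(triplets), traj.n_frames), dtype=bool)
    for t, (d, h, a) in enumerate(triplets):
        if len({int(d), int(h), int(a)}) != 3:
            raise ValueError(f"triplet {t}: overlapping atom indices ({d}, {h}, {a})")
        dpos = traj.coordinates[:, int(d), :]
        hpos = traj.coordinates[:, int(h), :]
        apos = traj.coordinates[:, int(a), :]
        da = np.linalg.norm(dpos - apos, axis=1)
        v1 = dpos - hpos
        v2 = apos - hpos
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        deviation = 180.0 - angle
        flags[t] = (da <= dist_cutoff) & (deviation <= angle_cutoff)
        series.append(MetricSeries("hbond_distance", da, traj.frame_times))
    occupancy = flags.mean(axis=1)
    return series, flags, occupancy


def load_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    selections: Mapping[str, str] | None = None,
    frame_dt_ns: float = 1.0,
) -> TrajectoryView:
    """Build a :class:`TrajectoryView` from standard structure files.

    ``topology`` is a PDB (a multi-model PDB alone also provides the
    frames); ``trajectory`` may add a DCD or similar coordinate file.
    ``selections`` maps the metric selection names to MDAnalysis
    selection strings, e.g. ``{"ligand": "resname CMP", "sheet_ca":
    "name CA and segid SHEE"}``; ``hbond_triplets`` may instead be given
    directly as index triples.  Masses are taken from the topology when
    it provides them, else unit masses are used.
    """
    import MDAnalysis as mda

    uni = (
        mda.Universe(str(topology), str(trajectory))
        if trajectory is not None
        else mda.Universe(str(topology))
    )
    sel_idx: dict[str, object] = {}
    for name, spec in (selections or {}).items():
        if name == "hbond_triplets" and not isinstance(spec, str):
            sel_idx[name] = [tuple(int(i) for i in t) for t in spec]
        else:
            sel_idx[name] = uni.select_atoms(spec).ix.copy()
    coords = np.stack([uni.atoms.positions.copy() for _ in uni.trajectory])
    try:
        masses = uni.atoms.masses.copy()
        if not np.all(masses > 0):
            masses = None
    except mda.exceptions.NoDataError:
        masses = None
    return TrajectoryView(
        coordinates=coords,
        selections=sel_idx,
        frame_times=np.arange(len(coords)) * frame_dt_ns,
        masses=masses,
    )
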