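"""Isoform-level aggregation of pose free energies and the residue-offset map.

The binding free energy of cAMP to one CNBD isoform is reported as
ΔG_solv − ⟨ΔG_protein⟩: the decoupling free energy of the ligand in
water minus the mean decoupling free energy over the isoform's FEP
poses (more negative = tighter binding).  No standard-state or
restraint corrections are applied.

Because the four CNBDs are highly homologous but numbered differently,
homologous positions are referenced by their "residue offset" — the
sequence distance from the first considered binding-site residue — via
a packaged offset → (HCN1, HCN2, HCN3, HCN4) residue-label map.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DELTA_G_SOLV_CAMP",
    "DELTA_G_SOLV_CAMP_STDERR",
    "ISOFORMS",
    "PoseEstimate",
    "IsoformSummary",
    "ResidueOffsetMap",
    "load_residue_offset_map",
    "isoform_binding_energy",
    "rank_isoforms",
    "offset_to_residues",
]

#: Decoupling free energy of cAMP in water (kcal/mol), from a ligand-only leg.
DELTA_G_SOLV_CAMP = 118.63
DELTA_G_SOLV_CAMP_STDERR = 0.39

ISOFORMS = ("HCN1", "HCN2", "HCN3", "HCN4")


@dataclass(frozen=True)
class PoseEstimate:
    """Protein-leg decoupling ΔG for one FEP pose of one isoform."""

    isoform: str
    pose_index: int
    delta_g_protein: float  # kcal/mol
    stderr: float = 0.0
    n_trajectories: int = 5

    def __post_init__(self) -> None:
        if not self.isoform:
            raise ValueError("isoform label must be non-empty")
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")


@dataclass(frozen=True)
class IsoformSummary:
    """Aggregated binding free energy for one isoform."""

    isoform: str
    mean_delta_g_protein: float
    binding_delta_g: float  # ΔG_solv − mean ΔG_protein
    error: float
    n_poses: int
    delta_g_solv: float = DELTA_G_SOLV_CAMP

    def __post_init__(self) -> None:
        expected = self.delta_g_solv - self.mean_delta_g_protein
        if abs(expected - self.binding_delta_g) > 1e-9:
            raise ValueError(
                f"binding_delta_g {self.binding_delta_g} != "
                f"delta_g_solv − mean_delta_g_protein = {expected}"
            )


def isoform_binding_energy(
    poses: Sequence[PoseEstimate],
    delta_g_solv: float = DELTA_G_SOLV_CAMP,
    solv_stderr: float = DELTA_G_SOLV_CAMP_STDERR,
) -> IsoformSummary:
    """ΔG_solv − mean(pose ΔG_protein) with a quadrature-combined error.

    The error is the sample standard deviation (ddof=1) of the pose
    values combined in quadrature with the solvation-leg stderr — a
    transparent convention; it is not claimed to reproduce any
    particular published error recipe.
    """
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    isoforms = {p.isoform for p in poses}
    if len(isoforms) != 1:
        raise ValueError(f"mixed isoforms in pose list: {sorted(isoforms)}")
    vals = np.array([p.delta_g_protein for p in poses], dtype=float)
    mean = float(vals.mean())
    spread = float(vals.std(ddof=1))
    return IsoformSummary(
        isoform=poses[0].isoform,
        mean_delta_g_protein=mean,
        binding_delta_g=delta_g_solv - mean,
        error=float(np.hypot(spread, solv_stderr)),
        n_poses=len(poses),
        delta_g_solv=delta_g_solv,
    )


def rank_isoforms(
    summaries: Sequence[IsoformSummary],
) -> list[tuple[IsoformSummary, frozenset[str]]]:
    """Order isoforms by affinity (most negative binding ΔG first).

    Each entry carries the set of other isoforms whose binding ΔG is
    within the two summaries' quadrature-combined errors — "comparable"
    affinities that the error bars cannot separate.  The sort is stable,
    so equal values keep input order.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to rank")
    ordered = sorted(summaries, key=lambda s: s.binding_delta_g)
    out = []
    for s in ordered:
        comparable = frozenset(
            o.isoform for o in summaries
            if o is not s
            and abs(o.binding_delta_g - s.binding_delta_g) <= float(np.hypot(o.error, s.error))
        )
        out.append((s, comparable))
    return out


# ---------------------------------------------------------------------------
# residue-offset map
# ---------------------------------------------------------------------------

class ResidueOffsetMap:
    """offset → per-isoform residue labels (letter + sequence number)."""

    def __init__(self, table: pd.DataFrame):
        required = ["offset", *ISOFORMS]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"offset map missing columns {missing}")
        if table["offset"].duplicated().any():
            raise ValueError("duplicate offsets in residue map")
        self._table = table.set_index("offset")[list(ISOFORMS)]

    @property
    def offsets(self) -> list[int]:
        return [int(o) for o in self._table.index]

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, offset: int) -> bool:
        return int(offset) in self._table.index

    def residues(self, offset: int) -> dict[str, str]:
        if int(offset) not in self._table.index:
            raise KeyError(
                f"offset {offset:+d} not in map; valid offsets: {self.offsets}"
            )
        row = self._table.loc[int(offset)]
        return {iso: str(row[iso]) for iso in ISOFORMS}

    def as_frame(self) -> pd.DataFrame:
        return self._table.reset_index()


def load_residue_offset_map() -> ResidueOffsetMap:
    """The packaged 27-row offset map (+0 … +90) across HCN1–4."""
    with resources.files("hcnfep.data").joinpath("residue_offsets.csv").open() as fh:
        return ResidueOffsetMap(pd.read_csv(fh))


def offset_to_residues(offset: int, offset_map: ResidueOffsetMap | None = None) -> dict[str, str]:
    """Residue labels of all four isoforms at one offset."""
    if offset_map is None:
        offset_map = load_residue_offset_map()
    return offset_map.residues(offset)
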