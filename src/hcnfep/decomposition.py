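"""Per-residue interaction free-energy decomposition.

The alchemical transformation is treated as an equilibrium between the
fully coupled and fully annihilated ligand states.  For each λ window an
equilibrium constant K is formed as an average of exponentials of the
scaled residue–ligand interaction energy; because electrostatics are
fully decoupled by λ = 0.5, the electrostatic term contributes only in
the first half of the schedule:

    window i ≤ 10:  K_i = ⟨exp(−(U_elec·0.1 + U_vdw·0.05)/RT)⟩
    window i ≥ 11:  K_i = ⟨exp(−(U_vdw·0.05)/RT)⟩

and the residue's relative interaction free energy is

    ΔG = −RT · Σ_{i=1..20} ln K_i   (kcal/mol).

The scale factors 0.1 and 0.05 are fixed constants of the decomposition,
not per-window λ values.  This is an approximation for ranking residue
contributions, not a rigorous free-energy partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .estimators import RT_KCAL_MOL
from .fep_io import PairEnergySeries

__all__ = [
    "ELEC_SCALE",
    "VDW_SCALE",
    "ResidueContribution",
    "window_equilibrium_constant",
    "residue_interaction_free_energy",
    "decomposition_table",
]

#: Fixed scale factor applied to the electrostatic term in windows 1–10.
ELEC_SCALE = 0.1
#: Fixed scale factor applied to the van der Waals term in every window.
VDW_SCALE = 0.05
#: First window with electrostatics fully decoupled (1-based).
_ELEC_OFF_WINDOW = 11
_N_WINDOWS = 20


@dataclass(frozen=True)
class ResidueContribution:
    """One residue's interaction free energy and its per-window log-constants."""

    residue_offset: int
    per_window_ln_k: tuple[float, ...]
    delta_g_contrib: float
    rt: float

    def __post_init__(self) -> None:
        expected = -self.rt * sum(self.per_window_ln_k)
        if abs(expected - self.delta_g_contrib) > 1e-9:
            raise ValueError(
                f"delta_g_contrib {self.delta_g_contrib} inconsistent with "
                f"−rt·Σ ln K = {expected}"
            )


def _scaled_energy(u_elec: np.ndarray, u_vdw: np.ndarray, window_index: int) -> np.ndarray:
    if window_index < _ELEC_OFF_WINDOW:
        return u_elec * ELEC_SCALE + u_vdw * VDW_SCALE
    return u_vdw * VDW_SCALE


def window_equilibrium_constant(
    u_elec: Sequence[float],
    u_vdw: Sequence[float],
    window_index: int,
    rt: float = RT_KCAL_MOL,
) -> float:
    """Equilibrium constant K for one window (overflow-safe).

    ``window_index`` is 1-based; windows 1–10 use the electrostatic and
    van der Waals terms, windows 11–20 the van der Waals term alone.
    """
    return float(np.exp(log_window_equilibrium_constant(u_elec, u_vdw, window_index, rt)))


def log_window_equilibrium_constant(
    u_elec: Sequence[float],
    u_vdw: Sequence[float],
    window_index: int,
    rt: float = RT_KCAL_MOL,
) -> float:
    """ln K for one window, computed via log-sum-exp so huge |U| cannot overflow."""
    if not 1 <= window_index <= _N_WINDOWS:
        raise ValueError(f"window_index {window_index} outside [1, {_N_WINDOWS}]")
    if rt <= 0:
        raise ValueError("rt must be positive")
    ue = np.asarray(u_elec, dtype=float)
    uv = np.asarray(u_vdw, dtype=float)
    if ue.size == 0 or uv.size == 0:
        raise ValueError("empty energy sample list")
    if ue.shape != uv.shape:
        raise ValueError(f"length mismatch: {ue.shape} vs {uv.shape}")
    if not (np.all(np.isfinite(ue)) and np.all(np.isfinite(uv))):
        raise ValueError("non-finite energy sample")
    s = _scaled_energy(ue, uv, window_index)
    return float(logsumexp(-s / rt) - np.log(s.size))


def residue_interaction_free_energy(
    series: PairEnergySeries, rt: float = RT_KCAL_MOL
) -> ResidueContribution:
    """ΔG = −RT·Σ ln K over the 20-window schedule for one residue."""
    if series.n_windows != _N_WINDOWS:
        raise ValueError(
            f"residue {series.residue_offset:+d}: expected {_N_WINDOWS} windows, "
            f"got {series.n_windows}"
        )
    ln_k = [
        log_window_equilibrium_constant(series.u_elec[i], series.u_vdw[i], i + 1, rt)
        for i in range(series.n_windows)
    ]
    if not all(np.isfinite(v) for v in ln_k):
        raise ValueError(f"residue {series.residue_offset:+d}: non-finite ln K")
    ln_k = tuple(float(v) for v in ln_k)
    return ResidueContribution(
        residue_offset=series.residue_offset,
        per_window_ln_k=ln_k,
        delta_g_contrib=-rt * sum(ln_k),
        rt=rt,
    )


def decomposition_table(
    series_by_isoform: Mapping[str, Sequence[PairEnergySeries]],
    rt: float = RT_KCAL_MOL,
) -> pd.DataFrame:
    """Long-form per-residue contribution table across isoforms.

    Columns: isoform, residue_offset, delta_g_contrib, strongest (True on
    the most negative — most favourable — contribution of each isoform).
    Sorted by residue_offset then isoform.
    """
    if not series_by_isoform:
        raise ValueError("no isoforms provided")
    rows = []
    for isoform, series_list in series_by_isoform.items():
        if not series_list:
            raise ValueError(f"isoform {isoform}: no residues")
        seen: set[int] = set()
        for s in series_list:
            if s.residue_offset in seen:
                raise ValueError(
                    f"duplicate (isoform, offset) = ({isoform}, {s.residue_offset:+d})"
                )
            seen.add(s.residue_offset)
            contrib = residue_interaction_free_energy(s, rt)
            rows.append((isoform, s.residue_offset, contrib.delta_g_contrib))
    df = pd.DataFrame(rows, columns=["isoform", "residue_offset", "delta_g_contrib"])
    df["strongest"] = False
    for isoform, grp in df.groupby("isoform"):
        df.loc[grp["delta_g_contrib"].idxmin(), "strongest"] = True
    return df.sort_values(["residue_offset", "isoform"]).reset_index(drop=True)
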