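"""Reading and writing alchemical energy-difference data.

Two text formats are handled here:

* A ``fepout``-style dialect carrying the per-window ΔU samples of a
  free-energy perturbation run (one sample per line, forward and backward
  legs).  The dialect is documented in ``docs/fepout_dialect.md`` and a
  writer is provided so fixtures are always self-generated and round-trip
  tested.
* A CSV pair-interaction log with per-residue electrostatic and van der
  Waals potential energies sampled along the same λ windows, feeding the
  per-residue decomposition.

Energies are kcal/mol throughout; no unit conversion happens in parsers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LambdaSchedule",
    "WindowSamples",
    "PairEnergySeries",
    "FepParseError",
    "ScheduleMismatchError",
    "parse_fepout",
    "write_fepout",
    "parse_pair_energies",
    "write_pair_energies",
    "pair_legs",
]


class FepParseError(ValueError):
    """A malformed line or structural problem in an input file."""


class ScheduleMismatchError(ValueError):
    """File contents disagree with the declared λ schedule."""


@dataclass(frozen=True)
class LambdaSchedule:
    """The λ-window protocol of one alchemical leg.

    The default mirrors a 20-window annihilation with Δλ = 0.05 per
    window, electrostatics fully decoupled by λ = 0.5, 10 ps of alchemical
    equilibration followed by 115 ps of sampling per window, and 25
    pair-interaction samples per window.
    """

    n_windows: int = 20
    delta_lambda: float = 0.05
    elec_off_lambda: float = 0.5
    equil_time_per_window: float = 10.0
    sample_time_per_window: float = 115.0
    samples_per_window: int = 25

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if abs(self.n_windows * self.delta_lambda - 1.0) > 1e-9:
            raise ValueError(
                f"n_windows * delta_lambda must equal 1: "
                f"{self.n_windows} * {self.delta_lambda} = "
                f"{self.n_windows * self.delta_lambda}"
            )
        if not (0.0 < self.elec_off_lambda <= 1.0):
            raise ValueError("elec_off_lambda must lie in (0, 1]")
        if self.samples_per_window < 1:
            raise ValueError("samples_per_window must be >= 1")

    def lambda_pair(self, window_index: int, leg: str = "forward") -> tuple[float, float]:
        """(λ_start, λ_end) of a 1-based window for the given leg."""
        if not 1 <= window_index <= self.n_windows:
            raise ValueError(f"window_index {window_index} outside [1, {self.n_windows}]")
        lo = (window_index - 1) * self.delta_lambda
        hi = window_index * self.delta_lambda
        if leg == "forward":
            return (lo, hi)
        if leg == "backward":
            return (hi, lo)
        raise ValueError(f"unknown leg {leg!r}")

    @property
    def elec_windows(self) -> int:
        """Number of leading windows during which electrostatics still scale."""
        return int(round(self.elec_off_lambda / self.delta_lambda))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LambdaSchedule":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class WindowSamples:
    """ΔU samples for one λ window of one leg, in kcal/mol."""

    window_index: int
    lambda_start: float
    lambda_end: float
    delta_u: np.ndarray
    leg: str
    n_equilibration_discarded: int = 0

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, dtype=float)
        if self.leg not in ("forward", "backward"):
            raise ValueError(f"leg must be 'forward' or 'backward', got {self.leg!r}")
        if self.delta_u.size == 0:
            raise ValueError(f"window {self.window_index} ({self.leg}): no samples")
        if not np.all(np.isfinite(self.delta_u)):
            raise ValueError(f"window {self.window_index} ({self.leg}): non-finite ΔU")

    @property
    def n_samples(self) -> int:
        return int(self.delta_u.size)

    @property
    def lambda_pair(self) -> tuple[float, float]:
        """Unordered λ pair, rounded for matching across legs."""
        return tuple(sorted((round(self.lambda_start, 9), round(self.lambda_end, 9))))


@dataclass
class PairEnergySeries:
    """Per-residue interaction energies sampled along the λ schedule.

    ``u_elec`` and ``u_vdw`` are (n_windows, samples_per_window) arrays of
    electrostatic and van der Waals potential energies (kcal/mol) between
    one residue and the transitioning ligand.
    """

    residue_offset: int
    u_elec: np.ndarray
    u_vdw: np.ndarray
    n_windows: int
    ground_truth_dg: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.u_elec = np.atleast_2d(np.asarray(self.u_elec, dtype=float))
        self.u_vdw = np.atleast_2d(np.asarray(self.u_vdw, dtype=float))
        if self.u_elec.shape != self.u_vdw.shape:
            raise ValueError(
                f"residue {self.residue_offset:+d}: u_elec shape {self.u_elec.shape} "
                f"!= u_vdw shape {self.u_vdw.shape}"
            )
        if self.u_elec.shape[0] != self.n_windows:
            raise ValueError(
                f"residue {self.residue_offset:+d}: {self.u_elec.shape[0]} windows "
                f"!= declared {self.n_windows}"
            )


# ---------------------------------------------------------------------------
# fepout dialect
# ---------------------------------------------------------------------------

def parse_fepout(
    path: str | Path,
    schedule: LambdaSchedule,
    *,
    include_equilibration: bool = False,
) -> list[WindowSamples]:
    """Parse a fepout-dialect file into per-window, per-leg sample sets.

    Samples before a window's ``#EQUIL_END`` marker belong to the
    alchemical-equilibration span and are excluded from ``delta_u`` (their
    count is kept in ``n_equilibration_discarded``) unless
    ``include_equilibration`` is set.

    Raises
    ------
    FepParseError
        On a malformed line (the message names the line number) or an
        empty window.
    ScheduleMismatchError
        If the number of windows per leg differs from the schedule.
    """
    path = Path(path)
    windows: list[WindowSamples] = []
    cur: dict | None = None

    def close_current() -> None:
        nonlocal cur
        if cur is None:
            return
        samples = cur["samples"] if include_equilibration is False else cur["equil"] + cur["samples"]
        discarded = len(cur["equil"]) if not include_equilibration else 0
        if not samples:
            raise FepParseError(
                f"{path}: window {cur['index']} ({cur['leg']}) has no production samples"
            )
        windows.append(
            WindowSamples(
                window_index=cur["index"],
                lambda_start=cur["l0"],
                lambda_end=cur["l1"],
                delta_u=np.array(samples, dtype=float),
                leg=cur["leg"],
                n_equilibration_discarded=discarded,
            )
        )
        cur = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (line.startswith("#") and not line.startswith(("#WINDOW", "#EQUIL_END"))):
                continue
            if line.startswith("#WINDOW"):
                close_current()
                parts = line.split()
                if len(parts) != 5:
                    raise FepParseError(
                        f"{path}:{lineno}: malformed window header: {line!r}"
                    )
                try:
                    idx = int(parts[1])
                    l0, l1 = float(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise FepParseError(f"{path}:{lineno}: {exc}") from None
                leg = parts[4]
                if leg not in ("forward", "backward"):
                    raise FepParseError(
                        f"{path}:{lineno}: leg must be forward|backward, got {leg!r}"
                    )
                cur = {"index": idx, "l0": l0, "l1": l1, "leg": leg,
                       "equil": [], "samples": [], "in_equil": False}
                continue
            if line.startswith("#EQUIL_END"):
                if cur is None:
                    raise FepParseError(f"{path}:{lineno}: #EQUIL_END outside a window")
                # everything seen so far in this window was equilibration
                cur["equil"].extend(cur["samples"])
                cur["samples"] = []
                continue
            if cur is None:
                raise FepParseError(f"{path}:{lineno}: sample line outside a window: {line!r}")
            parts = line.split()
            if len(parts) != 2:
                raise FepParseError(f"{path}:{lineno}: expected '<step> <delta_u>', got {line!r}")
            try:
                float(parts[0])
                du = float(parts[1])
            except ValueError:
                raise FepParseError(f"{path}:{lineno}: non-numeric sample line: {line!r}") from None
            if not math.isfinite(du):
                raise FepParseError(f"{path}:{lineno}: non-finite ΔU")
            cur["samples"].append(du)
    close_current()

    per_leg: dict[str, int] = {}
    for w in windows:
        per_leg[w.leg] = per_leg.get(w.leg, 0) + 1
    for leg, n in per_leg.items():
        if n != schedule.n_windows:
            raise ScheduleMismatchError(
                f"{path}: {leg} leg has {n} windows, schedule expects {schedule.n_windows}"
            )
    return windows


def write_fepout(windows: Iterable[WindowSamples], path: str | Path,
                 equilibration: dict[tuple[int, str], Sequence[float]] | None = None) -> None:
    """Write windows in the fepout dialect (inverse of :func:`parse_fepout`).

    ``equilibration`` optionally maps (window_index, leg) to ΔU samples to
    be emitted before an ``#EQUIL_END`` marker.
    """
    equilibration = equilibration or {}
    with open(path, "w") as fh:
        fh.write("# fepout dialect v1; energies kcal/mol\n")
        for w in windows:
            fh.write(f"#WINDOW {w.window_index} {w.lambda_start:.9g} {w.lambda_end:.9g} {w.leg}\n")
            step = 0
            eq = equilibration.get((w.window_index, w.leg), ())
            for du in eq:
                fh.write(f"{step} {float(du):.17g}\n")
                step += 1
            if eq:
                fh.write("#EQUIL_END\n")
            for du in w.delta_u:
                fh.write(f"{step} {float(du):.17g}\n")
                step += 1


def pair_legs(windows: Sequence[WindowSamples]) -> list[tuple[WindowSamples, WindowSamples]]:
    """Match forward and backward windows by λ pair, ordered by window index.

    Raises ``ScheduleMismatchError`` on a missing or duplicated pair.
    """
    fwd = {w.lambda_pair: w for w in windows if w.leg == "forward"}
    bwd = {w.lambda_pair: w for w in windows if w.leg == "backward"}
    if len(fwd) != sum(1 for w in windows if w.leg == "forward"):
        raise ScheduleMismatchError("duplicated λ pair in forward leg")
    if len(bwd) != sum(1 for w in windows if w.leg == "backward"):
        raise ScheduleMismatchError("duplicated λ pair in backward leg")
    missing = sorted(set(fwd) ^ set(bwd))
    if missing:
        raise ScheduleMismatchError(f"unmatched λ pairs between legs: {missing}")
    return [
        (fwd[key], bwd[key])
        for key in sorted(fwd, key=lambda k: fwd[k].window_index)
    ]


# ---------------------------------------------------------------------------
# pair-interaction energies
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = ["residue_offset", "window", "sample_index", "u_elec", "u_vdw"]


def parse_pair_energies(path: str | Path, schedule: LambdaSchedule) -> list[PairEnergySeries]:
    """Read a pair-interaction CSV into one series per residue offset.

    The file carries columns ``residue_offset, window, sample_index,
    u_elec, u_vdw``; each residue must supply exactly
    ``n_windows × samples_per_window`` rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FepParseError(f"{path}: missing columns {missing}")
    expected = schedule.n_windows * schedule.samples_per_window
    out: list[PairEnergySeries] = []
    for offset, grp in df.groupby("residue_offset", sort=True):
        if len(grp) != expected:
            raise FepParseError(
                f"{path}: residue offset {offset:+d} has {len(grp)} samples; expected "
                f"{expected} ({schedule.n_windows} windows × "
                f"{schedule.samples_per_window} samples)"
            )
        grp = grp.sort_values(["window", "sample_index"])
        shape = (schedule.n_windows, schedule.samples_per_window)
        out.append(
            PairEnergySeries(
                residue_offset=int(offset),
                u_elec=grp["u_elec"].to_numpy().reshape(shape),
                u_vdw=grp["u_vdw"].to_numpy().reshape(shape),
                n_windows=schedule.n_windows,
            )
        )
    if not out:
        raise FepParseError(f"{path}: no residues found")
    return out


def write_pair_energies(series: Iterable[PairEnergySeries], path: str | Path) -> None:
    """Write series as the pair-interaction CSV read by :func:`parse_pair_energies`."""
    rows = []
    for s in series:
        nw, ns = s.u_elec.shape
        for w in range(nw):
            for i in range(ns):
                rows.append((s.residue_offset, w + 1, i, s.u_elec[w, i], s.u_vdw[w, i]))
    # %.17g keeps the text round trip exact for float64
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.17g")
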