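"""Replicate quality control: admitting trajectories to free-energy runs.

A replicate is admitted when, over the post-restraint production frames,
a required fraction of frames keeps each enabled metric within its
bound: ligand COM displacement below 2 Å, ligand RMSD below 3 Å, lid
distance and helix angle within a bounded excursion of their own
medians, and hydrogen bonds present with sufficient occupancy.  The
absolute COM/RMSD bounds are the selection thresholds used in practice;
the stability criteria for lid distance and helix angle are this
package's operationalisation of a visual judgement call and are flagged
as such in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .traj_metrics import MetricSeries

__all__ = ["QCThresholds", "CriterionResult", "QCReport", "evaluate_replicate", "rank_replicates"]


@dataclass(frozen=True)
class QCThresholds:
    """Bounds and the frame-fraction required to call a metric stable."""

    com_max: float = 2.0          # Å
    rmsd_max: float = 3.0         # Å
    lid_excursion_max: float = 2.0    # Å from the series median (package default)
    helix_excursion_max: float = 15.0  # degrees from the series median (package default)
    fraction_required: float = 0.9
    hbond_dist_max: float = 3.0   # Å
    hbond_occupancy_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("com_max", "rmsd_max", "lid_excursion_max",
                     "helix_excursion_max", "hbond_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.fraction_required <= 1.0:
            raise ValueError("fraction_required must lie in (0, 1]")
        if not 0.0 <= self.hbond_occupancy_min <= 1.0:
            raise ValueError("hbond_occupancy_min must lie in [0, 1]")


@dataclass(frozen=True)
class CriterionResult:
    metric: str
    mean: float
    max: float
    fraction_within: float
    bound: float
    passed: bool
    note: str = ""


@dataclass
class QCReport:
    """Per-replicate verdicts; overall pass iff every enabled criterion passes."""

    replicate_id: str
    criteria: tuple[CriterionResult, ...]
    overall: bool
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        """Canonical JSON rendering; identical inputs give identical bytes."""
        payload = {
            "replicate_id": self.replicate_id,
            "overall": self.overall,
            "criteria": [
                {
                    "metric": c.metric,
                    "mean": round(c.mean, 12),
                    "max": round(c.max, 12),
                    "fraction_within": round(c.fraction_within, 12),
                    "bound": c.bound,
                    "passed": c.passed,
                    "note": c.note,
                }
                for c in self.criteria
            ],
            "notes": list(self.notes),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def criterion(self, metric: str) -> CriterionResult:
        for c in self.criteria:
            if c.metric == metric:
                return c
        raise KeyError(metric)


def _fraction_within(values: np.ndarray, bound: float) -> float:
    return float(np.mean(values <= bound))


def evaluate_replicate(
    metrics: Mapping[str, MetricSeries],
    thresholds: QCThresholds = QCThresholds(),
    production_start: float = 0.0,
    replicate_id: str = "replicate",
    hbond_occupancy: float | None = None,
) -> QCReport:
    """Apply the QC criteria to a replicate's metric series.

    ``metrics`` must contain ``com_displacement`` and ``ligand_rmsd``;
    ``lid_distance``, ``helix_angle`` and ``hbond_distance`` are
    optional (skipped with a note when absent).  Only frames with
    ``frame_times >= production_start`` (ns) are judged.
    """
    for required in ("com_displacement", "ligand_rmsd"):
        if required not in metrics:
            raise ValueError(f"required metric {required!r} missing")

    notes: list[str] = []
    results: list[CriterionResult] = []

    def post(series: MetricSeries) -> np.ndarray:
        vals = series.values[series.frame_times >= production_start]
        if vals.size == 0:
            raise ValueError(
                f"empty post-production window (production_start={production_start})"
            )
        return vals

    def absolute(metric: str, bound: float) -> None:
        vals = post(metrics[metric])
        frac = _fraction_within(vals, bound)
        results.append(CriterionResult(
            metric=metric, mean=float(vals.mean()), max=float(vals.max()),
            fraction_within=frac, bound=bound,
            passed=frac >= thresholds.fraction_required,
        ))

    def excursion(metric: str, bound: float) -> None:
        if metric not in metrics:
            notes.append(f"{metric} series absent: criterion skipped")
            return
        vals = post(metrics[metric])
        dev = np.abs(vals - np.median(vals))
        frac = _fraction_within(dev, bound)
        results.append(CriterionResult(
            metric=metric, mean=float(vals.mean()), max=float(vals.max()),
            fraction_within=frac, bound=bound,
            passed=frac >= thresholds.fraction_required,
            note="stability criterion (excursion from median); package default bound",
        ))

    absolute("com_displacement", thresholds.com_max)
    absolute("ligand_rmsd", thresholds.rmsd_max)
    excursion("lid_distance", thresholds.lid_excursion_max)
    excursion("helix_angle", thresholds.helix_excursion_max)

    if "hbond_distance" in metrics:
        vals = post(metrics["hbond_distance"])
        frac = _fraction_within(vals, thresholds.hbond_dist_max)
        occ = hbond_occupancy if hbond_occupancy is not None else frac
        results.append(CriterionResult(
            metric="hbond_distance", mean=float(vals.mean()), max=float(vals.max()),
            fraction_within=frac, bound=thresholds.hbond_dist_max,
            passed=occ >= thresholds.hbond_occupancy_min,
            note="passes on occupancy >= hbond_occupancy_min",
        ))
    else:
        notes.append("hbond_distance series absent: criterion skipped")

    overall = all(c.passed for c in results)
    return QCReport(
        replicate_id=replicate_id,
        criteria=tuple(results),
        overall=overall,
        notes=tuple(notes),
    )


def rank_replicates(reports: Sequence[QCReport], k: int,
                    thresholds: QCThresholds = QCThresholds()) -> list[str]:
    """Best-k passing replicates by a documented composite score.

    Score = mean COM displacement / com_max + mean ligand RMSD /
    rmsd_max (lower is better); ties break deterministically on
    replicate_id.  Raises ``ValueError`` if fewer than ``k`` replicates
    pass.
    """
    passing = [r for r in reports if r.overall]
    if len(passing) < k:
        raise ValueError(
            f"only {len(passing)} passing replicates, need {k} "
            f"(short by {k - len(passing)})"
        )

    def score(r: QCReport) -> tuple[float, str]:
        com = r.criterion("com_displacement").mean / thresholds.com_max
        rmsd = r.criterion("ligand_rmsd").mean / thresholds.rmsd_max
        return (com + rmsd, r.replicate_id)

    return [r.replicate_id for r in sorted(passing, key=score)][:k]
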