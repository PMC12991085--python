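"""Free-energy estimators: exponential averaging and the Bennett Acceptance Ratio.

Window ΔU samples from the forward (annihilation) and backward
(re-coupling) legs are combined per window with BAR — the statistically
optimal two-state estimator — and summed across the λ schedule.  The
exponential (Zwanzig) estimator is kept as a one-sided cross-check and
as the bracketing pair for BAR.

Sign convention: ΔG is reported for the annihilation direction, so the
protein- and solvent-leg decoupling free energies are large positive
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .fep_io import WindowSamples, pair_legs

__all__ = [
    "RT_KCAL_MOL",
    "FreeEnergyEstimate",
    "BarConvergenceError",
    "exp_estimator",
    "bar_estimator",
    "total_free_energy",
]

#: RT at 310 K in kcal/mol, the thermal energy used throughout.
RT_KCAL_MOL = 0.616


class BarConvergenceError(RuntimeError):
    """The Bennett self-consistency equation could not be solved."""


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG (kcal/mol) with its standard error and provenance."""

    delta_g: float
    stderr: float
    method: str  # EXP_forward | EXP_backward | BAR
    per_window: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if not (np.isfinite(self.stderr) and self.stderr >= 0):
            raise ValueError("stderr must be finite and >= 0")
        if self.per_window:
            total = sum(w[1] for w in self.per_window)
            if abs(total - self.delta_g) > 1e-9:
                raise ValueError(
                    f"delta_g {self.delta_g} != sum of per-window terms {total}"
                )

    def summary(self) -> str:
        lines = [
            f"Free-energy estimate ({self.method})",
            f"  ΔG     = {self.delta_g:.4f} kcal/mol",
            f"  stderr = {self.stderr:.4f} kcal/mol",
        ]
        if self.per_window:
            lines.append("  window   ΔG_w      stderr_w")
            for idx, dg, se in self.per_window:
                lines.append(f"  {idx:6d}  {dg:8.4f}  {se:8.4f}")
        return "\n".join(lines)


def exp_estimator(samples: WindowSamples, rt: float = RT_KCAL_MOL) -> float:
    """Zwanzig exponential average for one window: −RT·ln⟨exp(−ΔU/RT)⟩.

    Computed through log-sum-exp, stable for |ΔU|/RT of several hundred.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    du = np.asarray(samples.delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("empty sample list")
    return float(-rt * (logsumexp(-du / rt) - np.log(du.size)))


def _bennett_residual(dg: float, wf: np.ndarray, wr: np.ndarray,
                      rt: float, m: float) -> float:
    # Fermi-weighted forward sum minus backward sum; strictly increasing in dg.
    f_fwd = expit(-(m + (wf - dg) / rt))
    f_bwd = expit(-(-m + (wr + dg) / rt))
    return float(np.sum(f_fwd) - np.sum(f_bwd))


def bar_estimator(
    forward: WindowSamples,
    backward: WindowSamples,
    rt: float = RT_KCAL_MOL,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, float]:
    """Solve Bennett's self-consistency equation for one λ window.

    ``forward.delta_u`` holds the annihilation-direction work samples,
    ``backward.delta_u`` the re-coupling-direction ones for the same λ
    pair.  Returns (ΔG_window, stderr_window) in kcal/mol, the stderr from
    Bennett's asymptotic variance formula.

    Raises
    ------
    ValueError
        If the two legs do not refer to the same λ pair in opposite
        directions.
    BarConvergenceError
        If no root is bracketed/located within ``max_iter``.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    if forward.leg == backward.leg:
        raise ValueError("legs must have opposite direction")
    if forward.lambda_pair != backward.lambda_pair:
        raise ValueError(
            f"λ pair mismatch: forward {forward.lambda_pair} vs "
            f"backward {backward.lambda_pair}"
        )
    wf = np.asarray(forward.delta_u, dtype=float)
    wr = np.asarray(backward.delta_u, dtype=float)
    m = float(np.log(wf.size / wr.size))

    # Degenerate case: both legs constant and exactly consistent.
    lo = min(wf.min(), -wr.max()) - 10.0 * rt
    hi = max(wf.max(), -wr.min()) + 10.0 * rt
    f_lo = _bennett_residual(lo, wf, wr, rt, m)
    f_hi = _bennett_residual(hi, wf, wr, rt, m)
    it = 0
    while f_lo > 0 or f_hi < 0:
        # expand; residual is monotone increasing so this terminates
        span = hi - lo
        if f_lo > 0:
            lo -= span
            f_lo = _bennett_residual(lo, wf, wr, rt, m)
        if f_hi < 0:
            hi += span
            f_hi = _bennett_residual(hi, wf, wr, rt, m)
        it += 1
        if it > max_iter:
            raise BarConvergenceError(
                f"no sign change after {max_iter} bracket expansions; "
                f"last bracket [{lo}, {hi}] with residuals [{f_lo}, {f_hi}]"
            )
    try:
        dg = brentq(_bennett_residual, lo, hi, args=(wf, wr, rt, m),
                    xtol=tol, maxiter=max_iter)
    except RuntimeError as exc:  # pragma: no cover - brentq maxiter
        raise BarConvergenceError(
            f"root refinement failed in [{lo}, {hi}]: {exc}"
        ) from exc

    # Bennett asymptotic variance.
    f_f = expit(-(m + (wf - dg) / rt))
    f_b = expit(-(-m + (wr + dg) / rt))
    mf, mb = f_f.mean(), f_b.mean()
    if mf <= 0 or mb <= 0:
        var = np.inf
    else:
        var = rt * rt * (
            (np.mean(f_f * f_f) / (mf * mf) - 1.0) / wf.size
            + (np.mean(f_b * f_b) / (mb * mb) - 1.0) / wr.size
        )
    return float(dg), float(np.sqrt(max(var, 0.0)))


def total_free_energy(
    windows: Sequence[tuple[WindowSamples, WindowSamples]] | Sequence[WindowSamples],
    rt: float = RT_KCAL_MOL,
    schedule_n_windows: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FreeEnergyEstimate:
    """Sum per-window BAR estimates over a complete λ schedule.

    Accepts either a flat list of :class:`WindowSamples` (legs matched
    here by λ pair) or pre-matched (forward, backward) tuples.  Windows
    are treated as independent, so the total variance is the sum of the
    per-window variances; no autocorrelation correction is applied.

    Raises ``ValueError`` listing the gap if a λ pair is missing or
    duplicated, and requires exactly ``schedule_n_windows`` pairs.
    """
    if windows and isinstance(windows[0], WindowSamples):
        pairs = pair_legs(list(windows))
    else:
        pairs = list(windows)
    seen: set[tuple[float, float]] = set()
    for fwd, _ in pairs:
        if fwd.lambda_pair in seen:
            raise ValueError(f"duplicated λ pair {fwd.lambda_pair}")
        seen.add(fwd.lambda_pair)
    if len(pairs) != schedule_n_windows:
        have = {f.window_index for f, _ in pairs}
        gaps = sorted(set(range(1, schedule_n_windows + 1)) - have)
        raise ValueError(
            f"incomplete schedule: {len(pairs)} of {schedule_n_windows} λ pairs; "
            f"missing window indices {gaps}"
        )

    per_window = []
    var = 0.0
    for fwd, bwd in sorted(pairs, key=lambda p: p[0].window_index):
        dg, se = bar_estimator(fwd, bwd, rt=rt, tol=tol, max_iter=max_iter)
        per_window.append((fwd.window_index, dg, se))
        var += se * se
    total = float(sum(w[1] for w in per_window))
    return FreeEnergyEstimate(
        delta_g=total,
        stderr=float(np.sqrt(var)),
        method="BAR",
        per_window=tuple(per_window),
    )
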