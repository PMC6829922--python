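"""Indel-spectrum decomposition of mixed Sanger-style traces.

A Cas9-edited sample sequenced by capillary electrophoresis yields a
chromatogram that is pure wild type upstream of the cut and, downstream, a
mixture of the wild-type trace translated by each indel size present in the
cell population.  Decomposition regresses the treated trace, within a window
downstream of the cut, onto shifted copies of the control (wild-type) trace
with non-negative coefficients; the fitted coefficients estimate the fraction
of molecules carrying each signed indel size (0 = wild type).

Per-shift significance comes from the ordinary-least-squares covariance
restricted to the non-negative fit's active set; R^2 reports goodness of fit,
and the total significant indel percentage sums the non-zero-shift
coefficients with p below ``significance_alpha`` (default 0.001).  A
per-position aberrant-signal profile (intensity off the expected channel,
relative to control) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "DegenerateTraceError",
    "build_shift_matrix",
    "decompose",
    "aberrant_signal",
    "tide_replicate_frequency",
    "default_window",
]

_ACTIVE_TOL = 1e-10


class DegenerateTraceError(ValueError):
    """The treated trace carries no signal inside the decomposition window."""


@dataclass(frozen=True)
class DecompositionConfig:
    """Shift range, window and significance threshold for a decomposition.

    ``shift_range`` is inclusive on both ends and must contain 0 (the
    wild-type column).  ``decomposition_window`` is a half-open position
    interval (start, end) downstream of the cut; it must stay inside the
    trace after the maximal shift.
    """

    shift_range: tuple[int, int] = (-10, 10)
    decomposition_window: Optional[tuple[int, int]] = None
    significance_alpha: float = 0.001

    def __post_init__(self):
        lo, hi = self.shift_range
        if not lo <= 0 <= hi:
            raise ValueError("shift_range must contain 0 (wild type)")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must lie in (0, 1)")

    @property
    def shifts(self) -> list[int]:
        return list(range(self.shift_range[0], self.shift_range[1] + 1))


@dataclass
class DecompositionResult:
    """Non-negative decomposition fit: per-shift fractions and diagnostics."""

    coefficients: dict  # shift -> fraction >= 0
    standard_errors: dict  # shift -> SE (nan when pinned at zero)
    p_values: dict  # shift -> two-sided p (1.0 when pinned at zero)
    r_squared: float
    significance_alpha: float

    @property
    def significant_shifts(self) -> list[int]:
        return [
            s
            for s in self.coefficients
            if s != 0 and self.p_values[s] < self.significance_alpha
        ]

    @property
    def total_significant_pct(self) -> float:
        return 100.0 * sum(self.coefficients[s] for s in self.significant_shifts)


def default_window(cut_index: int, trace_length: int, max_shift: int = 10):
    """Default decomposition window: 5 bp downstream of the cut up to 10 bp
    before the end of the usable trace (leaving room for the maximal shift)."""
    start = cut_index + 5
    end = trace_length - 10 - max_shift
    if end - start < 3:
        raise ValueError("trace too short for a meaningful decomposition window")
    return (start, end)


def _validate_window(cfg: DecompositionConfig, length: int) -> tuple[int, int]:
    if cfg.decomposition_window is None:
        raise ValueError("decomposition_window must be set (see default_window)")
    a, b = cfg.decomposition_window
    lo, hi = cfg.shift_range
    if a - hi < 0 or b - lo > length or b <= a:
        raise ValueError(
            "decomposition window leaves insufficient flank for the shift range"
        )
    return a, b


def build_shift_matrix(control: np.ndarray, cfg: DecompositionConfig) -> np.ndarray:
    """Design matrix: one column per shift, the control trace within the
    window translated by that shift, all four channels stacked row-major.

    The shift-0 column is the in-window control verbatim; the column for
    shift s at window position i holds the control at position i - s.
    """
    control = np.asarray(control, dtype=float)
    if control.ndim != 2 or control.shape[1] != 4:
        raise ValueError("control trace must be (positions, 4)")
    a, b = _validate_window(cfg, control.shape[0])
    cols = [control[a - s : b - s].ravel() for s in cfg.shifts]
    return np.column_stack(cols)


def decompose(
    treated: np.ndarray,
    control: np.ndarray,
    cfg: DecompositionConfig,
) -> DecompositionResult:
    """Non-negative least-squares fit of the treated window on shifted controls.

    Coefficients are molecular fractions (the control's peak height sets the
    scale); if their sum exceeds 1.05 they are renormalised to sum to 1.
    p-values use the OLS covariance at the active set (coefficients pinned at
    zero are reported with p = 1 and no standard error).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated and control traces must have equal shapes")
    X = build_shift_matrix(control, cfg)
    a, b = cfg.decomposition_window
    y = treated[a:b].ravel()
    if not np.any(y > 0):
        raise DegenerateTraceError("treated trace is all zero inside the window")
    coef, _ = optimize.nnls(X, y)
    total = coef.sum()
    if total > 1.05:
        coef = coef / total
    shifts = cfg.shifts
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    active = np.flatnonzero(coef > _ACTIVE_TOL)
    se = {s: float("nan") for s in shifts}
    pv = {s: 1.0 for s in shifts}
    dof = y.size - active.size
    if active.size and dof > 0:
        Xa = X[:, active]
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
        ses = np.sqrt(np.diag(cov))
        tvals = coef[active] / ses
        ps = 2.0 * stats.t.sf(np.abs(tvals), dof)
        for k, idx in enumerate(active):
            se[shifts[idx]] = float(ses[k])
            pv[shifts[idx]] = float(ps[k])
    return DecompositionResult(
        coefficients={s: float(coef[i]) for i, s in enumerate(shifts)},
        standard_errors=se,
        p_values=pv,
        r_squared=float(min(r2, 1.0)),
        significance_alpha=cfg.significance_alpha,
    )


def aberrant_signal(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-position percent of signal off the control's dominant channel,
    treated minus control, floored at zero (range [0, 100])."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated and control traces must have equal shapes")

    def _aberrant(trace: np.ndarray, dominant: np.ndarray) -> np.ndarray:
        total = trace.sum(axis=1)
        main = trace[np.arange(trace.shape[0]), dominant]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, 1.0 - main / total, 0.0)
        return 100.0 * frac

    dominant = control.argmax(axis=1)
    diff = _aberrant(treated, dominant) - _aberrant(control, dominant)
    return np.clip(diff, 0.0, 100.0)


def tide_replicate_frequency(
    forward: DecompositionResult,
    reverse: Optional[DecompositionResult] = None,
) -> float:
    """Replicate indel frequency: the mean of the forward and reverse total
    significant percentages (forward alone when no reverse read is given)."""
    if reverse is None:
        return forward.total_significant_pct
    return 0.5 * (forward.total_significant_pct + reverse.total_significant_pct)
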