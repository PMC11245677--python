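"""Period, amplitude and robustness of oscillatory traces.

The protocol is extrema-based, not spectral.  Local extrema of the sampled
trace are located (plateaus collapse to their midpoint sample); a cycle is
the interval between successive local minima.  The first few cycles are
discarded as transient (gene expression spikes before settling), the
period is the mean gap between the remaining minima, and the oscillation
counts as robust only if every retained cycle's amplitude — the rise from
a minimum to the following maximum — clears a molecule-count floor.
Traces failing that are classified damped: period = +inf, amplitude = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["OscillationSummary", "find_extrema", "estimate_period", "estimate_amplitude",
           "summarize_solution"]

DEFAULT_DROP_CYCLES = 5
DEFAULT_MIN_AMPLITUDE = 10.0


@dataclass(frozen=True)
class OscillationSummary:
    """Period (minutes; +inf when damped), mean amplitude, robustness."""

    period: float
    mean_amplitude: float
    n_cycles_used: int
    robust: bool

    def __post_init__(self) -> None:
        damped = not self.robust
        assert damped == math.isinf(self.period) == (self.mean_amplitude == 0.0)


_DAMPED = OscillationSummary(period=math.inf, mean_amplitude=0.0, n_cycles_used=0, robust=False)


def find_extrema(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and kinds (+1 max, −1 min) of local extrema, strictly alternating.

    A plateau flanked by opposite slopes is resolved to its midpoint
    sample.  A monotone or constant trace yields empty arrays.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise DomainError("trace must be one-dimensional")
    d = np.diff(x)
    moving = np.flatnonzero(d != 0.0)
    if moving.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s = np.sign(d[moving])
    turn = np.flatnonzero(s[1:] != s[:-1])
    # slope changes between samples moving[j]+1 .. moving[j+1]: plateau midpoint
    idx = (moving[turn] + 1 + moving[turn + 1]) // 2
    kinds = np.where(s[turn] > 0, 1, -1).astype(np.int64)
    return idx.astype(np.int64), kinds


def _cycle_stats(trace, idx, kinds, drop_cycles, anchor):
    """Retained anchor extremum indices and per-cycle amplitudes.

    ``anchor`` is −1 to delimit cycles by minima (the reporting convention)
    or +1 for the maxima-based cross-check.
    """
    x = np.asarray(trace, dtype=float)
    anchors = idx[kinds == anchor]
    others = idx[kinds == -anchor]
    if anchors.size < drop_cycles + 2:
        return None
    kept = anchors[drop_cycles:]
    # by alternation there is exactly one opposite extremum inside each cycle
    inner = np.searchsorted(others, kept[:-1], side="right")
    valid = inner < others.size
    if not valid.all():
        kept = kept[: int(valid.sum()) + 1]
        inner = inner[valid]
        if kept.size < 2:
            return None
    opp = others[inner]
    amps = np.abs(x[opp] - x[kept[:-1]])
    return kept, amps


def estimate_period(
    trace: np.ndarray,
    dt: float,
    drop_cycles: int = DEFAULT_DROP_CYCLES,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
    t_span: float | None = None,
    use: str = "minima",
) -> OscillationSummary:
    """Summarise one trace sampled at ``dt`` minutes.

    Cycles are delimited by successive local minima (``use="maxima"``
    flips the anchor for the cross-check); the first ``drop_cycles`` cycles
    are discarded as transient.  If fewer than two minima remain, or any
    retained cycle's amplitude falls below ``min_amplitude`` molecules,
    the trace is classified damped (period +inf, amplitude 0).
    """
    if not dt > 0:
        raise DomainError(f"dt must be positive, got {dt}")
    if use not in ("minima", "maxima"):
        raise DomainError(f"use must be 'minima' or 'maxima', got {use!r}")
    x = np.asarray(trace, dtype=float)
    if t_span is not None:
        x = x[: int(round(t_span / dt)) + 1]
    idx, kinds = find_extrema(x)
    stats = _cycle_stats(x, idx, kinds, drop_cycles, -1 if use == "minima" else 1)
    if stats is None:
        return _DAMPED
    kept, amps = stats
    if amps.size == 0 or np.any(amps < min_amplitude):
        return _DAMPED
    period = float(np.mean(np.diff(kept))) * dt
    return OscillationSummary(
        period=period,
        mean_amplitude=float(np.mean(amps)),
        n_cycles_used=int(amps.size),
        robust=True,
    )


def estimate_amplitude(
    trace: np.ndarray,
    dt: float,
    drop_cycles: int = DEFAULT_DROP_CYCLES,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> float:
    """Mean cycle amplitude (max − preceding min); 0 when classified damped."""
    return estimate_period(trace, dt, drop_cycles, min_amplitude).mean_amplitude


def summarize_solution(solution, variable: str = "mrna", **kwargs) -> OscillationSummary:
    """Summary of a :class:`~segclock.clock_dde.DDESolution` trace.

    mRNA is the reporting variable; the protein trace is used for the
    agreement cross-check.
    """
    trace = getattr(solution, variable)
    return estimate_period(trace, solution.step, **kwargs)
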