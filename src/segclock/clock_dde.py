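"""The delayed-autorepression (Lewis) oscillator and its linear stability.

A clock protein represses transcription of its own gene through a Hill
function, with explicit production delays:

    dp/dt = a·m(t − T_p) − b·p(t)
    dm/dt = f(p(t − T_m)) − c·m(t),      f(p) = k / (1 + (p/p_crit)^n)

where T_p is the translation delay and T_m the mRNA production delay
(transcription + splicing + nuclear export).  For sufficient total delay
T = T_m + T_p and fast enough degradation the fixed point undergoes a Hopf
bifurcation and the system oscillates with a period of roughly twice the
total delay plus turnover times — the segmentation clock.

The integrator is fixed-step RK4 with the method of steps and cubic
Hermite dense output for the delayed lookups (kernel in ``_dde_core``);
fixed stepping makes runs bit-reproducible and convergence trivially
checkable by step halving.  ``critical_delay`` locates the Hopf threshold
from the characteristic equation of the linearisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._dde_core import rk4_delay
from .errors import ConfigurationError, DomainError, IntegrationError
from .species_params import ClockParameters

__all__ = [
    "DDESolution",
    "StabilityResult",
    "hill_repression",
    "hill_repression_slope",
    "integrate",
    "steady_state",
    "critical_delay",
]


@dataclass(frozen=True)
class DDESolution:
    """Trajectory on a uniform grid; molecule counts are real-valued."""

    time: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray
    params: ClockParameters
    step: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.time, "mrna": self.mrna, "protein": self.protein})


@dataclass(frozen=True)
class StabilityResult:
    """Steady state and Hopf threshold of the linearised oscillator."""

    m_star: float
    p_star: float
    sqrt_k: float  # geometric mean of the degradation rates, sqrt(b·c)
    gain: float  # a·f'(p*) at the steady state (negative)
    oscillation_possible: bool
    omega: float  # imaginary-axis crossing frequency, rad/min (nan if none)
    T_crit: float  # minutes, +inf when no crossing exists

    @property
    def period_at_crossing(self) -> float:
        """Oscillation period 2π/ω right at the Hopf point, minutes."""
        return 2.0 * math.pi / self.omega if np.isfinite(self.omega) else math.inf


def hill_repression(p_delayed: float, k: float, p_crit: float, n: float = 2.0):
    """Repressive Hill function f(p) = k / (1 + (p/p_crit)^n).

    Equals k at p=0, k/2 at p=p_crit, and tends to 0 as p → ∞.
    """
    p_delayed = np.asarray(p_delayed, dtype=float)
    if np.any(p_delayed < 0):
        raise DomainError("delayed protein count must be non-negative")
    if k < 0 or not p_crit > 0:
        raise DomainError("k must be non-negative and p_crit positive")
    if n < 1:
        raise DomainError(f"Hill coefficient must be >= 1, got {n}")
    out = k / (1.0 + (p_delayed / p_crit) ** n)
    return float(out) if out.ndim == 0 else out


def hill_repression_slope(p: float, k: float, p_crit: float, n: float = 2.0) -> float:
    """df/dp of the repressive Hill function (≤ 0)."""
    x = (p / p_crit) ** n
    return -k * n * x / (p * (1.0 + x) ** 2) if p > 0 else 0.0


def integrate(
    params: ClockParameters,
    t_end: float = 3100.0,
    step: float = 0.02,
    history: tuple[float, float] = (0.0, 0.0),
) -> DDESolution:
    """Integrate the oscillator over [0, t_end] from constant pre-history.

    ``history`` gives the constant (mRNA, protein) levels on the
    pre-interval [−max(T_m, T_p), 0]; the default empty cell (0, 0) is the
    standard initial condition.  Positive delays must be at least 10 steps
    long; exactly-zero delays are handled exactly (ODE limit).
    """
    if not t_end > 0 or not step > 0:
        raise DomainError("t_end and step must be positive")
    m_hist, p_hist = float(history[0]), float(history[1])
    if m_hist < 0 or p_hist < 0:
        raise DomainError("history molecule counts must be non-negative")
    t_m, t_p = params.delays.T_m, params.delays.T_p
    for name, delay in (("T_m", t_m), ("T_p", t_p)):
        if 0.0 < delay < 10.0 * step:
            raise ConfigurationError(
                f"step {step} min is too large for delay {name}={delay} min "
                f"(need step <= {name}/10)"
            )
    n_steps = int(round(t_end / step))
    m, p, _, _ = rk4_delay(
        params.a, params.b, params.c, params.k, params.p_crit, params.n,
        t_m, t_p, step, n_steps, m_hist, p_hist,
    )
    if not (np.isfinite(m[-1]) and np.isfinite(p[-1])):
        bad = int(np.flatnonzero(~(np.isfinite(m) & np.isfinite(p)))[0])
        raise IntegrationError(
            f"non-finite state at t = {bad * step:.3f} min with {params}"
        )
    time = np.arange(n_steps + 1) * step
    return DDESolution(time=time, mrna=m, protein=p, params=params, step=step)


def steady_state(params: ClockParameters) -> tuple[float, float]:
    """The unique positive fixed point (m*, p*).

    At equilibrium b·p* = a·m* and c·m* = f(p*), so p* solves the scalar
    monotone equation p = (a/(b·c))·f(p); solved by bracketed root-finding
    on [0, a·k/(b·c)].
    """
    a, b, c, k = params.a, params.b, params.c, params.k
    if k == 0:
        return 0.0, 0.0
    scale = a / (b * c)

    def residual(p: float) -> float:
        return p - scale * hill_repression(p, k, params.p_crit, params.n)

    hi = scale * k
    p_star = brentq(residual, 0.0, hi, xtol=1e-12 * max(1.0, hi), rtol=8.9e-16)
    m_star = hill_repression(p_star, k, params.p_crit, params.n) / c
    return m_star, p_star


def critical_delay(params: ClockParameters) -> StabilityResult:
    """Hopf threshold of the total delay T = T_m + T_p.

    Linearising about (m*, p*) gives the characteristic equation
    (λ+b)(λ+c) = g·e^(−λT) with gain g = a·f'(p*) < 0.  A purely imaginary
    root λ = iω requires |g| > b·c (the geometric mean of the degradation
    rates must lie below the gain-implied bound); then

        ω² = [−(b²+c²) + sqrt((b²+c²)² − 4(b²c² − g²))]/2
        T_crit = (π − atan(ω/b) − atan(ω/c))/ω

    is the smallest delay putting a root on the imaginary axis.  When
    |g| ≤ b·c no crossing exists and T_crit = +∞ (the fixed point is
    stable for every delay).
    """
    m_star, p_star = steady_state(params)
    b, c = params.b, params.c
    gain = params.a * hill_repression_slope(p_star, params.k, params.p_crit, params.n)
    sqrt_k = math.sqrt(b * c)
    if abs(gain) <= b * c:
        return StabilityResult(
            m_star=m_star, p_star=p_star, sqrt_k=sqrt_k, gain=gain,
            oscillation_possible=False, omega=math.nan, T_crit=math.inf,
        )
    bb, cc = b * b, c * c
    disc = (bb + cc) ** 2 - 4.0 * (bb * cc - gain * gain)
    omega_sq = (-(bb + cc) + math.sqrt(disc)) / 2.0
    omega = math.sqrt(omega_sq)
    t_crit = (math.pi - math.atan(omega / b) - math.atan(omega / c)) / omega
    return StabilityResult(
        m_star=m_star, p_star=p_star, sqrt_k=sqrt_k, gain=gain,
        oscillation_possible=True, omega=omega, T_crit=t_crit,
    )
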