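"""Numba kernel for the delayed-autorepression integrator.

Fixed-step classical RK4 with the method of steps: state and derivative are
stored at every grid node and delayed values are read back through cubic
Hermite interpolation of that dense history.  Constant pre-history is
assumed.  Delays must be either exactly zero (the lookup then collapses to
the current stage value, recovering plain ODE RK4) or at least one step
long — the wrapper in :mod:`segclock.clock_dde` enforces a 10-step minimum.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _hermite(values, derivs, x, h, hist):
    """Cubic Hermite read of the dense history at fractional index x."""
    if x <= 0.0:
        return hist
    i = int(x)
    if i >= values.shape[0] - 1:
        i = values.shape[0] - 2
    s = x - i
    y0 = values[i]
    y1 = values[i + 1]
    d0 = derivs[i] * h
    d1 = derivs[i + 1] * h
    s2 = s * s
    s3 = s2 * s
    return ((2.0 * s3 - 3.0 * s2 + 1.0) * y0 + (s3 - 2.0 * s2 + s) * d0
            + (-2.0 * s3 + 3.0 * s2) * y1 + (s3 - s2) * d1)


@njit(cache=True)
def rk4_delay(a, b, c, k, p_crit, n, t_m, t_p, h, n_steps, m_hist, p_hist):
    """Integrate the two-variable delayed feedback loop.

    dm/dt = k / (1 + (p(t - t_m)/p_crit)^n) - c m(t)
    dp/dt = a m(t - t_p) - b p(t)

    Returns (m, p, dm, dp) on the uniform grid of n_steps+1 nodes.
    """
    m = np.empty(n_steps + 1)
    p = np.empty(n_steps + 1)
    dm = np.empty(n_steps + 1)
    dp = np.empty(n_steps + 1)
    m[0] = m_hist
    p[0] = p_hist
    lag_m = t_p / h  # lookup of m at t - t_p
    lag_p = t_m / h  # lookup of p at t - t_m
    dm[0] = k / (1.0 + (p_hist / p_crit) ** n) - c * m_hist
    dp[0] = a * m_hist - b * p_hist
    for i in range(n_steps):
        m0 = m[i]
        p0 = p[i]
        # stage 1 at t_i
        md = m0 if lag_m == 0.0 else _hermite(m, dm, i - lag_m, h, m_hist)
        pd = p0 if lag_p == 0.0 else _hermite(p, dp, i - lag_p, h, p_hist)
        k1m = k / (1.0 + (pd / p_crit) ** n) - c * m0
        k1p = a * md - b * p0
        # stage 2 at t_i + h/2
        mv = m0 + 0.5 * h * k1m
        pv = p0 + 0.5 * h * k1p
        md = mv if lag_m == 0.0 else _hermite(m, dm, i + 0.5 - lag_m, h, m_hist)
        pd = pv if lag_p == 0.0 else _hermite(p, dp, i + 0.5 - lag_p, h, p_hist)
        k2m = k / (1.0 + (pd / p_crit) ** n) - c * mv
        k2p = a * md - b * pv
        # stage 3 at t_i + h/2
        mv = m0 + 0.5 * h * k2m
        pv = p0 + 0.5 * h * k2p
        md = mv if lag_m == 0.0 else _hermite(m, dm, i + 0.5 - lag_m, h, m_hist)
        pd = pv if lag_p == 0.0 else _hermite(p, dp, i + 0.5 - lag_p, h, p_hist)
        k3m = k / (1.0 + (pd / p_crit) ** n) - c * mv
        k3p = a * md - b * pv
        # stage 4 at t_i + h
        mv = m0 + h * k3m
        pv = p0 + h * k3p
        md = mv if lag_m == 0.0 else _hermite(m, dm, i + 1.0 - lag_m, h, m_hist)
        pd = pv if lag_p == 0.0 else _hermite(p, dp, i + 1.0 - lag_p, h, p_hist)
        k4m = k / (1.0 + (pd / p_crit) ** n) - c * mv
        k4p = a * md - b * pv
        m[i + 1] = m0 + h / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        p[i + 1] = p0 + h / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        # derivative at the new node for the dense history
        md = m[i + 1] if lag_m == 0.0 else _hermite(m, dm, i + 1.0 - lag_m, h, m_hist)
        pd = p[i + 1] if lag_p == 0.0 else _hermite(p, dp, i + 1.0 - lag_p, h, p_hist)
        dm[i + 1] = k / (1.0 + (pd / p_crit) ** n) - c * m[i + 1]
        dp[i + 1] = a * md - b * p[i + 1]
    return m, p, dm, dp
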