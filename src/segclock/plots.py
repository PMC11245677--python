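"""Optional heatmap rendering of period grids (matplotlib imported lazily)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .experiments import GridResult

__all__ = ["plot_period_grid"]


def plot_period_grid(result: GridResult, path: str | Path, title: str = "") -> Path:
    """Heatmap of finite periods with the capture set outlined.

    Damped cells render dark; when the spec carries a target period, cells
    within tolerance are hatched.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = result.spec
    periods = np.where(np.isfinite(result.periods), result.periods, np.nan)
    fig, ax = plt.subplots(figsize=(7, 5))
    extent = (
        spec.total_delays[0], spec.total_delays[-1],
        spec.h_p_values[0], spec.h_p_values[-1],
    )
    im = ax.imshow(
        periods.T, origin="lower", aspect="auto", extent=extent, cmap="viridis",
    )
    ax.set_facecolor("#2a1a4a")
    if spec.target_period is not None:
        mask = result.capture_mask().T.astype(float)
        ax.contour(
            spec.total_delays, spec.h_p_values, mask, levels=[0.5],
            colors="white", linestyles="dashed",
        )
    ax.set_xlabel("total delay $T_m + T_p$ (min)")
    ax.set_ylabel("protein half-life $h_p$ (min)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="period (min)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
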