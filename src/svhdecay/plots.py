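"""Diagnostic plots: pooled data points with both fitted decay curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .decay_models import eval_model
from .group_analysis import PooledFit

__all__ = ["plot_pooled_fit"]


def plot_pooled_fit(pooled: PooledFit, path: str | Path) -> Path:
    """Scatter of pooled (t, SVH) points with the exponential fit as a
    solid line and the power fit as a dotted line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = pooled.points["t"].to_numpy()
    ax.plot(t, pooled.points["svh"], "o", ms=4, color="0.3", label="pooled settings")
    grid = np.linspace(max(t.min(), 1e-3), t.max(), 400)
    ax.plot(
        grid,
        eval_model(pooled.fit_exponential.params, grid),
        "-",
        label=f"exponential (RMS {pooled.fit_exponential.rms:.2f}°)",
    )
    ax.plot(
        grid,
        eval_model(pooled.fit_power.params, grid),
        ":",
        label=f"power (RMS {pooled.fit_power.rms:.2f}°)",
    )
    ax.set_xlabel("time since G plateau (s)")
    ax.set_ylabel("SVH tilt (°)")
    ax.set_title(pooled.scheme.value)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
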