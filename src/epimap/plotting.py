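"""Static figure export of activation and phase maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .conduction import PhaseMapResult  # noqa: E402
from .features import ActivationMap  # noqa: E402
from .synthetic.geometry import ArrayGeometry  # noqa: E402


def _scatter(values, geometry: ArrayGeometry, path: Path, label: str, cmap: str):
    fig, ax = plt.subplots(figsize=(4, 6))
    sc = ax.scatter(geometry.x_mm, geometry.y_mm, c=values, cmap=cmap, s=120,
                    edgecolors="k", linewidths=0.3)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # row 0 at the top
    fig.colorbar(sc, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_activation_map(activation: ActivationMap, geometry: ArrayGeometry,
                        path: str | Path) -> None:
    """Isochrone-style scatter of per-channel activation times."""
    _scatter(activation.time_ms, geometry, Path(path),
             "activation time (ms)", "viridis")


def plot_phase_map(phases: PhaseMapResult, geometry: ArrayGeometry,
                   path: str | Path) -> None:
    _scatter(phases.delay_ms, geometry, Path(path),
             "max neighbor delay (ms)", "magma")
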