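"""Map rendering for predicted distributions (plotting layer).

Global equirectangular panels: suitability density shading, citizen
reports as points, legacy records as circles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .envelope import SuitabilityMap
from .ingest import Report


def plot_distribution_map(
    smap: SuitabilityMap,
    reports: Sequence[Report] = (),
    legacy: Sequence[Report] = (),
    density: Optional[np.ndarray] = None,
    title: str = "",
    path: str | Path | None = None,
):
    fig, ax = plt.subplots(figsize=(9, 4.5))
    extent = (-180, 180, -90, 90)
    if smap.ocean is not None:
        ax.imshow(np.where(smap.ocean, np.nan, 0.5), origin="lower", extent=extent,
                  cmap="Greys", vmin=0, vmax=1, alpha=0.6)
    shade = density if density is not None else smap.mask.astype(float)
    shade = np.where(shade > 0, shade, np.nan)
    ax.imshow(shade, origin="lower", extent=extent, cmap="viridis", alpha=0.8)
    if reports:
        ax.scatter([r.longitude for r in reports], [r.latitude for r in reports],
                   s=4, marker="s", c="deeppink", label="citizen reports")
    if legacy:
        ax.scatter([r.longitude for r in legacy], [r.latitude for r in legacy],
                   s=10, marker="o", facecolors="none", edgecolors="royalblue",
                   label="legacy records")
    ax.set_xlim(-180, 180)
    ax.set_ylim(-90, 90)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or smap.genus)
    if reports or legacy:
        ax.legend(loc="lower left", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return None
    return fig
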