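"""Optional PNG rendering of transversal sections (cosmetic output only)."""

from __future__ import annotations

import numpy as np


def rpm_colormap():
    """Probability colormap: 0 red, 0.5 yellow, 1 green (never to always resected)."""
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "rpm", [(0.0, "#c62828"), (0.5, "#fbc02d"), (1.0, "#2e7d32")]
    )
    cmap.set_bad(color="#f2f2f2")
    return cmap


def save_sections(volume: np.ndarray, path: str, n_sections: int = 6, vmin=0.0, vmax=1.0, cmap=None) -> None:
    """Write a row of evenly spaced transversal (axial) sections as one PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cmap is None:
        cmap = rpm_colormap()
    nz = volume.shape[2]
    zs = np.linspace(0, nz - 1, n_sections + 2, dtype=int)[1:-1]
    fig, axes = plt.subplots(1, len(zs), figsize=(2.2 * len(zs), 2.4))
    for ax, z in zip(np.atleast_1d(axes), zs):
        ax.imshow(np.ma.masked_invalid(volume[:, :, z]).T, origin="lower",
                  cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
        ax.set_title(f"z={z}", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
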