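"""Minimal plotting: motif logo from a PWM and histone heatmap rendering."""

from __future__ import annotations

import numpy as np

from .motif import BASES, PositionWeightMatrix, pwm_information_content

_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def plot_logo(pwm: PositionWeightMatrix, path) -> None:
    """Render an information-content-scaled sequence logo to an image file.

    Letters are drawn as stretched text patches; per-column letter heights
    are base frequency times column information content (bits).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.textpath import TextPath
    from matplotlib.patches import PathPatch
    from matplotlib.transforms import Affine2D
    from matplotlib.font_manager import FontProperties

    ic = pwm_information_content(pwm)
    arr = pwm.array
    fig, ax = plt.subplots(figsize=(0.6 * pwm.width + 1, 2.4))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for j in range(pwm.width):
        y = 0.0
        order = np.argsort(arr[:, j])  # draw small letters first, stack upward
        for i in order:
            h = arr[i, j] * ic[j]
            if h <= 1e-3:
                continue
            tp = TextPath((0, 0), BASES[i], size=1.0, prop=fp)
            bbox = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.9 / bbox.width, h / bbox.height)
                .translate(j + 0.05, y)
            )
            ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                                   color=_LOGO_COLORS[BASES[i]], linewidth=0))
            y += h
    ax.set_xlim(0, pwm.width)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(np.arange(pwm.width) + 0.5)
    ax.set_xticklabels(range(1, pwm.width + 1))
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_signal_heatmap(matrix: np.ndarray, path, sort_rows: bool = True) -> None:
    """Regions-by-position read-count heatmap (metaregion view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.asarray(matrix, dtype=float)
    if sort_rows and len(mat):
        mat = mat[np.argsort(-mat.mean(axis=1))]
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(mat, aspect="auto", cmap="Reds", interpolation="nearest")
    ax.set_xlabel("position bin")
    ax.set_ylabel("region")
    fig.colorbar(im, ax=ax, label="read count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
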