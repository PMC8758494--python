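"""Polar-plot export for spike-phase distributions.

Optional: requires matplotlib (``pip install spikegamma[plot]``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .coupling import resultant_vector


def polar_phase_plot(angles, path: str | Path, n_bins: int = 24, title: str = ""):
    """Angle histogram with the mean resultant vector overlaid, saved as SVG.

    The radial axis is spike count per bin; the resultant vector is drawn
    at the preferred angle with length r x (max bin count) so it reads on
    the same scale.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    angles = np.asarray(angles, dtype=float)
    r, mu = resultant_vector(angles)
    counts, edges = np.histogram(angles, bins=n_bins, range=(-np.pi, np.pi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(111, projection="polar")
    ax.bar(centers, counts, width=2 * np.pi / n_bins, alpha=0.6, color="0.4")
    ax.annotate(
        "", xy=(mu, r * counts.max()), xytext=(0, 0),
        arrowprops=dict(arrowstyle="-|>", color="crimson", lw=2),
    )
    ax.set_theta_zero_location("E")  # peak of the gamma cycle at angle 0
    ax.set_title(title or f"r = {r:.3f}, angle = {mu:+.2f} rad", fontsize=10)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return Path(path)
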