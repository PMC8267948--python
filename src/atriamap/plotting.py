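"""Basic activation-map and phase-histogram figures (matplotlib optional)."""

from __future__ import annotations

import numpy as np


def plot_activation_map(amap, ax=None, cmap: str = "turbo"):
    """Colour-coded LAT map with unannotated channels blanked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        np.ma.masked_invalid(amap.lat_ms),
        origin="lower",
        cmap=cmap,
        interpolation="nearest",
    )
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.figure.colorbar(im, ax=ax, label="activation time (ms)")
    return ax


def plot_phase_histogram(dist, ax=None, bin_width_ms: float = 0.25):
    """Histogram of quadruplet activation-time differences (phase values)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = dist.values_ms
    bins = np.arange(0.0, v.max() + 2 * bin_width_ms, bin_width_ms)
    ax.hist(v, bins=bins, edgecolor="black")
    ax.set_xlabel("largest phase difference per quadruplet (ms)")
    ax.set_ylabel("episodes")
    return ax
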