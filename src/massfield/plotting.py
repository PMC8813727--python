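"""Snapshot plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_raster", "plot_mass_trajectory", "plot_field_snapshot"]


def plot_raster(raster, max_neurons: int = 100, ax=None):
    """Spike raster of (a sample of) the network."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    idx, times = raster.all_spikes()
    keep = idx < max_neurons
    ax.plot(times[keep], idx[keep], ".", ms=1.5, color="C0")
    ax.set(xlabel="t (ms)", ylabel="neuron")
    return ax


def plot_mass_trajectory(tr, ax=None):
    """R, V and |Z| of a mass-model run on twin axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(tr.t, tr.R, color="teal", label="R")
    ax.set(xlabel="t (ms)", ylabel="R (1/ms)")
    ax2 = ax.twinx()
    ax2.plot(tr.t, np.abs(tr.Z), color="green", alpha=0.7, label="|Z|")
    ax2.set_ylabel("|Z|")
    return ax


def plot_field_snapshot(tr, i: int = -1, variable: str = "absZ", ax=None):
    """One saved frame of a field run (1D profile or 2D image)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    data = getattr(tr, variable)[i]
    if data.ndim == 1:
        ax.plot(tr.x, data)
        ax.set(xlabel="x", ylabel=variable)
    else:
        im = ax.imshow(data, origin="lower", extent=[0, tr.x[-1], 0, tr.x[-1]],
                       cmap="viridis")
        plt.colorbar(im, ax=ax, label=variable)
        ax.set(xlabel="x", ylabel="y", title=f"t = {tr.t[i]:.0f} ms")
    return ax
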