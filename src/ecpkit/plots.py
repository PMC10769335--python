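"""Standard figures: FSCV color plots, spike rasters, condition averages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from ecpkit.fscv_chemometrics import CVStream, color_plot_matrix
from ecpkit.task_alignment import AlignedMatrix, condition_average


def plot_color_plot(delta_i: np.ndarray, stream: CVStream, ax=None):
    """Background-subtracted current as color over (scan voltage x time)."""
    ax = ax or plt.subplots()[1]
    M = color_plot_matrix(delta_i, stream)
    vmax = np.abs(M).max() or 1.0
    im = ax.imshow(
        M, aspect="auto", origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        extent=[stream.scan_times[0], stream.scan_times[-1], 0, M.shape[0]],
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("scan voltage point (−0.4 → 1.3 → −0.4 V)")
    ax.figure.colorbar(im, ax=ax, label="ΔI (nA)")
    return ax


def plot_raster(mat: AlignedMatrix, ax=None):
    """Trial-by-trial raster of an aligned spike matrix (dots at spike bins)."""
    ax = ax or plt.subplots()[1]
    rows, cols = np.nonzero(np.nan_to_num(mat.data) > 0)
    ax.scatter(mat.bin_centers[cols], rows, s=2, c="k", marker="|")
    ax.axvline(0.0, color="r", lw=0.8)
    ax.set_xlabel(f"time from {mat.event or 'event'} (s)")
    ax.set_ylabel("trial")
    return ax


def plot_condition_average(mat: AlignedMatrix, split_by: str, ax=None,
                           colors=("tab:red", "tab:blue")):
    """Per-condition mean ± SE traces (shading is the standard error)."""
    ax = ax or plt.subplots()[1]
    stats = condition_average(mat, split_by)
    for (cond, st), color in zip(sorted(stats.items()), colors):
        m, se = st["mean"], st["se"]
        ax.plot(mat.bin_centers, m, color=color,
                label=f"{cond} (n={st['n_trials']})")
        ax.fill_between(mat.bin_centers, m - se, m + se, color=color, alpha=0.25)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(f"time from {mat.event or 'event'} (s)")
    ax.legend(frameon=False)
    return ax
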