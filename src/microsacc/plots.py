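"""Optional matplotlib renderers for the standard views.

Every analytic also exists as a plain table; these helpers only draw.
All functions accept an optional Axes and return the Axes they drew on.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import numpy as np

from .analytics import RoseHistogram
from .core import GazeEvent


def rose_plot(hist: RoseHistogram, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Polar bar chart of an angular histogram, with mean direction marked."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    widths = np.radians(np.diff(hist.bin_edges_deg))
    centers = np.radians(hist.bin_edges_deg[:-1]) + widths / 2
    ax.bar(centers, hist.counts, width=widths, align="center",
           edgecolor="black", linewidth=0.5, alpha=0.7)
    if hist.mean_dir_deg is not None and hist.counts.sum() > 0:
        ax.axvline(np.radians(hist.mean_dir_deg), color="black", linewidth=1.5)
    return ax


def temporal_plot(counts: np.ndarray, bin_ms: float = 40.0,
                  ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Histogram of event onset latency within fixations."""
    if ax is None:
        _, ax = plt.subplots()
    edges = np.arange(len(counts) + 1) * bin_ms
    ax.bar(edges[:-1], counts, width=bin_ms, align="edge", edgecolor="black")
    ax.set_xlabel("onset latency in fixation (ms)")
    ax.set_ylabel("microsaccade count")
    return ax


def main_sequence_plot(events: Sequence[GazeEvent],
                       ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Amplitude vs peak velocity on log-log axes."""
    if ax is None:
        _, ax = plt.subplots()
    amps = [e.amplitude for e in events if e.amplitude > 0 and e.peak_velocity > 0]
    pvs = [e.peak_velocity for e in events if e.amplitude > 0 and e.peak_velocity > 0]
    ax.loglog(amps, pvs, ".", markersize=3)
    ax.set_xlabel("amplitude (deg)")
    ax.set_ylabel("peak velocity (deg/s)")
    return ax
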