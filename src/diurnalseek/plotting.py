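"""Basic diagnostic plots: wavelet power heatmap, folded days, dot matrix."""

from __future__ import annotations

import numpy as np

from .diurnal import FoldedDays
from .hourly_stats import SignificanceMatrix
from .wavelet import WaveletSpectrum, power_spectrum


def plot_power_spectrum(spectrum: WaveletSpectrum, ax=None, show_coi=True):
    """Time-period heatmap of wavelet power with the cone of influence."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(spectrum.n_times)
    ax.pcolormesh(t, spectrum.periods, power_spectrum(spectrum),
                  shading="nearest")
    if show_coi:
        ax.plot(t, np.clip(spectrum.coi, spectrum.periods[0], None),
                "w--", lw=1)
    ax.set_yscale("log")
    ax.set_ylabel("period (h)")
    ax.set_xlabel("time (h)")
    ax.invert_yaxis()
    return ax


def plot_folded_days(folded: FoldedDays, ax=None):
    """All 24-hour cycles superimposed with their arithmetic mean."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hours = np.arange(24)
    for row in folded.matrix:
        ax.plot(hours, row, color="C0", alpha=0.3, lw=0.8)
    ax.plot(hours, folded.matrix.mean(axis=0), color="C3", lw=2,
            label="mean")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("RSV")
    ax.legend()
    return ax


def plot_significance_matrix(matrix: SignificanceMatrix, ax=None):
    """Dot plot: a marker at (j, i) when hour i > hour j significantly."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ii, jj = np.nonzero(matrix.greater)
    ax.scatter(jj, ii, s=12, color="k")
    ax.set_xlim(-0.5, 23.5)
    ax.set_ylim(-0.5, 23.5)
    ax.set_xlabel("hour (lesser)")
    ax.set_ylabel("hour (greater)")
    ax.set_aspect("equal")
    return ax
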