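"""Debug renders and analysis plots.

Maximum-intensity projections with annotated landmarks for visual QC of
the anatomy stage, and the standard growth-analysis panels: caliper vs CT
histograms, a Bland-Altman agreement plot, and growth curves with fitted
models.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .growth import BlandAltmanResult, GrowthCurve, TumorGrowthResults
from .voxcore import ScanVolume, max_intensity_projection

__all__ = [
    "plot_mip_landmarks",
    "plot_volume_histograms",
    "plot_bland_altman",
    "plot_growth_fit",
]

_AXIS_PAIRS = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}


def plot_mip_landmarks(vol: ScanVolume, points_mm: dict, axis: str = "x"):
    """Maximum-intensity projection with labeled landmark points."""
    fig, ax = plt.subplots(figsize=(5, 5))
    mip = max_intensity_projection(vol, axis)
    ax.imshow(mip.T, origin="lower", cmap="gray")
    r, c = _AXIS_PAIRS[axis]
    for name, p in points_mm.items():
        idx = vol.index_of_mm(np.asarray(p, dtype=float))
        ax.plot(idx[r], idx[c], "o", ms=5)
        ax.annotate(name, (idx[r], idx[c]), fontsize=7, color="yellow")
    ax.set_title(f"MIP along {axis}")
    ax.set_xticks([])
    ax.set_yticks([])
    return fig


def plot_volume_histograms(caliper, ct, bins=30):
    """Overlaid histograms of volumes from the two measurement methods."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(np.asarray(caliper), bins=bins, alpha=0.6, label="caliper")
    ax.hist(np.asarray(ct), bins=bins, alpha=0.6, label="CT")
    ax.set_xlabel("volume (mm$^3$)")
    ax.set_ylabel("count")
    ax.legend()
    return fig


def plot_bland_altman(res: BlandAltmanResult, log_x: bool = True):
    """Agreement plot: difference vs pairwise mean with limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.means, res.differences, s=10)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, lw=0.8)
    if log_x and np.all(np.asarray(res.means) > 0):
        ax.set_xscale("log")
    ax.set_xlabel("mean of methods (mm$^3$)")
    ax.set_ylabel("caliper $-$ CT (mm$^3$)")
    return fig


def plot_growth_fit(curve: GrowthCurve, fit: TumorGrowthResults | None = None):
    """One mouse's growth curve with the fitted model and its components."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.days, curve.volumes, "o", label=curve.method)
    if fit is not None:
        t = np.linspace(curve.days.min(), curve.days.max(), 200)
        ax.plot(t, fit.predict(t), "-", label="model")
        p = fit.params
        gauss = p.a * np.exp(-((t - p.b) ** 2) / p.c**2)
        ax.plot(t, gauss, ":", lw=0.8, label="Gaussian")
    ax.set_xlabel("days post implantation")
    ax.set_ylabel("volume (mm$^3$)")
    ax.set_title(curve.mouse_id)
    ax.legend(fontsize=8)
    return fig
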