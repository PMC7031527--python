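"""Plotting helpers (matplotlib) for time courses, histograms and fits."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_time_course(tc, ax=None, **kwargs):
    """Field time course at one voxel over one signal period."""
    ax = _ax(ax)
    ax.plot(tc.times * 1e3, tc.magnitudes, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(str(tc.quantity.value))
    ax.set_title(f"voxel {tc.voxel_index}")
    return ax


def plot_exposure_histogram(summary, ax=None, **kwargs):
    """Frequency of occurrence of field intensities over the lesion."""
    ax = _ax(ax)
    centers = 0.5 * (summary.bin_edges[:-1] + summary.bin_edges[1:])
    width = summary.bin_edges[1] - summary.bin_edges[0]
    ax.bar(centers, summary.counts, width=0.9 * width, **kwargs)
    ax.axvline(summary.mode_value, color="k", ls="--", lw=1,
               label=f"mode {summary.mode_value:.2f}")
    ax.set_xlabel("field magnitude")
    ax.set_ylabel("voxel count")
    ax.legend()
    return ax


def plot_dose_response(results, ax=None):
    """Pooled threshold/ratio points with the fitted exponential curve."""
    ax = _ax(ax)
    model = results.model
    for cid in np.unique(model.case_ids):
        sel = model.case_ids == cid
        ax.scatter(model.thresholds[sel], model.ratios_percent[sel],
                   label=str(cid), s=18)
    x = np.linspace(model.thresholds.min(), model.thresholds.max(), 200)
    ax.plot(x, results.predict(x), "k-",
            label=f"fit M={results.M:.1f}, a={results.a:.3f}")
    ax.set_xlabel(f"lower-bound threshold ({model.quantity})")
    ax.set_ylabel("V_post / V_pre (%)")
    ax.axhline(100.0, color="grey", lw=0.8, ls=":")
    ax.legend()
    return ax


def plot_slice_areas(slices, ax=None):
    """Pre/post slice areas along the slicing direction."""
    ax = _ax(ax)
    ax.plot(slices.offsets_mm, slices.pre_areas_mm2, "o-", label="pre")
    ax.plot(slices.offsets_mm, slices.post_areas_mm2, "s-", label="post")
    ax.set_xlabel(f"{slices.plane}-offset (mm)")
    ax.set_ylabel("slice area (mm$^2$)")
    ax.legend()
    return ax
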