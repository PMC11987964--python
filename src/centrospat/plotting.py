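"""Quick-look figures: patterns, overlay fields, posterior chains.

Thin matplotlib helpers; every function accepts an existing ``ax`` (or
creates one) and returns it, so the plots compose into panels.
"""

from __future__ import annotations

import numpy as np

from .core import SpotPattern
from .models import PosteriorSamples
from .similarity import OverlayField


def plot_pattern(pattern: SpotPattern, ax=None, **scatter_kw):
    """Spots and the nucleus outline for one pattern."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    cx, cy = pattern.region.center
    circle = plt.Circle((cx, cy), pattern.region.radius, fill=False, color="crimson")
    ax.add_patch(circle)
    scatter_kw.setdefault("s", 12)
    ax.scatter(pattern.spots[:, 0], pattern.spots[:, 1], **scatter_kw)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y grows downward
    ax.set_title(pattern.provenance)
    return ax


def plot_overlay(field: OverlayField, ax=None, cmap="magma"):
    """2D histogram of the pooled, center-aligned spots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    extent = [field.edges[0], field.edges[-1], field.edges[-1], field.edges[0]]
    im = ax.imshow(field.hist, extent=extent, cmap=cmap)
    ax.figure.colorbar(im, ax=ax, label="spot count")
    ax.set_xlabel("x - center (px)")
    ax.set_ylabel("y - center (px)")
    return ax


def plot_overlay_profiles(field: OverlayField, ax=None):
    """X=0 / Y=0 line profiles of the overlay histogram."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(field.centers, field.profile_x, label="y = 0 row")
    ax.plot(field.centers, field.profile_y, label="x = 0 column")
    ax.set_xlabel("position (px)")
    ax.set_ylabel("count")
    ax.legend()
    return ax


def plot_chain(samples: PosteriorSamples, axes=None):
    """Trace and marginal histogram per parameter of an MCMC chain."""
    import matplotlib.pyplot as plt

    d = samples.draws.shape[1]
    if axes is None:
        _, axes = plt.subplots(d, 2, figsize=(8, 2.2 * d), squeeze=False)
    for i, name in enumerate(samples.param_names):
        axes[i][0].plot(samples.draws[:, i], lw=0.5)
        axes[i][0].set_ylabel(name)
        axes[i][1].hist(samples.draws[:, i], bins=40, density=True)
        axes[i][1].axvline(samples.draws[:, i].mean(), color="crimson")
    axes[-1][0].set_xlabel("retained iteration")
    return axes
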