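"""Core domain objects: nucleus regions and spot patterns.

Coordinates follow the image convention (origin top-left, y increasing
downward) and are continuous, in pixel units.  A :class:`NucleusRegion` is
circular by default; an ellipse or a binary mask can refine the boundary for
observed nuclei.  A :class:`SpotPattern` ties a set of 2D spot coordinates to
the region that contains them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CentrospatError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(CentrospatError, ValueError):
    """A parameter violates its documented constraints."""


class InsufficientPointsError(CentrospatError, ValueError):
    """An operation requires more spots than the pattern contains."""


class InfeasiblePackingError(CentrospatError, RuntimeError):
    """Rejection sampling exhausted its attempt budget.

    Carries ``achieved`` so callers can see how many points fit before the
    budget ran out.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


@dataclass(frozen=True)
class Ellipse:
    """Moment-equivalent ellipse of a nucleus: semi-axes ``a >= b``, tilt phi."""

    a: float
    b: float
    phi: float = 0.0

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise InvalidParameterError(
                f"ellipse requires a >= b > 0, got a={self.a}, b={self.b}"
            )


@dataclass(frozen=True)
class NucleusRegion:
    """A nucleus footprint: a circle, optionally refined by an ellipse or mask.

    Parameters
    ----------
    center : (2,) array-like
        Circle/ellipse center in pixels, (x, y).
    radius : float
        Circle radius in pixels (the equivalent radius when built from a mask).
    ellipse : Ellipse, optional
        Moment-equivalent ellipse for non-circular nuclei.
    mask : ndarray of bool, optional
        Binary footprint; when present, containment is tested against it.
    pixel_size : float
        Physical pixel size in micrometres per pixel (bookkeeping only).
    label : int or str, optional
        Cell identifier carried from a label mask or spot table.
    """

    center: tuple[float, float]
    radius: float
    ellipse: Ellipse | None = None
    mask: np.ndarray | None = field(default=None, compare=False)
    pixel_size: float = 0.108
    label: object = None

    def __post_init__(self):
        if not np.isfinite(self.center).all():
            raise InvalidParameterError("region center must be finite")
        if not (self.radius > 0):
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if self.mask is not None and not self.mask.any():
            raise InvalidParameterError("mask must be non-empty")

    @property
    def area(self) -> float:
        """Region area in px^2 (mask pixel count if a mask is present)."""
        if self.mask is not None:
            return float(self.mask.sum())
        if self.ellipse is not None:
            return float(np.pi * self.ellipse.a * self.ellipse.b)
        return float(np.pi * self.radius**2)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean containment test for an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.mask is not None:
            h, w = self.mask.shape
            xi = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
            yi = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
            inside_canvas = (
                (pts[:, 0] >= -0.5)
                & (pts[:, 0] < w - 0.5)
                & (pts[:, 1] >= -0.5)
                & (pts[:, 1] < h - 0.5)
            )
            return inside_canvas & self.mask[yi, xi]
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        if self.ellipse is not None:
            c, s = np.cos(self.ellipse.phi), np.sin(self.ellipse.phi)
            u = c * dx + s * dy
            v = -s * dx + c * dy
            return (u / self.ellipse.a) ** 2 + (v / self.ellipse.b) ** 2 <= 1.0
        return dx**2 + dy**2 <= self.radius**2

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the circular footprint."""
        cx, cy = self.center
        r = self.radius
        return cx - r, cx + r, cy - r, cy + r


#: Default synthetic-nucleus geometry: 256x256 px patch, circle of radius
#: 46 px at (128,128).  46 px corresponds to a 10 um nucleus diameter at the
#: 0.108 um/px acquisition pixel size.
DEFAULT_REGION = NucleusRegion(center=(128.0, 128.0), radius=46.0)


@dataclass(frozen=True)
class SpotPattern:
    """One nucleus and its detected or simulated spot coordinates.

    ``provenance`` records the generator id (or ``"observed"``); ``roles`` is
    an optional per-spot label array used by the adjacent-spot generators to
    track seed/companion multiplets.
    """

    region: NucleusRegion
    spots: np.ndarray
    provenance: str = "observed"
    roles: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        spots = np.asarray(self.spots, dtype=float)
        if spots.ndim != 2 or spots.shape[1] != 2:
            raise InvalidParameterError("spots must be an (n, 2) array")
        if spots.shape[0] < 1:
            raise InvalidParameterError("a pattern needs at least one spot")
        if not np.isfinite(spots).all():
            raise InvalidParameterError("spot coordinates must be finite")
        object.__setattr__(self, "spots", spots)

    @property
    def n_spots(self) -> int:
        return int(self.spots.shape[0])

    def subsample(self, keep: np.ndarray) -> "SpotPattern":
        """Return a pattern restricted to the given index array."""
        roles = None if self.roles is None else self.roles[keep]
        return SpotPattern(self.region, self.spots[keep], self.provenance, roles)
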