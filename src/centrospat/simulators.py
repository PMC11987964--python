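"""Synthetic spot-pattern generators.

Nine spatial models generate point patterns inside a circular nucleus,
spanning the qualitative regimes seen in centromere imaging data:

========  ==========================================================
id        pattern
========  ==========================================================
CSR       complete spatial randomness (homogeneous Poisson)
PDS       Poisson disk sampling (hard-core minimum spacing)
UTA       uniform spots with 15 two-spot adjacencies (seed+companion)
UTHA      uniform spots with 15 three-spot adjacencies
S2DG      single 2D Gaussian cluster at the nucleus center
T2DG      two-mode 2D Gaussian mixture (modes +/-25 px of center)
TH2DG     three-mode 2D Gaussian mixture
2DGNB     central Gaussian with a central nuclear-body exclusion disk
T2DGTNB   two Gaussians, each with a nuclear-body exclusion disk
========  ==========================================================

All samplers take a :class:`numpy.random.Generator` (or an integer seed) and
are bit-reproducible.  Rejection sampling against the circular boundary has a
hard attempt budget; exhausting it raises
:class:`~centrospat.core.InfeasiblePackingError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_REGION,
    InfeasiblePackingError,
    InvalidParameterError,
    NucleusRegion,
    SpotPattern,
)

MODEL_IDS = (
    "CSR",
    "PDS",
    "UTA",
    "UTHA",
    "S2DG",
    "T2DG",
    "TH2DG",
    "2DGNB",
    "T2DGTNB",
)

#: Per-pattern rejection-sampling attempt budget.
MAX_ATTEMPTS = 1_000_000

#: Covariance-size grid swept by the Gaussian models: 50..1000 px^2 in
#: increments of 50.
COV_SIZE_GRID = np.arange(50.0, 1000.0 + 1e-9, 50.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_covariance(size, theta: float, size_y: float | None = None) -> np.ndarray:
    """Rotated 2x2 covariance matrix ``R @ diag(sx2, sy2) @ R.T``.

    Parameters
    ----------
    size : float
        Principal variance sigma_x^2 in px^2 (the only variance if
        ``size_y`` is omitted, giving an isotropic matrix).
    theta : float
        Rotation angle of the principal axes, radians in [0, pi).
    size_y : float, optional
        Second principal variance sigma_y^2; defaults to ``size``.
    """
    sx2 = float(size)
    sy2 = sx2 if size_y is None else float(size_y)
    if sx2 <= 0 or sy2 <= 0:
        raise InvalidParameterError(f"variances must be > 0, got {sx2}, {sy2}")
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([sx2, sy2]) @ rot.T


@dataclass(frozen=True)
class CovarianceSpec:
    """One component's covariance: principal variances (px^2) and tilt."""

    size: float
    theta: float = 0.0
    size_y: float | None = None

    def matrix(self) -> np.ndarray:
        return build_covariance(self.size, self.theta, self.size_y)


@dataclass(frozen=True)
class NuclearBody:
    """Exclusion disk (e.g. a nucleolus) inside which no spot may fall."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius < 0:
            raise InvalidParameterError("body radius must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic pattern model.

    Defaults mirror the simulated-nucleus study conditions: 46 spots per
    pattern (the diploid human centromere count), 10 px hard-core distance
    for PDS, 15 perturbed seeds with +/-3 px shifts for UTA/UTHA, Gaussian
    modes offset 25 px from the nucleus center, and per-pattern covariances
    drawn from the 50-1000 px^2 grid with orientation uniform on [0, pi).
    """

    model: str
    n_spots: int = 46
    min_dist: float = 10.0
    n_perturbed: int = 15
    shift_range: float = 3.0
    mode_offsets: tuple[tuple[float, float], ...] | None = None
    weights: tuple[float, ...] | None = None
    body_radius: float = 15.0
    cov_size_range: tuple[float, float] = (50.0, 1000.0)
    cov_size_step: float = 50.0
    region: NucleusRegion = DEFAULT_REGION

    def __post_init__(self):
        if self.model not in MODEL_IDS:
            raise InvalidParameterError(f"unknown model id {self.model!r}")
        if self.n_spots < 1:
            raise InvalidParameterError("n_spots must be >= 1")
        if self.n_perturbed > self.n_spots:
            raise InvalidParameterError("n_perturbed must be <= n_spots")
        if self.weights is not None and abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvalidParameterError("component weights must sum to 1")

    def mode_means(self) -> np.ndarray:
        """Absolute component means for the Gaussian models."""
        cx, cy = self.region.center
        if self.mode_offsets is not None:
            offs = np.asarray(self.mode_offsets, dtype=float)
        elif self.model in ("S2DG", "2DGNB"):
            offs = np.array([[0.0, 0.0]])
        elif self.model in ("T2DG", "T2DGTNB"):
            offs = np.array([[0.0, -25.0], [0.0, 25.0]])
        elif self.model == "TH2DG":
            offs = np.array([[0.0, -25.0], [0.0, 25.0], [-25.0, 0.0]])
        else:
            raise InvalidParameterError(f"{self.model} has no Gaussian modes")
        return np.array([cx, cy]) + offs

    def bodies(self) -> tuple[NuclearBody, ...]:
        """Default nuclear-body disks: one per Gaussian mode, radius 15 px."""
        if self.model == "2DGNB":
            return (NuclearBody(tuple(self.region.center), self.body_radius),)
        if self.model == "T2DGTNB":
            return tuple(
                NuclearBody((m[0], m[1]), self.body_radius) for m in self.mode_means()
            )
        return ()

    def draw_cov_specs(self, k: int, rng: np.random.Generator) -> list[CovarianceSpec]:
        """Per-component covariance draws for one pattern."""
        lo, hi = self.cov_size_range
        grid = np.arange(lo, hi + 1e-9, self.cov_size_step)
        specs = []
        for _ in range(k):
            sx2, sy2 = rng.choice(grid, size=2)
            theta = rng.uniform(0.0, np.pi)
            specs.append(CovarianceSpec(float(sx2), float(theta), float(sy2)))
        return specs


def _uniform_in_region(region: NucleusRegion, n: int, rng, batch: int = 256):
    """Yield n uniform points inside the region by box rejection."""
    xmin, xmax, ymin, ymax = region.bounding_box()
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        m = min(batch, 4 * (n - got) + 16)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        attempts += m
        good = cand[region.contains(cand)]
        take = min(len(good), n - got)
        out[got : got + take] = good[:take]
        got += take
        if attempts > MAX_ATTEMPTS:
            raise InfeasiblePackingError(
                f"uniform sampling exhausted {MAX_ATTEMPTS} attempts", got
            )
    return out


def sample_csr(region: NucleusRegion, n: int = 46, seed=None) -> SpotPattern:
    """Complete spatial randomness: n iid uniform points in the region."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = _as_rng(seed)
    return SpotPattern(region, _uniform_in_region(region, n, rng), "CSR")


def sample_pds(
    region: NucleusRegion, n: int = 46, min_dist: float = 10.0, seed=None
) -> SpotPattern:
    """Poisson disk sampling: uniform candidates, hard-core spacing.

    Candidates are drawn uniformly in the region and accepted only if at
    least ``min_dist`` from every already-retained spot (dart throwing).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if min_dist < 0:
        raise InvalidParameterError("min_dist must be >= 0")
    rng = _as_rng(seed)
    xmin, xmax, ymin, ymax = region.bounding_box()
    pts = np.empty((n, 2))
    got = 0
    attempts = 0
    d2 = min_dist * min_dist
    while got < n:
        m = 64
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        inside = region.contains(cand)
        attempts += m
        for p, ok in zip(cand, inside):
            if not ok:
                continue
            if got and (((pts[:got] - p) ** 2).sum(axis=1) < d2).any():
                continue
            pts[got] = p
            got += 1
            if got == n:
                break
        if attempts > MAX_ATTEMPTS:
            raise InfeasiblePackingError(
                f"placed {got}/{n} spots at min_dist={min_dist} before the "
                f"{MAX_ATTEMPTS}-attempt budget ran out",
                got,
            )
    return SpotPattern(region, pts, "PDS")


def sample_uniform_with_adjacent(
    region: NucleusRegion,
    n: int = 46,
    n_perturbed: int = 15,
    companions_per_seed: int = 1,
    shift_range: float = 3.0,
    seed=None,
) -> SpotPattern:
    """Uniform pattern with small multi-spot adjacencies (UTA/UTHA).

    ``n_perturbed`` uniform seed spots each receive ``companions_per_seed``
    companions displaced by a shift drawn uniformly from
    [-shift_range, shift_range] per axis (resampled if it lands outside the
    nucleus).  Companions are interleaved directly after their seed so the
    first-n truncation retains whole multiplets; the remainder of the pattern
    is filled with independent uniform spots.
    """
    if shift_range <= 0:
        raise InvalidParameterError("shift_range must be > 0")
    if companions_per_seed not in (1, 2):
        raise InvalidParameterError("companions_per_seed must be 1 or 2")
    if n_perturbed > n:
        raise InvalidParameterError("n_perturbed must be <= n")
    rng = _as_rng(seed)
    pts: list[np.ndarray] = []
    roles: list[str] = []
    for i in range(n_perturbed):
        s = _uniform_in_region(region, 1, rng)[0]
        pts.append(s)
        roles.append(f"seed:{i}")
        for _ in range(companions_per_seed):
            for _ in range(10_000):
                c = s + rng.uniform(-shift_range, shift_range, 2)
                if region.contains(c[None, :])[0]:
                    break
            else:  # pragma: no cover - shift box always overlaps the region
                raise InfeasiblePackingError("companion placement failed", len(pts))
            pts.append(c)
            roles.append(f"companion:{i}")
    n_fill = max(0, n - len(pts))
    if n_fill:
        for p in _uniform_in_region(region, n_fill, rng):
            pts.append(p)
            roles.append("single")
    name = "UTA" if companions_per_seed == 1 else "UTHA"
    return SpotPattern(
        region, np.array(pts[:n]), name, np.array(roles[:n], dtype=object)
    )


def _mixture_points(
    region: NucleusRegion,
    n: int,
    means: np.ndarray,
    covs: list[np.ndarray],
    weights: np.ndarray,
    rng,
    bodies: tuple[NuclearBody, ...] = (),
):
    """First n mixture draws inside the region and outside every body disk."""
    chols = [np.linalg.cholesky(c) for c in covs]
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        m = 4 * (n - got) + 16
        comp = rng.choice(len(weights), size=m, p=weights)
        z = rng.standard_normal((m, 2))
        cand = np.empty((m, 2))
        for k in range(len(weights)):
            sel = comp == k
            cand[sel] = means[k] + z[sel] @ chols[k].T
        ok = region.contains(cand)
        for b in bodies:
            d2 = ((cand - np.asarray(b.center)) ** 2).sum(axis=1)
            ok &= d2 > b.radius**2
        good = cand[ok]
        take = min(len(good), n - got)
        out[got : got + take] = good[:take]
        got += take
        attempts += m
        if attempts > MAX_ATTEMPTS:
            raise InfeasiblePackingError(
                f"mixture sampling accepted {got}/{n} points in "
                f"{MAX_ATTEMPTS} attempts (bodies may cover the support)",
                got,
            )
    return out


def sample_gaussian_mixture(
    region: NucleusRegion,
    n: int,
    means,
    cov_specs: list[CovarianceSpec],
    weights=None,
    seed=None,
    provenance: str = "GMM",
) -> SpotPattern:
    """Draw the first n in-region points from a 2D Gaussian mixture."""
    rng = _as_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k = len(means)
    if len(cov_specs) != k:
        raise InvalidParameterError("one covariance spec per component required")
    if not region.contains(means).all():
        raise InvalidParameterError("all mode means must lie inside the region")
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != k or abs(w.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("weights must match components and sum to 1")
    covs = [cs.matrix() for cs in cov_specs]
    pts = _mixture_points(region, n, means, covs, w, rng)
    return SpotPattern(region, pts, provenance)


def sample_gaussian_with_bodies(
    region: NucleusRegion,
    n: int,
    means,
    cov_specs: list[CovarianceSpec],
    bodies: tuple[NuclearBody, ...],
    weights=None,
    seed=None,
    provenance: str = "GMM+NB",
) -> SpotPattern:
    """Gaussian mixture with nuclear-body exclusion disks."""
    rng = _as_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k = len(means)
    if len(cov_specs) != k:
        raise InvalidParameterError("one covariance spec per component required")
    for b in bodies:
        if not region.contains(np.asarray(b.center)[None, :])[0]:
            raise InvalidParameterError("body disks must lie inside the region")
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    covs = [cs.matrix() for cs in cov_specs]
    pts = _mixture_points(region, n, means, covs, w, rng, bodies=tuple(bodies))
    return SpotPattern(region, pts, provenance)


def sample_pattern(config: GeneratorConfig, rng) -> SpotPattern:
    """One pattern from the configured model (covariances redrawn per call)."""
    rng = _as_rng(rng)
    m = config.model
    if m == "CSR":
        return sample_csr(config.region, config.n_spots, rng)
    if m == "PDS":
        return sample_pds(config.region, config.n_spots, config.min_dist, rng)
    if m in ("UTA", "UTHA"):
        return sample_uniform_with_adjacent(
            config.region,
            config.n_spots,
            config.n_perturbed,
            1 if m == "UTA" else 2,
            config.shift_range,
            rng,
        )
    means = config.mode_means()
    specs = config.draw_cov_specs(len(means), rng)
    if m in ("S2DG", "T2DG", "TH2DG"):
        return sample_gaussian_mixture(
            config.region, config.n_spots, means, specs, config.weights, rng, m
        )
    return sample_gaussian_with_bodies(
        config.region,
        config.n_spots,
        means,
        specs,
        config.bodies(),
        config.weights,
        rng,
        m,
    )


def generate_dataset(
    config: GeneratorConfig, n_patterns: int, seed=None
) -> list[SpotPattern]:
    """Generate ``n_patterns`` independent patterns; reproducible from seed."""
    if n_patterns < 1:
        raise InvalidParameterError("n_patterns must be >= 1")
    rng = _as_rng(seed)
    return [sample_pattern(config, rng) for _ in range(n_patterns)]


def default_configs(region: NucleusRegion = DEFAULT_REGION) -> dict[str, GeneratorConfig]:
    """The nine study configurations keyed by model id."""
    return {m: GeneratorConfig(model=m, region=region) for m in MODEL_IDS}


def multiplet_census(pattern: SpotPattern) -> dict[int, int]:
    """Count retained seed-companion multiplets by size (UTA/UTHA only)."""
    if pattern.roles is None:
        return {}
    sizes: dict[str, int] = {}
    for role in pattern.roles:
        if role == "single":
            continue
        key = role.split(":")[1]
        sizes[key] = sizes.get(key, 0) + 1
    census: dict[int, int] = {}
    for c in sizes.values():
        census[c] = census.get(c, 0) + 1
    return census
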