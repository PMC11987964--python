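"""Generative models of centromere localization and their estimators.

Five models describe where spots fall inside a nucleus:

* **M1** — uniform (complete spatial randomness); no parameters.
* **M2** — elliptical Gaussian shaped by the nucleus: an ellipse with
  semi-axes (a, b) is fitted to the nucleus mask and spots are drawn from a
  centered Gaussian with sigma_x = a/3, sigma_y = b/3.
* **M3** — centered radial Gaussian; its single sigma is estimated by
  least-squares fitting the closed-form pairwise-distance CDF
  ``F(d) = 1 - exp(-d^2 / 4 sigma^2)`` to the empirical CDF.
* **M4** — radially *shifted* Gaussian (a doughnut: radius ~ N(r0, sigma),
  angle uniform) with (r0, sigma) estimated by Metropolis-Hastings MCMC on
  the exact Gaussian likelihood of the observed radial distances.
* **M5** — the same doughnut, but fitted to observed *pairwise* distances:
  the pairwise-distance density has no closed form and is tabulated by Monte
  Carlo inside every likelihood evaluation.

M4 and M5 follow the statsmodels convention: a model object built from data
whose :meth:`fit` returns a results object carrying the posterior draws,
their summaries, and a :meth:`~RadialGaussianResults.summary` table.

Radial distances are normalized by each cell's equivalent nucleus radius
before pooling, so nuclei of different sizes share one (r0, sigma) in
normalized units; simulation rescales per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from skimage.measure import regionprops, label as sk_label

from .core import (
    DEFAULT_REGION,
    Ellipse,
    InvalidParameterError,
    NucleusRegion,
    SpotPattern,
)
from .simulators import _as_rng, _uniform_in_region, sample_csr

MODEL_IDS_M = ("M1", "M2", "M3", "M4", "M5")

#: Log-likelihood floor for pairwise distances that fall in zero-mass bins
#: of the Monte Carlo density table.
LOGLIK_FLOOR = -1e10


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialGaussianParams:
    """Doughnut parameters: mean radius r0 and radial SD sigma."""

    r0: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")
        if self.r0 < 0:
            raise InvalidParameterError("r0 must be >= 0")


@dataclass(frozen=True)
class PriorSpec:
    """Independent Normal priors on r0 and sigma (means and variances)."""

    mu_r0: float
    var_r0: float
    mu_sigma: float
    var_sigma: float

    def __post_init__(self):
        if self.var_r0 <= 0 or self.var_sigma <= 0:
            raise InvalidParameterError("prior variances must be > 0")

    @classmethod
    def from_radii(cls, radii: np.ndarray) -> "PriorSpec":
        """Weakly informative default: r0 prior at the mean observed radius
        with SD half that mean; sigma prior at the radii SD with equal SD."""
        radii = np.asarray(radii, dtype=float)
        mu = float(radii.mean())
        sd = float(radii.std(ddof=1)) if radii.size > 1 else max(mu / 2, 1e-3)
        sd = max(sd, 1e-3)
        return cls(mu_r0=mu, var_r0=(mu / 2) ** 2, mu_sigma=sd, var_sigma=sd**2)

    def logpdf(self, r0: float, sigma: float) -> float:
        return float(
            -0.5 * (r0 - self.mu_r0) ** 2 / self.var_r0
            - 0.5 * (sigma - self.mu_sigma) ** 2 / self.var_sigma
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Random-walk Metropolis settings.

    Step sizes of ``None`` trigger a pilot phase that doubles/halves the
    steps until the acceptance rate lands near 30%.
    """

    n_iter: int = 5000
    burn_in: int = 1000
    step_r0: float | None = None
    step_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise InvalidParameterError("require 0 <= burn_in < n_iter")
        for s in (self.step_r0, self.step_sigma):
            if s is not None and s <= 0:
                raise InvalidParameterError("step sizes must be > 0")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws and chain diagnostics."""

    draws: np.ndarray  # (n_kept, d)
    log_posterior: np.ndarray  # (n_kept,)
    acceptance_rate: float
    steps: tuple[float, ...]
    param_names: tuple[str, ...] = ("r0", "sigma")

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "iteration", np.arange(len(df)))
        df["log_posterior"] = self.log_posterior
        return df


# ---------------------------------------------------------------------------
# closed forms and likelihoods
# ---------------------------------------------------------------------------

def analytic_radial_k(r, sigma: float, c: float = 1.0, lam: float = 1.0):
    """Closed-form K(r) of a centered radial Gaussian: (C/lam)(1 - e^{-r^2/2s^2})."""
    if sigma <= 0 or lam <= 0:
        raise InvalidParameterError("sigma and lam must be > 0")
    r = np.asarray(r, dtype=float)
    return (c / lam) * (1.0 - np.exp(-(r**2) / (2.0 * sigma**2)))


def centered_pairwise_cdf(d, sigma: float):
    """Pairwise-distance CDF of a centered 2D Gaussian with SD sigma per axis.

    The difference of two independent centered Gaussians is centered with
    doubled variance, so the inter-point distance is Rayleigh(sigma*sqrt(2))
    and F(d) = 1 - exp(-d^2 / 4 sigma^2).
    """
    d = np.asarray(d, dtype=float)
    return 1.0 - np.exp(-(d**2) / (4.0 * sigma**2))


def radial_loglik(radii, r0: float, sigma: float) -> float:
    """Exact Gaussian log-likelihood of radial distances; -inf for sigma <= 0."""
    if sigma <= 0:
        return -np.inf
    r = np.asarray(radii, dtype=float)
    n = r.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma**2)
        - 0.5 * np.sum((r - r0) ** 2) / sigma**2
    )


def log_posterior(radii, r0: float, sigma: float, prior: PriorSpec) -> float:
    """Unnormalized log posterior: radial log-likelihood plus Normal log-priors."""
    ll = radial_loglik(radii, r0, sigma)
    if not np.isfinite(ll):
        return -np.inf
    return ll + prior.logpdf(r0, sigma)


def pairwise_distance_pdf_mc(
    params: RadialGaussianParams,
    n_mc: int = 100_000,
    n_bins: int = 200,
    seed=None,
    _z=None,
):
    """Monte Carlo pairwise-distance density of the doughnut model.

    Draws r1, r2 ~ N(r0, sigma) (negative draws discarded), the angle
    difference uniform on [0, 2pi), forms d = sqrt(r1^2 + r2^2 - 2 r1 r2
    cos(dtheta)), and histograms d on ``n_bins`` equal bins spanning
    [0, 2 (r0 + 4 sigma)].  Returns ``(edges, density)`` with the density
    integrating to 1 over the grid.
    """
    if n_mc < 10_000:
        raise InvalidParameterError("n_mc must be >= 10^4")
    if _z is None:
        rng = _as_rng(seed)
        z1 = rng.standard_normal(n_mc)
        z2 = rng.standard_normal(n_mc)
        cos_u = np.cos(rng.uniform(0.0, 2.0 * np.pi, n_mc))
    else:
        z1, z2, cos_u = _z
    r1 = params.r0 + params.sigma * z1
    r2 = params.r0 + params.sigma * z2
    ok = (r1 >= 0) & (r2 >= 0)
    r1, r2 = r1[ok], r2[ok]
    d = np.sqrt(np.maximum(r1**2 + r2**2 - 2.0 * r1 * r2 * cos_u[ok], 0.0))
    hi = 2.0 * (params.r0 + 4.0 * params.sigma)
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    return edges, density


def pairwise_loglik(distances, edges: np.ndarray, density: np.ndarray) -> float:
    """Sum of log densities of observed distances on a tabulated grid.

    Distances landing in zero-mass bins (or off the grid) each contribute the
    -1e10 floor instead of -inf, keeping the MCMC acceptance ratio finite.
    """
    d = np.asarray(distances, dtype=float)
    idx = np.searchsorted(edges, d, side="right") - 1
    inside = (idx >= 0) & (idx < len(density))
    p = np.zeros(d.size)
    p[inside] = density[idx[inside]]
    out = np.full(d.size, LOGLIK_FLOOR)
    pos = p > 0
    out[pos] = np.log(p[pos])
    return float(out.sum())


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------

def metropolis_hastings(
    log_post_fn,
    init,
    config: MCMCConfig,
    steps=None,
    lower_bounds=None,
    param_names=("r0", "sigma"),
) -> PosteriorSamples:
    """Gaussian random-walk Metropolis sampler.

    Proposals below ``lower_bounds`` are rejected outright (used to keep
    sigma positive).  When ``steps`` is None a pilot phase of 200-iteration
    rounds rescales the step vector toward ~30% acceptance before the main
    chain runs.
    """
    x = np.atleast_1d(np.asarray(init, dtype=float))
    d = x.size
    lo = np.full(d, -np.inf) if lower_bounds is None else np.asarray(lower_bounds)
    lp = log_post_fn(x)
    if not np.isfinite(lp):
        raise InvalidParameterError("log posterior must be finite at init")
    rng = np.random.default_rng(config.seed)

    if steps is None:
        cfg_steps = (config.step_r0, config.step_sigma)[:d]
        if all(s is not None for s in cfg_steps):
            steps = np.asarray(cfg_steps, dtype=float)
        else:
            steps = np.maximum(0.1 * np.abs(x), 0.05)
            for _ in range(8):
                acc, x, lp = _mh_run(log_post_fn, x, lp, steps, lo, 200, rng)[:3]
                if 0.2 <= acc <= 0.45:
                    break
                steps = steps * (0.5 if acc < 0.2 else 2.0)
    else:
        steps = np.asarray(steps, dtype=float)

    acc, x, lp, chain, lps = _mh_run(
        log_post_fn, x, lp, steps, lo, config.n_iter, rng, record=True
    )
    if acc == 0.0:
        warnings.warn("MCMC accepted no proposals; check step sizes", RuntimeWarning)
    keep = slice(config.burn_in, None)
    return PosteriorSamples(
        draws=chain[keep],
        log_posterior=lps[keep],
        acceptance_rate=acc,
        steps=tuple(float(s) for s in steps),
        param_names=tuple(param_names[:d]),
    )


def _mh_run(log_post_fn, x, lp, steps, lo, n, rng, record=False):
    d = x.size
    chain = np.empty((n, d)) if record else None
    lps = np.empty(n) if record else None
    n_acc = 0
    for i in range(n):
        prop = x + steps * rng.standard_normal(d)
        if np.all(prop >= lo):
            lp_prop = log_post_fn(prop)
            if lp_prop - lp > np.log(rng.uniform()):
                x, lp = prop, lp_prop
                n_acc += 1
        if record:
            chain[i] = x
            lps[i] = lp
    return n_acc / n, x, lp, chain, lps


# ---------------------------------------------------------------------------
# Model / Results objects (M3, M4, M5)
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    """Portable fit record consumed by :func:`generate_from_model`."""

    model: str
    params: dict[str, float] = field(default_factory=dict)
    normalized: bool = True
    diagnostics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODEL_IDS_M:
            raise InvalidParameterError(f"unknown model id {self.model!r}")


class RadialGaussianResults:
    """Posterior summary for the doughnut models (M4/M5).

    Attributes
    ----------
    params : ndarray
        Posterior means of (r0, sigma), in normalized units when the model
        pooled radius-normalized data.
    bse : ndarray
        Posterior standard deviations.
    samples : PosteriorSamples
        The retained chain.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self.params = samples.mean()
        self.bse = samples.sd()

    @property
    def r0(self) -> float:
        return float(self.params[0])

    @property
    def sigma(self) -> float:
        return float(self.params[1])

    @property
    def acceptance_rate(self) -> float:
        return self.samples.acceptance_rate

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        q = [(1 - level) / 2, 1 - (1 - level) / 2]
        return np.quantile(self.samples.draws, q, axis=0).T

    def to_model_fit(self) -> ModelFitResult:
        return ModelFitResult(
            model=self.model.model_id,
            params={"r0": self.r0, "sigma": self.sigma},
            normalized=self.model.normalized,
            diagnostics={"acceptance_rate": self.acceptance_rate},
        )

    def summary(self) -> str:
        ci = self.credible_interval()
        lines = [
            f"{self.model.model_id}: radially shifted Gaussian "
            f"({'normalized' if self.model.normalized else 'pixel'} units)",
            f"{'param':>8} {'mean':>10} {'sd':>10} {'2.5%':>10} {'97.5%':>10}",
        ]
        for name, m, s, (lo, hi) in zip(
            self.samples.param_names, self.params, self.bse, ci
        ):
            lines.append(f"{name:>8} {m:10.4f} {s:10.4f} {lo:10.4f} {hi:10.4f}")
        lines.append(
            f"n_draws={len(self.samples.draws)}  "
            f"acceptance={self.acceptance_rate:.2f}  steps={self.samples.steps}"
        )
        return "\n".join(lines)


class RadialGaussianModel:
    """M4: Bayesian doughnut model fitted to per-cell radial distances.

    Parameters
    ----------
    radii_per_cell : sequence of 1D arrays
        Radial distance of each spot to its nucleus center, one array per
        cell, in pixels.
    cell_radii : sequence of float, optional
        Equivalent nucleus radius per cell; when given, radii are divided by
        it before pooling (recommended whenever nuclei differ in size).
    prior : PriorSpec, optional
        Defaults to :meth:`PriorSpec.from_radii` on the pooled data.
    """

    model_id = "M4"

    def __init__(self, radii_per_cell, cell_radii=None, prior: PriorSpec | None = None):
        radii_per_cell = [np.asarray(r, dtype=float) for r in radii_per_cell]
        if len(radii_per_cell) < 1:
            raise InvalidParameterError("need at least one cell")
        if cell_radii is not None:
            cell_radii = np.asarray(cell_radii, dtype=float)
            radii_per_cell = [r / s for r, s in zip(radii_per_cell, cell_radii)]
        self.normalized = cell_radii is not None
        self.pooled = np.concatenate(radii_per_cell)
        self.prior = prior if prior is not None else PriorSpec.from_radii(self.pooled)

    def loglike(self, params) -> float:
        return radial_loglik(self.pooled, params[0], params[1])

    def fit(self, mcmc: MCMCConfig = MCMCConfig()) -> RadialGaussianResults:
        prior = self.prior

        def lp(x):
            return log_posterior(self.pooled, x[0], x[1], prior)

        init = np.array([prior.mu_r0, prior.mu_sigma])
        samples = metropolis_hastings(lp, init, mcmc, lower_bounds=(0.0, 1e-9))
        return RadialGaussianResults(self, samples)


class PairwiseRadialGaussianModel:
    """M5: Bayesian doughnut model fitted to per-cell pairwise distances.

    The likelihood of each proposed (r0, sigma) is evaluated against a Monte
    Carlo table of the pairwise-distance density (common random numbers are
    reused across evaluations so the noisy likelihood stays coherent along
    the chain).
    """

    model_id = "M5"

    def __init__(
        self,
        distances_per_cell,
        cell_radii=None,
        prior: PriorSpec | None = None,
        n_mc: int = 100_000,
        n_bins: int = 200,
        mc_seed: int = 12345,
    ):
        distances_per_cell = [np.asarray(d, dtype=float) for d in distances_per_cell]
        if len(distances_per_cell) < 1:
            raise InvalidParameterError("need at least one cell")
        if cell_radii is not None:
            cell_radii = np.asarray(cell_radii, dtype=float)
            distances_per_cell = [
                d / s for d, s in zip(distances_per_cell, cell_radii)
            ]
        self.normalized = cell_radii is not None
        self.pooled = np.concatenate(distances_per_cell)
        if prior is None:
            # pairwise distances of a doughnut concentrate near ~sqrt(2) r0;
            # recover a crude radial scale for the default prior
            scale = float(self.pooled.mean()) / np.sqrt(2.0)
            spread = max(float(self.pooled.std(ddof=1)) / np.sqrt(2.0), 1e-3)
            prior = PriorSpec(scale, (scale / 2) ** 2, spread, spread**2)
        self.prior = prior
        self.n_mc = n_mc
        self.n_bins = n_bins
        rng = np.random.default_rng(mc_seed)
        self._z = (
            rng.standard_normal(n_mc),
            rng.standard_normal(n_mc),
            np.cos(rng.uniform(0.0, 2.0 * np.pi, n_mc)),
        )

    def loglike(self, params) -> float:
        if params[1] <= 0 or params[0] < 0:
            return -np.inf
        edges, density = pairwise_distance_pdf_mc(
            RadialGaussianParams(params[0], params[1]),
            n_mc=self.n_mc,
            n_bins=self.n_bins,
            _z=self._z,
        )
        return pairwise_loglik(self.pooled, edges, density)

    def fit(self, mcmc: MCMCConfig = MCMCConfig()) -> RadialGaussianResults:
        prior = self.prior

        def lp(x):
            ll = self.loglike(x)
            if not np.isfinite(ll):
                return -np.inf
            return ll + prior.logpdf(x[0], x[1])

        init = np.array([prior.mu_r0, prior.mu_sigma])
        samples = metropolis_hastings(lp, init, mcmc, lower_bounds=(0.0, 1e-9))
        return RadialGaussianResults(self, samples)


class CenteredRadialResults:
    """Least-squares fit of the centered radial Gaussian CDF (M3)."""

    def __init__(self, model, sigma, resid_norm, success):
        self.model = model
        self.sigma = float(sigma)
        self.params = np.array([self.sigma])
        self.resid_norm = float(resid_norm)
        self.success = bool(success)

    def to_model_fit(self) -> ModelFitResult:
        return ModelFitResult(
            model="M3",
            params={"sigma": self.sigma},
            normalized=self.model.normalized,
            diagnostics={"resid_norm": self.resid_norm},
        )

    def summary(self) -> str:
        return (
            "M3: centered radial Gaussian (pairwise-CDF fit)\n"
            f"   sigma = {self.sigma:.4f} "
            f"({'normalized' if self.model.normalized else 'pixel'} units), "
            f"residual norm {self.resid_norm:.4g}"
        )


class CenteredRadialModel:
    """M3: centered radial Gaussian fitted to pairwise-distance CDFs."""

    model_id = "M3"

    def __init__(self, distances_per_cell, cell_radii=None, n_grid: int = 200):
        distances_per_cell = [np.asarray(d, dtype=float) for d in distances_per_cell]
        if cell_radii is not None:
            cell_radii = np.asarray(cell_radii, dtype=float)
            distances_per_cell = [
                d / s for d, s in zip(distances_per_cell, cell_radii)
            ]
        self.normalized = cell_radii is not None
        self.pooled = np.sort(np.concatenate(distances_per_cell))
        if self.pooled.size < 10:
            raise InvalidParameterError("need at least 10 pairwise distances")
        self.grid = np.linspace(0.0, self.pooled[-1], n_grid)
        self.ecdf = np.searchsorted(self.pooled, self.grid, side="right") / self.pooled.size

    def fit(self) -> CenteredRadialResults:
        # F(d) = 0.5 at d = 2 sigma sqrt(ln 2): a robust starting value
        med = float(np.median(self.pooled))
        s0 = med / (2.0 * np.sqrt(np.log(2.0)))

        def resid(s):
            return centered_pairwise_cdf(self.grid, s[0]) - self.ecdf

        sol = optimize.least_squares(resid, x0=[s0], bounds=([1e-9], [np.inf]))
        if not sol.success:
            raise InvalidParameterError(f"M3 CDF fit failed: {sol.message}")
        return CenteredRadialResults(self, sol.x[0], np.linalg.norm(sol.fun), sol.success)


def fit_m3(pairwise_distances, cell_radii=None) -> CenteredRadialResults:
    """Convenience wrapper: fit M3 to one or more cells' pairwise distances."""
    if np.ndim(pairwise_distances[0]) == 0:
        pairwise_distances = [pairwise_distances]
    return CenteredRadialModel(pairwise_distances, cell_radii).fit()


def fit_m4(
    radii_per_cell,
    cell_radii=None,
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
) -> RadialGaussianResults:
    """Fit the coordinate-based doughnut model (M4)."""
    return RadialGaussianModel(radii_per_cell, cell_radii, prior).fit(mcmc)


def fit_m5(
    distances_per_cell,
    cell_radii=None,
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
    n_mc: int = 100_000,
    n_bins: int = 200,
) -> RadialGaussianResults:
    """Fit the pairwise-distance doughnut model (M5)."""
    return PairwiseRadialGaussianModel(
        distances_per_cell, cell_radii, prior, n_mc=n_mc, n_bins=n_bins
    ).fit(mcmc)


# ---------------------------------------------------------------------------
# geometry-driven samplers (M2) and the doughnut sampler (M3-M5)
# ---------------------------------------------------------------------------

def fit_ellipse_to_mask(mask: np.ndarray):
    """Moment-equivalent ellipse of a binary mask.

    Returns ``(center, a, b, angle)`` with semi-axes a >= b in px and the
    major-axis angle in radians measured from the +x image axis.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise InvalidParameterError("mask too small for an ellipse fit")
    props = regionprops(sk_label(mask))[0]
    cy, cx = props.centroid
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    if b <= 0:
        raise InvalidParameterError("degenerate mask: zero minor axis")
    # regionprops orientation is measured from the row (y) axis, clockwise
    angle = np.pi / 2.0 - props.orientation
    return (float(cx), float(cy)), float(a), float(b), float(angle % np.pi)


def region_from_mask(mask: np.ndarray, label_value=None, pixel_size=0.108) -> NucleusRegion:
    """Build a NucleusRegion (equivalent radius + moment ellipse) from a mask."""
    mask = np.asarray(mask).astype(bool)
    center, a, b, angle = fit_ellipse_to_mask(mask)
    radius = float(np.sqrt(mask.sum() / np.pi))
    return NucleusRegion(
        center=center,
        radius=radius,
        ellipse=Ellipse(a, b, angle),
        mask=mask,
        pixel_size=pixel_size,
        label=label_value,
    )


def sample_m2(region: NucleusRegion, n: int, seed=None) -> SpotPattern:
    """Nucleus-shaped Gaussian: sigma_x = a/3, sigma_y = b/3 along the ellipse
    axes, centered on the nucleus, truncated to the nucleus boundary.

    Circular regions without a fitted ellipse use a = b = radius.
    """
    rng = _as_rng(seed)
    if region.ellipse is None:
        a = b = region.radius
        phi = 0.0
    else:
        a, b, phi = region.ellipse.a, region.ellipse.b, region.ellipse.phi
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = 4 * (n - got) + 16
        z = rng.standard_normal((m, 2)) * np.array([a / 3.0, b / 3.0])
        cand = np.asarray(region.center) + z @ rot.T
        good = cand[region.contains(cand)]
        take = min(len(good), n - got)
        out[got : got + take] = good[:take]
        got += take
    return SpotPattern(region, out, "M2")


def sample_centered_radial_gaussian(
    sigma: float, region: NucleusRegion, n: int, seed=None
) -> SpotPattern:
    """Centered isotropic 2D Gaussian (the M3 model), truncated to the region.

    Its radial coordinate is Rayleigh(sigma) and its pairwise-distance CDF is
    the closed form 1 - exp(-d^2 / 4 sigma^2) fitted by
    :class:`CenteredRadialModel`.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    rng = _as_rng(seed)
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = 4 * (n - got) + 16
        cand = np.asarray(region.center) + sigma * rng.standard_normal((m, 2))
        good = cand[region.contains(cand)]
        take = min(len(good), n - got)
        out[got : got + take] = good[:take]
        got += take
    return SpotPattern(region, out, "M3")


def sample_radially_shifted_gaussian(
    params: RadialGaussianParams, region: NucleusRegion, n: int, seed=None
) -> SpotPattern:
    """Doughnut sampler: radius ~ N(r0, sigma) (>= 0), angle ~ U[0, 2pi),
    about the region center; points outside the region are rejected."""
    rng = _as_rng(seed)
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        m = 4 * (n - got) + 16
        r = params.r0 + params.sigma * rng.standard_normal(m)
        th = rng.uniform(0.0, 2.0 * np.pi, m)
        ok = r >= 0
        cand = np.column_stack(
            [
                region.center[0] + r * np.cos(th),
                region.center[1] + r * np.sin(th),
            ]
        )
        ok &= region.contains(cand)
        good = cand[ok]
        take = min(len(good), n - got)
        out[got : got + take] = good[:take]
        got += take
        attempts += m
        if attempts > 10_000_000:
            raise InvalidParameterError(
                "doughnut sampler rejected too many draws; params incompatible "
                "with the region"
            )
    return SpotPattern(region, out, "doughnut")


def generate_from_model(
    fit: ModelFitResult,
    nuclei: list[NucleusRegion],
    spots_per_cell,
    seed=None,
) -> list[SpotPattern]:
    """Simulate per-cell patterns from a fitted model (M1-M5).

    ``spots_per_cell`` may be a single int or one count per nucleus, so the
    simulated spot counts can match the observed ones.
    """
    rng = _as_rng(seed)
    counts = (
        [int(spots_per_cell)] * len(nuclei)
        if np.ndim(spots_per_cell) == 0
        else [int(c) for c in spots_per_cell]
    )
    if len(counts) != len(nuclei):
        raise InvalidParameterError("one spot count per nucleus required")
    out = []
    for region, n in zip(nuclei, counts):
        scale = region.radius if fit.normalized else 1.0
        if fit.model == "M1":
            pat = sample_csr(region, n, rng)
        elif fit.model == "M2":
            pat = sample_m2(region, n, rng)
        elif fit.model == "M3":
            pat = sample_centered_radial_gaussian(
                fit.params["sigma"] * scale, region, n, rng
            )
        elif fit.model in ("M4", "M5"):
            params = RadialGaussianParams(
                fit.params["r0"] * scale, fit.params["sigma"] * scale
            )
            pat = sample_radially_shifted_gaussian(params, region, n, rng)
        else:  # pragma: no cover
            raise InvalidParameterError(fit.model)
        out.append(SpotPattern(region, pat.spots, fit.model))
    return out
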