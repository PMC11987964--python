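"""Distribution-similarity scoring and the overlay ("doughnut") analysis.

Real and simulated spot populations are compared through their pairwise
spot-to-spot distance distributions and their radial (spot-to-center)
distance distributions, using three scores:

* the 1D Wasserstein distance (L1 distance between empirical CDFs),
* the normalized MSE between density histograms on a shared grid (MSE of
  bin values divided by the population variance of the reference PDF), and
* the two-sample Kolmogorov-Smirnov statistic.

The overlay analysis pools center-shifted spots from many cells into one
field, histograms them in 2D, extracts the X=0 / Y=0 line profiles, and fits
each profile with a two-component 1D Gaussian mixture — the signature of a
radially symmetric "doughnut" is a symmetric pair of profile modes with
near-identical parameters on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.mixture import GaussianMixture

from .core import InsufficientPointsError, InvalidParameterError, SpotPattern
from .models import ModelFitResult, generate_from_model


def pairwise_distances(pattern: SpotPattern) -> np.ndarray:
    """All N(N-1)/2 unordered Euclidean spot-to-spot distances (px)."""
    if pattern.n_spots < 2:
        raise InsufficientPointsError("pairwise distances need >= 2 spots")
    return pdist(pattern.spots)


def radial_distances(
    pattern: SpotPattern, center=None, normalize: bool = False
) -> np.ndarray:
    """Spot-to-center distances, optionally over the equivalent radius."""
    c = np.asarray(center if center is not None else pattern.region.center, float)
    r = np.linalg.norm(pattern.spots - c, axis=1)
    return r / pattern.region.radius if normalize else r


def wasserstein_distance(a, b) -> float:
    """1D Wasserstein distance: integral of |F1 - F2| between the ECDFs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    return float(stats.wasserstein_distance(a, b))


def ks_statistic(a, b) -> float:
    """Two-sample KS statistic: sup |F1 - F2| over the pooled support."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b).statistic)


def normalized_mse(pdf_real, pdf_synth) -> float:
    """Mean squared bin difference over the population variance of the real PDF."""
    pr = np.asarray(pdf_real, dtype=float)
    ps = np.asarray(pdf_synth, dtype=float)
    if pr.shape != ps.shape:
        raise InvalidParameterError("PDFs must share one grid")
    var = pr.var(ddof=0)
    if var == 0:
        raise InvalidParameterError("zero-variance reference PDF: NMSE undefined")
    return float(((pr - ps) ** 2).mean() / var)


def density_histograms(a, b, n_bins: int = 100):
    """Density histograms of two samples on a shared grid over their union range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    return edges, pa, pb


@dataclass(frozen=True)
class SimilarityScores:
    """The three distribution-similarity scores for one comparison."""

    wasserstein: float
    normalized_mse: float
    ks: float


def similarity_scores(real, synth, n_bins: int = 100) -> SimilarityScores:
    """All three scores between a reference sample and a synthetic sample."""
    _, pr, ps = density_histograms(real, synth, n_bins)
    return SimilarityScores(
        wasserstein=wasserstein_distance(real, synth),
        normalized_mse=normalized_mse(pr, ps),
        ks=ks_statistic(real, synth),
    )


# ---------------------------------------------------------------------------
# overlay analysis
# ---------------------------------------------------------------------------

@dataclass
class Gmm1DFit:
    """Two-component 1D Gaussian mixture parameters (sorted by mean)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool
    log_likelihood: float

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.means, self.sds, self.weights])


def fit_1d_gmm2(values, seed: int = 0) -> Gmm1DFit:
    """EM fit of a 2-mode 1D Gaussian mixture (10 seeded k-means++ restarts)."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise InsufficientPointsError("GMM fit needs >= 20 values")
    gm = GaussianMixture(
        n_components=2, n_init=10, random_state=seed, covariance_type="full"
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    return Gmm1DFit(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel())[order],
        weights=gm.weights_[order],
        converged=bool(gm.converged_),
        log_likelihood=float(gm.score(x) * x.shape[0]),
    )


@dataclass
class OverlayField:
    """Pooled center-shifted spots, their 2D histogram, and axis profiles."""

    coords: np.ndarray  # (n, 2) center-shifted
    hist: np.ndarray  # 2D counts, hist[iy, ix]
    edges: np.ndarray  # shared bin edges for both axes
    profile_x: np.ndarray  # counts along x at the y=0 row
    profile_y: np.ndarray  # counts along y at the x=0 column
    gmm_x: Gmm1DFit | None = None
    gmm_y: Gmm1DFit | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])


def overlay_standardize(
    cells: list[SpotPattern],
    bin_width: float = 2.0,
    fit_profiles: bool = False,
    seed: int = 0,
) -> OverlayField:
    """Pool spots across cells with every nuclear center shifted to (0, 0).

    The 2D histogram spans the largest nucleus radius with ``bin_width``-px
    bins; line profiles are the central row (y = 0) and column (x = 0).
    When ``fit_profiles`` is set, 2-mode 1D GMMs are fitted to the x and y
    coordinates of the pooled spots near each axis line.
    """
    if not cells:
        raise InvalidParameterError("need at least one cell")
    shifted = [p.spots - np.asarray(p.region.center) for p in cells]
    coords = np.concatenate(shifted)
    rmax = max(p.region.radius for p in cells)
    n_bins = int(np.ceil(2 * rmax / bin_width))
    half = n_bins * bin_width / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    hist, _, _ = np.histogram2d(coords[:, 1], coords[:, 0], bins=(edges, edges))
    mid = n_bins // 2
    profile_x = hist[mid, :]
    profile_y = hist[:, mid]
    gx = gy = None
    if fit_profiles:
        band = bin_width / 2.0
        near_y0 = np.abs(coords[:, 1]) <= band
        near_x0 = np.abs(coords[:, 0]) <= band
        gx = fit_1d_gmm2(coords[near_y0, 0], seed=seed)
        gy = fit_1d_gmm2(coords[near_x0, 1], seed=seed)
    return OverlayField(coords, hist, edges, profile_x, profile_y, gx, gy)


# ---------------------------------------------------------------------------
# real-vs-model comparison
# ---------------------------------------------------------------------------

def _pooled_distances(cells: list[SpotPattern], normalize: bool):
    pw = np.concatenate([pairwise_distances(p) for p in cells if p.n_spots >= 2])
    rad = np.concatenate([radial_distances(p, normalize=normalize) for p in cells])
    return {"pairwise": pw, "radial": rad}


def compare_real_vs_model(
    observed_cells: list[SpotPattern],
    model_fits: list[ModelFitResult],
    seed=None,
    n_bins: int = 100,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score each fitted model against the observed cells.

    For every model, synthetic cells are simulated on the observed nuclei
    with matching spot counts, then the pooled pairwise and radial distance
    distributions are scored with all three similarity metrics.  Returns a
    long table (model, kind, metric, value, best_in_row) where
    ``best_in_row`` flags the best model for each (kind, metric) pair.
    """
    rng = np.random.default_rng(seed)
    nuclei = [p.region for p in observed_cells]
    counts = [p.n_spots for p in observed_cells]
    ref = _pooled_distances(observed_cells, normalize)
    rows = []
    for fit in model_fits:
        sim_cells = generate_from_model(
            fit, nuclei, counts, rng.integers(2**31)
        )
        sim = _pooled_distances(sim_cells, normalize)
        for kind in ("pairwise", "radial"):
            sc = similarity_scores(ref[kind], sim[kind], n_bins)
            for metric, value in (
                ("wasserstein", sc.wasserstein),
                ("normalized_mse", sc.normalized_mse),
                ("ks", sc.ks),
            ):
                rows.append({"model": fit.model, "kind": kind,
                             "metric": metric, "value": value})
    df = pd.DataFrame(rows)
    df["best_in_row"] = False
    for (_, _), idx in df.groupby(["kind", "metric"]).groups.items():
        best = df.loc[idx, "value"].idxmin()
        df.loc[best, "best_in_row"] = True
    return df


def metric_nmse_table(
    observed_cells: list[SpotPattern],
    model_fits: list[ModelFitResult],
    seed=None,
    n_bins: int = 30,
    settings=None,
) -> pd.DataFrame:
    """Normalized MSE of per-cell clustering-metric distributions per model.

    For each clustering metric, the distribution of per-cell values in the
    observed data is compared (NMSE on a shared histogram grid) with the
    distribution from cells simulated under each model; the per-row minimum
    is flagged.
    """
    from .metrics import MetricSettings, compute_all_metrics

    settings = settings or MetricSettings()
    rng = np.random.default_rng(seed)
    nuclei = [p.region for p in observed_cells]
    counts = [p.n_spots for p in observed_cells]

    def metric_frame(cells):
        recs = [compute_all_metrics(p, settings).as_dict() for p in cells]
        return pd.DataFrame(recs)

    obs = metric_frame(observed_cells)
    rows = []
    for fit in model_fits:
        sim_cells = generate_from_model(fit, nuclei, counts, rng.integers(2**31))
        sim = metric_frame(sim_cells)
        for metric in obs.columns:
            a = obs[metric].dropna().to_numpy()
            b = sim[metric].dropna().to_numpy()
            if a.size < 2 or b.size < 2 or a.var() == 0:
                val = np.nan
            else:
                _, pa, pb = density_histograms(a, b, n_bins)
                try:
                    val = normalized_mse(pa, pb)
                except InvalidParameterError:
                    val = np.nan
            rows.append({"model": fit.model, "metric": metric, "value": val})
    df = pd.DataFrame(rows)
    df["best_in_row"] = False
    for _, idx in df.groupby("metric").groups.items():
        sub = df.loc[idx, "value"].dropna()
        if len(sub):
            df.loc[sub.idxmin(), "best_in_row"] = True
    return df
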