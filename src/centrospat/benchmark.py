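"""Statistical benchmarking of clustering metrics across pattern generators.

Two experiments are supported:

* **Sensitivity** — for each metric, a Kruskal-Wallis omnibus test across
  generators followed by pairwise two-sided Mann-Whitney U tests (against a
  reference generator, or all pairs), Benjamini-Hochberg FDR correction
  within each metric family, and rank-biserial / Cohen's D effect sizes.
* **Robustness** — spots are removed uniformly at random (1..30 per pattern)
  from each generator's patterns and the percent change of each metric's
  mean relative to the full 46-spot baseline is tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .core import InvalidParameterError
from .metrics import (
    MetricSettings,
    RadiiGrid,
    SpatialGraph,
    _clustering_pct_sorted,
    _knn_edges,
    _morans_i_xy,
    assortativity,
    modularity_louvain,
)
from .simulators import GeneratorConfig, MODEL_IDS, sample_pattern

#: Canonical generator ordering used for pair orientation in reports.
GENERATOR_ORDER = MODEL_IDS

ALL_METRICS = (
    "ripley_clustering_pct",
    "assortativity",
    "modularity",
    "morans_i",
    "mnnd",
    "dispersion_index",
)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group ``a`` versus group ``b``.

    Uses exact enumeration for small tie-free samples (both n <= 20) and the
    tie- and continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; identical data gives H=0, p=1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InvalidParameterError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Effect size r = 2U/(n1 n2) - 1 for the Mann-Whitney U of group one."""
    if not (0 <= u <= n1 * n2):
        raise InvalidParameterError(f"U={u} outside [0, {n1 * n2}]")
    return 2.0 * u / (n1 * n2) - 1.0


def cohens_d(a, b) -> float:
    """Cohen's D with the pooled (ddof=1) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each sample needs >= 2 values")
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise InvalidParameterError("zero pooled variance: Cohen's D undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def effect_label(d: float) -> str:
    """Conventional |D| bands: 0.2 / 0.5 / 0.8 = small / medium / large."""
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


@dataclass(frozen=True)
class TestResult:
    """One pairwise comparison row of the benchmark report."""

    metric: str
    group1: str
    group2: str
    u_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    rank_biserial: float
    cohens_d: float
    effect: str


# ---------------------------------------------------------------------------
# metric tables and the benchmark report
# ---------------------------------------------------------------------------

def metric_table(
    configs: dict[str, GeneratorConfig],
    n_patterns: int,
    seed=None,
    metrics=ALL_METRICS,
    settings: MetricSettings = MetricSettings(),
) -> pd.DataFrame:
    """Long-format table (generator, pattern, metric, value) of metric values."""
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(configs, key=_generator_sort_key):
        cfg = configs[name]
        for i in range(n_patterns):
            pat = sample_pattern(cfg, rng)
            vals = _fast_metrics(pat.spots, pat.region.area, pat.region.radius,
                                 metrics, settings)
            for m, v in vals.items():
                rows.append((name, i, m, v))
    return pd.DataFrame(rows, columns=["generator", "pattern", "metric", "value"])


def _generator_sort_key(name: str):
    try:
        return (0, GENERATOR_ORDER.index(name))
    except ValueError:
        return (1, name)


def benchmark_report(
    table: pd.DataFrame,
    reference: str | None = "CSR",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Omnibus + pairwise comparison report over a long metric table.

    ``reference=None`` runs all unordered pairs (first-named group follows the
    canonical generator order); otherwise every group is compared with the
    reference.  BH-FDR is applied within each metric family.  Returns one row
    per (metric, pair) with the Kruskal-Wallis omnibus attached.
    """
    out_rows = []
    for metric, sub in table.groupby("metric", sort=False):
        groups = {
            g: s["value"].dropna().to_numpy()
            for g, s in sub.groupby("generator", sort=False)
        }
        names = sorted(groups, key=_generator_sort_key)
        kw_h, kw_p = kruskal_wallis([groups[g] for g in names])
        if reference is None:
            pairs = [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ]
        else:
            if reference not in groups:
                raise InvalidParameterError(f"reference group {reference!r} missing")
            pairs = [(reference, g) for g in names if g != reference]
        stats_rows = []
        for g1, g2 in pairs:
            a, b = groups[g1], groups[g2]
            u, p = mann_whitney_u(a, b)
            rb = rank_biserial(u, a.size, b.size)
            try:
                d = cohens_d(a, b)
            except InvalidParameterError:
                d = np.nan
            stats_rows.append((g1, g2, u, p, rb, d))
        padj = bh_fdr([r[3] for r in stats_rows])
        for (g1, g2, u, p, rb, d), q in zip(stats_rows, padj):
            out_rows.append(
                {
                    "metric": metric,
                    "group1": g1,
                    "group2": g2,
                    "kw_H": kw_h,
                    "kw_p": kw_p,
                    "U": u,
                    "p_raw": p,
                    "p_adjusted": q,
                    "significant": q < alpha,
                    "rank_biserial": rb,
                    "cohens_d": d,
                    "effect": effect_label(d) if np.isfinite(d) else "undefined",
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# spot-removal robustness
# ---------------------------------------------------------------------------

def _fast_metrics(xy, area, radius, metrics, settings, dmat=None):
    """Metric subset on raw coordinates, reusing one distance matrix."""
    out = {}
    if dmat is None:
        dmat = squareform(pdist(xy))
    n = xy.shape[0]
    iu = np.triu_indices(n, 1)
    cond = dmat[iu]
    if "ripley_clustering_pct" in metrics:
        grid = settings.radii or RadiiGrid(r_max=radius)
        out["ripley_clustering_pct"] = _clustering_pct_sorted(
            np.sort(cond), n, area, grid
        )
    if "morans_i" in metrics:
        out["morans_i"] = _morans_i_xy(xy, dmat**2)
    if "mnnd" in metrics:
        dd = dmat + np.diag(np.full(n, np.inf))
        out["mnnd"] = float(dd.min(axis=1).mean())
    if "dispersion_index" in metrics:
        mu = cond.mean()
        out["dispersion_index"] = float(cond.var(ddof=0) / mu) if mu > 0 else np.nan
    if "assortativity" in metrics or "modularity" in metrics:
        if n > settings.k:
            edges, weights = _knn_edges(dmat, settings.k)
            graph = SpatialGraph(n, edges, weights)
            if "assortativity" in metrics:
                out["assortativity"] = assortativity(graph)
            if "modularity" in metrics:
                out["modularity"] = modularity_louvain(graph, settings.louvain_seed)
        else:
            for m in ("assortativity", "modularity"):
                if m in metrics:
                    out[m] = np.nan
    return out


def robustness_to_removal(
    configs: dict[str, GeneratorConfig],
    n_patterns: int,
    removals=range(1, 31),
    metrics=ALL_METRICS,
    seed=None,
    settings: MetricSettings = MetricSettings(),
) -> pd.DataFrame:
    """Percent change of mean metric values under random spot removal.

    For each generator, ``n_patterns`` full patterns are simulated; for each
    removal count k the same patterns are subsampled uniformly at random
    without replacement and the metrics recomputed.  Returns a long table
    (generator, metric, n_removed, mean_value, percent_change) including the
    k=0 baseline rows (percent change exactly 0).  Baselines with magnitude
    below 1e-6 yield NaN percent changes rather than infinities; removal
    counts >= the spot count are skipped.
    """
    rng = np.random.default_rng(seed)
    removals = [k for k in removals if k > 0]
    acc: dict[tuple[str, str, int], list[float]] = {}
    for name in sorted(configs, key=_generator_sort_key):
        cfg = configs[name]
        for _ in range(n_patterns):
            pat = sample_pattern(cfg, rng)
            xy = pat.spots
            n = xy.shape[0]
            dmat = squareform(pdist(xy))
            levels = [0] + [k for k in removals if k < n]
            for k in levels:
                if k == 0:
                    sub_xy, sub_d = xy, dmat
                else:
                    keep = rng.choice(n, size=n - k, replace=False)
                    sub_xy = xy[keep]
                    sub_d = dmat[np.ix_(keep, keep)]
                vals = _fast_metrics(
                    sub_xy, pat.region.area, pat.region.radius, metrics, settings, sub_d
                )
                for m, v in vals.items():
                    acc.setdefault((name, m, k), []).append(v)
    rows = []
    for name in sorted({g for g, _, _ in acc}, key=_generator_sort_key):
        for m in metrics:
            base = np.nanmean(acc.get((name, m, 0), [np.nan]))
            for k in [0] + removals:
                if (name, m, k) not in acc:
                    continue
                mean_k = float(np.nanmean(acc[(name, m, k)]))
                if k == 0:
                    pct = 0.0
                elif abs(base) < 1e-6:
                    pct = np.nan
                else:
                    pct = 100.0 * (mean_k - base) / base
                rows.append((name, m, k, mean_k, pct))
    return pd.DataFrame(
        rows, columns=["generator", "metric", "n_removed", "mean_value", "percent_change"]
    )


def median_abs_percent_change(table: pd.DataFrame, metric: str) -> float:
    """Median |percent change| over all (generator, k>0) cells of one metric."""
    sub = table[(table.metric == metric) & (table.n_removed > 0)]
    return float(sub["percent_change"].abs().median())


def max_abs_percent_change(table: pd.DataFrame, metrics) -> float:
    """Maximum |percent change| over the given metrics and all k>0 cells."""
    sub = table[table.metric.isin(list(metrics)) & (table.n_removed > 0)]
    return float(sub["percent_change"].abs().max())
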