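# centrospat

Quantitative analysis and simulation of spatial spot patterns in cell
nuclei, built for centromeres imaged by high-throughput fluorescence
microscopy (one CENP-C punctum per chromosome), and applicable to any
punctate nuclear signal delivered as per-cell spot coordinate tables.

Centromeres are non-randomly positioned in the interphase nucleus, and
perturbations (e.g. condensin II loss) change their clustering.  Screening
for regulators of that organization needs two things this package provides:

1. **Metrics + benchmarks** — six clustering metrics computed per cell, and
   a simulation harness that measures each metric's sensitivity (can it
   separate known pattern types?) and robustness (does it survive variation
   in detected spot number?).
2. **Generative models** — parametric models of spot placement fitted to
   observed cells, sampled in silico, and scored against the data with
   distribution-similarity metrics.

## The statistics at the core

**Ripley's K clustering percentage.**  For N spots in a nucleus of area A,

    K(r) = (A / N²) · Σ_{i≠j} 1(d_ij ≤ r)

with no edge correction; the *clustering percentage* is the fraction of a
50-step radius grid (0 → nucleus radius R) on which K(r) exceeds the
homogeneous-Poisson expectation πr², × 100.  Hard-core (dispersed) patterns
score 0; a single tight cluster saturates the score.  The other metrics are
assortativity and Louvain modularity Q on a k = 10 nearest-neighbour graph
with 1/d² edge weights, Moran's I with 1/d² weights, mean
nearest-neighbour distance (MNND), and the dispersion index σ²_d/μ_d of the
pairwise distances.

**Nine pattern generators** provide ground truth inside a circular nucleus
(R = 46 px ≈ 10 µm diameter at 0.108 µm/px, 46 spots): CSR, Poisson disk
sampling (10 px hard core), uniform with 15 two- or three-spot adjacencies
(UTA/UTHA, ±3 px shifts), one/two/three-mode 2D Gaussian mixtures
(S2DG/T2DG/TH2DG, covariances swept over 50–1000 px² and orientations over
[0, π)), and Gaussian(s) with nuclear-body exclusion disks
(2DGNB/T2DGTNB).

**The doughnut model.**  Pooled, center-aligned centromere positions form a
ring: low density at the nuclear center, a peak in the mid-region.  The
package models this with a radially shifted Gaussian — radius ~ N(r0, σ)
truncated at 0, angle uniform — and estimates (r0, σ) by
Metropolis–Hastings MCMC from either the per-spot radial distances (model
M4, exact Gaussian likelihood) or the per-cell pairwise distances (M5,
Monte-Carlo likelihood with a −10¹⁰ floor for empty bins).  Baselines: M1
uniform, M2 nucleus-shaped Gaussian (σx = a/3, σy = b/3 from the fitted
ellipse), M3 centered radial Gaussian fitted through the closed-form
pairwise CDF F(d) = 1 − exp(−d²/4σ²).  Model output is scored against data
with the Wasserstein distance, a normalized MSE, and the KS statistic.

## Worked example

```python
from centrospat import (GeneratorConfig, generate_dataset, compute_all_metrics,
                        metric_table, benchmark_report)

# one single-Gaussian-cluster pattern, all six metrics
pattern = generate_dataset(GeneratorConfig(model="S2DG"), 1, seed=7)[0]
for name, value in compute_all_metrics(pattern).as_dict().items():
    print(f"{name:22s} {value:8.3f}")

# benchmark the clustering percentage: CSR vs PDS vs S2DG, 200 patterns each
cfgs = {m: GeneratorConfig(model=m) for m in ("CSR", "PDS", "S2DG")}
table = metric_table(cfgs, 200, seed=7, metrics=("ripley_clustering_pct",))
print(benchmark_report(table, reference="CSR"))
```

prints

```
ripley_clustering_pct    64.000
assortativity             0.334
modularity                0.670
morans_i                  0.230
mnnd                      5.661
dispersion_index          8.735

               metric group1 group2       U   p_adjusted  significant  rank_biserial  cohens_d
ripley_clustering_pct    CSR    PDS 37100.0 2.672172e-60         True       0.855000  1.398671
ripley_clustering_pct    CSR   S2DG  2347.5 9.591811e-53         True      -0.882625 -2.635060
```

The S2DG pattern's clustering percentage (64) reflects K(r) exceeding πr²
on most radii — a central cluster; its Moran's I (0.23) is *below* the CSR
baseline (~0.7), the signature of spots concentrated at the centroid.  In
the benchmark, both comparisons against CSR are significant after BH-FDR:
PDS sits *below* CSR (rank-biserial +0.86, CSR higher) because hard-core
patterns never exceed the Poisson expectation, while S2DG sits far above
(−0.88).  Cohen's D magnitudes (1.4, 2.6) are "large" on the usual
0.2/0.5/0.8 scale.

Fitting the doughnut model to observed cells and scoring all five models:

```python
from centrospat import fit_m4, radial_distances, compare_real_vs_model
res = fit_m4([radial_distances(p) for p in cells],
             [p.region.radius for p in cells])
print(res.summary())          # posterior mean/sd and 95% CI for (r0, sigma)
```

A command-line layer wraps the same pipelines:

```bash
centrospat simulate --model T2DG --n-patterns 100 --seed 1 --out out/
centrospat metrics  --spots out/spots.csv --nuclei out/nuclei.csv --out out/
centrospat benchmark --reps 200 --seed 1 --out out/
centrospat fit --spots out/spots.csv --nuclei out/nuclei.csv --model M4 --out out/
```

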