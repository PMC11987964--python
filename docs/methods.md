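# Methods

`centrospat` quantifies and models the spatial distribution of punctate
nuclear signals — its motivating case is centromeres, imaged as one CENP-C
spot per chromosome in maximally projected fluorescence images.  Three
ingredients make up the package: synthetic pattern generators that define
controlled clustering regimes, clustering metrics with a statistical
benchmarking layer, and generative localization models fitted to observed
spot tables.  This note records the scientific conventions, defaults, and
numerical choices, and what the synthetic experiments do and do not show.

## Geometry and units

All analysis happens on continuous 2D coordinates in pixel units, image
convention (origin top-left, y downward).  The synthetic nucleus is a circle
of radius R = 46 px centered at (128, 128) in a 256×256 px patch.  The
radius corresponds to a 10 µm nucleus diameter at a 0.108 µm/px camera
pixel size — the mean HCT116 nucleus footprint in the motivating
high-throughput datasets.  Every synthetic spot satisfies
(x−cx)² + (y−cy)² ≤ r².  Observed nuclei enter either as spot/nucleus CSV
tables or as 16-bit label masks, from which the centroid, equivalent radius
√(area/π) and the moment-equivalent ellipse are extracted.

## Pattern generators

Each generator produces N = 46 spots per pattern (the diploid human
centromere count).  CSR rejection-samples uniform points from the bounding
box.  PDS (Poisson disk sampling) enforces a 10 px hard-core distance by
dart throwing: uniform candidates are accepted only if at least 10 px from
every retained spot, with a 10⁶-candidate budget per pattern
(`InfeasiblePackingError` reports the achieved count on exhaustion — e.g.
46 spots at 10 px spacing fit easily, 200 cannot, the hexagonal packing
bound for the disk being far below that).

The Gaussian family (S2DG, T2DG, TH2DG) draws from mixtures with equal
component weights; modes sit at the nucleus center (S2DG), at ±25 px along
y (T2DG: (128,103), (128,153)), and with a third mode at (103,128)
(TH2DG).  Per pattern and per component, a covariance
Σ = R·diag(σx², σy²)·Rᵀ is drawn with σx², σy² independent and uniform on
the grid {50, 100, …, 1000} px² and θ ~ U[0, π).  The variance grid is the
stated sweep range; drawing the two principal variances independently is
this package's resolution of how a single "size" sweep can coexist with a
meaningful orientation sweep — an isotropic matrix would make θ vacuous.
Draws are rejected outside the circle and the first 46 accepted points are
kept.

UTA/UTHA model small adjacency clusters: 15 uniform "seed" spots each
receive one (UTA) or two (UTHA) companions displaced by a uniform ±3 px
shift per axis (companion resampled if outside the nucleus).  Companions are
interleaved directly after their seeds so the first-46 truncation retains
whole multiplets: UTA patterns contain 15 pairs + 16 singletons, UTHA 15
triplets + 1 singleton.  Per-spot provenance labels make the multiplet
census testable.

2DGNB/T2DGTNB add nuclear-body exclusion: spots are additionally rejected
inside disk(s) of radius 15 px placed at each Gaussian mode center (one
central body for 2DGNB, two at ±25 px for T2DGTNB).  The body radius is a
package default — chosen as a nucleolus-scale void, roughly a third of the
nucleus radius — and is configurable, since no canonical value exists for
simulated data.

A single seeded `numpy.random.Generator` threads through all samplers;
identical config + seed reproduces patterns bit for bit.

## Clustering metrics

**Ripley's K / clustering percentage.**  K(r) = (A/N²)·Σ_{i≠j} I(d_ij ≤ r)
with A the region area and both ordered pairs counted; deliberately no edge
correction, matching the plain estimator the benchmarks are built on.  The
clustering percentage is 100 × #{r : K(r) − πr² > 0} / n_steps on a grid of
50 equal steps from 0 to R (51 radii including 0).  Two structural facts
follow: a hard-core pattern scores exactly 0 (K stays below πr²
everywhere), and the ceiling is 98% rather than 100% because at r = R the
estimator saturates at A(N−1)/N < πR².  The score is invariant when
coordinates, region and radii are scaled together.

**k-NN graph metrics.**  A symmetrized k = 10 nearest-neighbour graph with
edge weights 1/d² (capped at 1/0.5² for near-coincident spots) feeds two
metrics.  Assortativity is the Pearson correlation of endpoint *strengths*
(weighted degrees) over the directed edge list — identical to networkx's
weighted degree assortativity; graphs with constant strength return 0 with
a degeneracy flag.  Modularity Q is computed on the weighted Louvain
(multilevel) partition; the C implementation in igraph is used for speed
(~0.2 ms/graph, needed for the ~4×10⁵ graphs of the removal experiment)
with the partition's Q cross-checked in the tests against the definition
Q = Σ_c (e_c − a_c²) evaluated independently.  Louvain's node-order
randomness is pinned by a recorded seed.

**Moran's I.**  Weights w_ij = 1/d_ij² (0 for coincident pairs); the
statistic is evaluated per coordinate axis on centered values and averaged
over axes with non-zero variance.  The printed formula treats the
coordinate vector itself as the variable; the per-axis average is this
package's resolution (a dot-product form is the main alternative and is
noted as such).  Two caveats are worth stating plainly: because the
"variable" is the coordinate and the weights favour close pairs, Moran's I
of any spatial pattern is strongly positive (CSR ≈ 0.7 here, not 0), and
the usual [−1, 1] range does **not** bound this weighted form — adjacency
patterns reach ≈ 1.8.  Orderings, not absolute values, carry the signal:
UTA/UTHA > CSR > S2DG, which the tests assert.

**MNND** is the mean distance to each spot's nearest neighbour; PDS bounds
it below by the hard-core distance.  **Dispersion index** is the population
variance (ddof = 0) of the N(N−1)/2 unordered pairwise distances divided by
their mean; the population-variance convention is deliberate and tested
(collinear {1, 2, 3} distances give exactly 1/3).

`compute_all_metrics` shares one distance matrix and k-NN graph across the
six metrics and records per-metric failures (too few spots, degenerate
geometry) as missing values rather than aborting a batch.

## Benchmarking

Sensitivity: per metric, a Kruskal–Wallis omnibus test across generators,
then two-sided Mann–Whitney U tests (exact enumeration for tie-free samples
of ≤ 20, tie- and continuity-corrected normal approximation otherwise)
against a reference generator (CSR) or all pairs, Benjamini–Hochberg FDR
within each metric family, rank-biserial r = 2U/(n₁n₂) − 1 and pooled-SD
(ddof = 1) Cohen's D with the conventional 0.2/0.5/0.8 magnitude bands.
Pair orientation follows the fixed generator order CSR, PDS, UTA, UTHA,
S2DG, T2DG, TH2DG, 2DGNB, T2DGTNB.

Robustness: from each 46-spot pattern, k = 1…30 spots are removed uniformly
at random; the percent change of each metric's mean (per generator and k)
relative to the 46-spot baseline is tabulated.  Baselines below 1e-6 in
magnitude (e.g. the PDS clustering percentage, identically 0) yield flagged
NaN percent changes rather than infinities.

At full desk scale (`scripts/acceptance.py`: 2000 patterns/generator for
the removal and pairwise experiments, 5000/group for the two targeted
effect sizes) the experiments reproduce the qualitative benchmark: the
clustering percentage is the most removal-robust metric (median |Δ| ≈ 6–7%),
Moran's I and modularity vary moderately (max |Δ| ≈ 40%), and MNND and the
clustering percentage achieve complete separation (|r| = 1) for at least
one generator pair.  The routine test suite runs the same experiments at
300 patterns/generator (3000/group for the targeted effect sizes), sizes at
which the medians/maxima above are stable.  Two printed near-zero effect
sizes (dispersion index CSR vs T2DG, assortativity PDS vs UTA) could not be
reproduced under any defensible reading of the under-specified estimator
details; the corresponding checks are left failing rather than loosened,
and the package reports its honestly computed values.

## Generative models

Five models describe spot placement in a nucleus.  M1 is uniform.  M2 draws
from a centered Gaussian aligned with the nucleus ellipse, σx = a/3,
σy = b/3, truncated at the boundary.  M3 is a centered isotropic 2D
Gaussian whose single σ is fitted by least squares of the closed-form
pairwise-distance CDF F(d) = 1 − exp(−d²/4σ²) (difference of two centered
Gaussians has doubled variance, hence a Rayleigh(σ√2) distance law) to the
empirical CDF on a 200-point grid.  The closed-form cumulative
K(r) = (C/λ)(1 − exp(−r²/2σ²)) of the centered radial density is exposed
and verified against quadrature; the C/λ scale is treated as a single free
constant, equal to 1 when fitting normalized CDFs.

M4 and M5 are Bayesian estimators of the *radially shifted* Gaussian
("doughnut"): radius ~ N(r0, σ) truncated at 0, angle uniform.  M4 uses the
exact Gaussian likelihood of the observed radial distances; M5 uses
observed pairwise distances, whose model density has no closed form and is
tabulated per likelihood evaluation by Monte Carlo: draw r₁, r₂ ~ N(r0, σ)
(negative draws discarded), Δθ uniform, histogram
d = √(r₁² + r₂² − 2r₁r₂cosΔθ) on 200 equal bins spanning [0, 2(r0 + 4σ)],
normalized to a density; empty bins contribute a −10¹⁰ log-likelihood
floor.  A fixed auxiliary draw (common random numbers) is reused across
evaluations so the noisy likelihood is coherent along the chain.  Priors
are independent Normals on r0 and σ; the data-driven defaults center the r0
prior at the mean observed radius with SD half that mean, and the σ prior
at the radii SD with equal SD.  Sampling is random-walk Metropolis
(default 5000 iterations, 1000 burn-in) with a pilot phase that
doubles/halves step sizes toward ~30% acceptance; proposals with σ ≤ 0 are
rejected.  Radial distances are normalized by each cell's equivalent radius
before pooling, so differently sized nuclei share one (r0, σ) in normalized
units; simulation rescales per cell.

Two internal-consistency decisions deserve emphasis.  First, the likelihood
is an *untruncated* Normal on radii while sampling rejects negative radii
and points outside the nucleus; the induced bias is negligible when
σ ≪ r0 and the nucleus does not clip the doughnut, which is why the
parameter-recovery experiments simulate in a nucleus of radius r0 + 4σ (the
default 46 px nucleus clips a (30, 8) doughnut enough to bias σ̂ low by
about 5%).  Second, the doughnut family's polar density admits two
readings — area density (whose r0 = 0 limit is the true 2D Gaussian with
Rayleigh radii) or radial density (radius literally Gaussian).  The
estimators are defined under the radial reading, and the package follows it
throughout for self-consistency; consequently the r0 → 0 limit of the M5
Monte-Carlo distance density is *not* Rayleigh(σ√2) (max absolute deviation
≈ 0.04 at σ = 8), and M3 — which genuinely is the 2D-Gaussian case — has
its own sampler rather than reusing the doughnut sampler at r0 = 0.

Parameter recovery at desk scale: M4 recovers (r0, σ) = (30, 8) px within
5% from 200 cells × 46 spots; M5 within 10% from 50 cells of pairwise
distances; on conjugate sub-problems the MH chain matches the closed-form
Normal posterior within Monte-Carlo error.  M4 and M5 agree with each other
on large synthetic datasets; M5 needs more cells for the same precision —
its ~1000 distances per cell are strongly inter-dependent, carrying less
information than their count suggests.

## Similarity scoring and overlay analysis

Real-vs-model comparison simulates, for each fitted model, cells on the
observed nuclei with matching spot counts, then scores the pooled pairwise
and radial distance distributions with the 1D Wasserstein distance, the
two-sample KS statistic, and a normalized MSE: density histograms on a
shared 100-bin grid over the union range, mean squared bin difference
divided by the population variance of the reference PDF's bin values (the
bin-value variance is the literal reading of the normalization; a
sample-variance alternative exists and is noted).  All three scores are 0
for identical inputs; KS ≤ 1; Wasserstein obeys the triangle inequality
(property-tested).  On synthetic doughnut ground truth the doughnut models
(M3/M4/M5) outrank M1/M2 on all three pairwise-distance scores in ≥ 95% of
seeded repetitions.

The overlay analysis shifts every cell's spots so nuclear centers coincide
at (0, 0), pools them, histograms in 2D with 2 px bins, and takes the
central row/column as X = 0 / Y = 0 line profiles (no interpolation).
Profile coordinates are fitted with 2-component 1D Gaussian mixtures
(scikit-learn EM, 10 seeded k-means++ restarts).  For radially symmetric
input the X- and Y-axis parameter vectors correlate above 0.99, the
quantitative signature of a doughnut; pooling uses raw center-shifted
pixels by default with a normalized option for heterogeneous nuclei.

## What the synthetic experiments do not show

The generators emulate controlled spatial statistics, not microscopy: no
detection noise, no blending of nearby spots into single detections, no
nucleus shape variability (circular synthetic nuclei), no 3D→2D projection
effects, and exactly 46 spots per cell where real detections median ~32.
Passing benchmarks therefore demonstrates the metrics' behaviour under
known ground truth — sensitivity orderings, removal robustness, estimator
consistency — not performance on any particular imaging dataset.  The I/O
layer ingests real spot tables and masks so the same pipeline applies, but
no claim about real-cell biology is tested here.

## Known limitations

* K(r) is uncorrected for edge effects; values near r = R are biased low,
  which the clustering percentage inherits by design.
* The weighted Moran's I is unbounded above 1 and strongly positive even
  for CSR; only relative comparisons are meaningful.
* The M4/M5 likelihoods ignore nucleus-boundary truncation; fits to cells
  whose doughnut is clipped by the boundary underestimate σ.
* M5's Monte-Carlo likelihood is noisy; with common random numbers the
  chain is stable, but posterior SDs are approximate.
* The dispersion index and assortativity have tiny effects for some
  generator pairs; their values there are sensitive to estimator details
  and should not be over-interpreted.
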