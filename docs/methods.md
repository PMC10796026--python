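# Methods

## Age-structured forward map

The package assumes a population of genomes growing exponentially at rate
Λ (1/s) in steady asynchronous state, with genome "birth" defined as the
initiation of the replication round that creates it.  Genome ages are then
exponential, p(τ) = Λe^{−Λτ}, and any replication program f(x, τ)
(probability that position x is copied by age τ; in [0, 1] and
non-decreasing in τ) maps to the abundance P(x) = ∫ Λe^{−Λτ} f(x, τ) dτ.
Genome degradation, cell-cycle structure and division are deliberately not
modelled; the map holds independently of them under the assumptions above.

Two non-identifiabilities follow directly from the map and shape every
interface in the package:

* the measured track is proportional to P(x) with an unknown factor, so a
  multiplicative scale is profiled analytically (weighted least squares)
  inside every objective;
* shifting the absolute initiation time rescales P(x) uniformly, so
  absolute replication timing is never reported — only compound
  parameters such as Λ/v and I*/v.

Numerics: the generic age integral is truncated where e^{−Λτ} <
`quad_tol` (default 1e−10) and evaluated by adaptive quadrature over a
geometric panelling of the age axis, so that programs with steps or kinks
at any time scale are resolved.  Bins are 0-based half-open; a bin is
represented by its midpoint.

## Deterministic limit and speed inversion

For a single deterministic fork, P(x) = exp(−Λτ₀ − Λ∫dx′/v(x′)) and the
speed follows from the log-slope, v(x) = −Λ/(d ln P/dx).  The inversion
smooths ln P with an edge-normalised boxcar (default 10 bins) and applies
central finite differences (one-sided at ends).  Smoothing happens in log
space because an exponential decay is log-linear, which the boxcar leaves
slope-invariant; the first window//2+1 bins at each chromosome end are
flagged, since the shrinking end windows bias the smoothed slope there.
Zero-slope bins return an infinite-speed sentinel and are flagged.

## Point-origin (eukaryotic) model

Origins sit at fixed positions and fire independently at constant rates —
a known simplification, as firing rates in budding yeast are
time-dependent.  The model is parametrised by the rescaled intensities
ι_j = I*_j/v (1/bp) and λ̂ = Λ/v (1/bp).  The closed-form abundance sorts
origins by travel time per evaluation position (ties are
order-independent) and is vectorised over a position grid at O(K log K)
per position.  A quadrature oracle integrating the light-cone exponent
directly is kept as an independent test route; its integrator receives a
graded mesh after each kink because strong origins create boundary layers
of width 1/(I*/Λ) that a plain adaptive rule can step over.

Chromosomes are linear and independent; no fork enters from outside, and
an origin near an end simply has a truncated light-cone.

### Inference

Simulated annealing over (K, positions, intensities, λ̂) with the AIC cost
2p + N ln(SQ/N), p = 2K + 2, under a Gaussian residual likelihood; the
scale is profiled per dataset and λ̂ is shared across chromosomes.
Schedule and proposals (geometric cooling 0.95, 200·K moves per
temperature clamped to [200, 20000], move mix 0.4 move / 0.3 intensity /
0.1 add / 0.1 remove / 0.1 λ̂, adaptive proposal widths, occasional 10×
wide position jumps for basin hopping) are standard choices; the
temperature starts at three times the median |ΔAIC| of trial moves and
stops at 1e−3 of that.  Candidates are seeded at local maxima of the
smoothed track (every origin is a local maximum of the model abundance);
a monotone track seeds its boundary argmax and a flat track seeds
nothing, leaving insertion moves to the annealer.  After annealing, a
bounded Powell polish refines the continuous parameters at fixed K in
normalised coordinates (positions as chromosome fractions, intensities
and λ̂ in log space).  Intensity bounds default to [1e−7, 1e−1] per bp
with a minimum origin separation of 1 kb (below data resolution).

### What intensity recovery can and cannot do

Near an isolated origin the model abundance is scale · r/(1+r) ·
e^{−λ̂ d} with r = I*/Λ.  For K = 1 the level r/(1+r) is absorbed by the
profiled scale entirely: a single origin's intensity is unidentifiable,
and only its position and λ̂ can be recovered.  For K ≥ 2 the relative
peak levels identify the intensities, but the sensitivity of the level to
ln r is r/(1+r)², which decays like 1/r: origins firing much faster than
the growth rate (I* ≫ Λ) saturate and their intensity is
information-limited at realistic noise.  The four-origin benchmark
therefore places intensities at I*/Λ ≈ 2–15 — strong enough to detect,
unsaturated enough to quantify — with λ̂ = 1e−5/bp (a slow-growth,
high-contrast condition).  The many-origin benchmark instead draws
intensities log-uniformly over [1e−5, 2e−3]/bp spanning two orders of
magnitude; there, the weakest and the tightly clustered origins are
expected to be missed, and recovery is scored as the fraction of true
origins with an inferred origin within 5 kb plus the median
inferred-to-true distance.  Benchmark sizes (300 kb / 4 origins and
600 kb / 15 origins at 1 kb bins) were chosen so a full multi-seed
recovery study runs in minutes on one core.

## Two-fork (bacterial) model

Coordinates x ∈ [0, L] on a circular genome with the origin at 0 ≡ L.
Each fork position is the running extremum of an auxiliary process with
drift ±v₀h(τ) and diffusivity D·h(τ), h(τ) = 1 + δ cos(ωτ + φ) with
0 ≤ δ < 1 (the same modulation applied to both forks and to the
diffusivity, so time can be rescaled through H(τ) = ∫₀^τ h).  φ is the
modulation phase at replication initiation.  The single-fork program is
the inverse-Gaussian first-passage CDF with mean dist/v₀ and variance
2D·dist/v₀³, evaluated at H(τ) via the two-Φ closed form with the
e^{2λ/μ} factor handled through log Φ for numerical stability; D = 0
reduces to a step and the joint program is f = 1 − (1−f₁)(1−f₂).
Abundance integrates the joint survival against the age density by
adaptive vectorised quadrature, truncated both at the exponential-weight
cutoff and shortly after the latest plausible completion age; the D = 0
case inverts H in closed form instead (Brent root finding on the strictly
increasing clock).

The Euler–Maruyama simulator steps both auxiliary processes with shared
block-vectorised noise (default dt keeps v₀·dt ≤ L/10⁵) and takes running
extrema per block via cumulative maxima; paths are compacted as they
complete, and paths still active at ten deterministic completion times
are flagged.  First-passage sampling applies the Broadie–Glasserman
continuity correction (barrier shifted by 0.5826·σ√dt) to remove the
O(√dt) bias of discretely monitored crossings; without it, 10⁴-path
comparisons against the analytic law fail at practical time steps.  The
asymptotic meeting-point spread ΔZ = √(DL/2v₀) is accurate to ~1% for
Péclet numbers ≳100; at Pe ≲ 20 the true spread is several percent
smaller, so simulation-vs-formula checks are run at Pe ≈ 100.

### Fitting

Free parameters (v₀, D, δ, ω, φ) with Λ fixed; objective
SQ = Σ(aᵢ − λPᵢ)²/σᵢ², scale λ profiled.  Per-bin noise scales σᵢ are the
centred rolling standard deviation (default 50 bins) of the first
differences divided by √2, which cancels the smooth replication trend.
The ω multistart grid spans frequencies commensurate with the doubling
time, [2π/4τ₂, 2π/0.25τ₂]; for each ω the best phase on a coarse grid
seeds a local Nelder–Mead search in normalised coordinates (bounded;
the best evaluated point is kept, as bounded simplex/line-search methods
can terminate off their best visit).  The optimiser's phase coordinate is
referenced to mid-replication because the initiation-referenced φ is
nearly collinear with ω.  All starts run with D pinned to 0 (the
modulation signature is sharpest without diffusive smoothing); D is then
freed from the winning start and kept only if it clears a one-parameter
AIC-style penalty.  The oscillating vs constant-speed choice instead uses
a BIC-style penalty (ln N per parameter): the oscillating model's three
extra parameters always reduce raw SQ and clear a flat 2-per-parameter
penalty by chance on a few percent of null datasets, whereas the
sample-size-dependent penalty rejects them reliably while the genuine
20–30% residual decrease of real modulation clears it easily.  Gauge
fixing: δ ≥ 0 and φ ∈ [0, 2π).

ω is identifiable only to the extent that modulation periods fit inside
the replication window L/2v₀: the benchmark (L = 4,641,652 bp — the
E. coli MG1655 genome length — v₀ = 800 bp/s, δ = 0.15, ω = 2π/2700 s⁻¹,
φ = 1.5, Λ = ln2/2700 s⁻¹, Gamma noise CV 0.02) shows roughly one period,
and at 25 kb bins the likelihood optimum sits 15–20% off the true ω under
many noise draws; 10 kb bins carry enough information for ~5% recovery
and are used for the recovery benchmark.

## Synthetic data

Generators bin the exact model abundance at bin midpoints and apply
either multiplicative Gamma noise (mean 1, configurable CV; 0.04 for the
yeast benchmarks, 0.02 for the bacterial ones) or Poisson read counts at
a target mean depth.  They emulate the statistical noise floor of a deep
coverage track and nothing else: no mappability gaps, GC bias,
copy-number variants, repeats or finite-fragment effects.  Passing
recovery tests on these tracks therefore demonstrates correctness of the
inference machinery under the stated noise model, not robustness to the
systematic artefacts of real sequencing data, which should be corrected
upstream.

## Origin validation

Origin sets are compared by (i) Pearson correlation of Gaussian-kernel
density estimates on a 1 kb grid per chromosome (concatenated), where the
smoothing scale is interpreted as the kernel standard deviation; (ii)
nearest-neighbour distances in both directions with pooled medians,
restricted to matching chromosomes; (iii) two-sided Mann–Whitney U tests
of observed distances against two nulls: independent uniform shifts of
each origin (default range ±5× the mean half-spacing of the input set)
and a chromosome-label permutation preserving relative positions.
Chromosome lengths default to the maximum observed position when not
supplied.

## Known limitations

* Constant per-origin firing rates; no time-dependent firing, so origin
  efficiency/timing beyond the compound intensity is out of reach.
* No position-dependent fork stalling or terminus traps in the bacterial
  model; stalling is homogeneous along the genome.
* Single-origin intensity is unidentifiable (scale degeneracy), and
  intensities of very strong origins (I* ≫ Λ) are information-limited.
* The annealer is stochastic; different seeds can differ by one or two
  weak origins near the AIC margin.
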