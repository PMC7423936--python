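# Methods

## Problem and model

`spread-dti` detects longitudinal white-matter change in a *single subject*
from two co-registered fractional-anisotropy (FA) volumes acquired a season
apart. FA is a unitless scalar in [0, 1] per voxel; a local decrease is the
imaging signature of white-matter damage. Group-level voxel statistics are
underpowered when the injury location varies across subjects, so inference is
done per subject and only then aggregated.

At voxel v the change statistic is the absolute fitted FA difference

    T(v) = | S[Y_post − Y_pre](v) |,

where S is a Nadaraya–Watson kernel regression over the 3-D grid:

    S[f](v) = Σ_{u ∈ F, ‖u−v‖ ≤ c} w(‖u−v‖) f(u) / Σ w(‖u−v‖),
    w(d) = exp(−d² / (2h²)),

with F the brain foreground, h the bandwidth in voxels and c the spherical
truncation radius. Smoothing pools the spatial correlation of neighboring
voxels into the statistic, which is what gives the method its power. Because
S is linear with mask-determined weights, smoothing the difference field once
equals differencing the two smoothed scans; the implementation exploits this
(one FFT convolution per permutation) and the identity is asserted in tests
to 1e−10.

### Permutation inference

The null hypothesis at each voxel is exchangeability of its two time labels.
The null distribution is built by flipping the sign of the difference field
independently at every foreground voxel with a fair coin (equivalent to
swapping that voxel's pre/post labels), re-smoothing, and recomputing T. With
K permutations,

    p_raw(v) = (1 + #{k : T_k(v) ≥ T_obs(v)}) / (K + 1).

Conventions (not dictated by the method's description; chosen and fixed
here): the add-one rule guarantees valid, never-zero p-values under the
permutation null; ties count against the null. Multiplicity is handled two
ways: Benjamini–Hochberg step-up across foreground voxels (FDR), and
Westfall–Young as *single-step maxT* — each T_obs(v) is referred to the
permutation distribution of the map-wide maximum — floored at the raw map so
wy ≥ raw. Step-down minP would be slightly less conservative but needs the
full per-voxel null stack; maxT is the standard map-level choice and is valid
under exchangeability.

### Subject summaries

With a significance rule p < t on a chosen map (default: raw p < 0.002, the
rule used for single-subject map display; BH/WY selectable), the scalar
outputs are NSV (count of significant voxels), TDSV (signed sum of raw FA
differences over them) and ADSV (sum of absolute differences). Global change
is summarized by norms of the fitted difference Δ̂ over the foreground — L¹ =
mean|Δ̂|, L² = √mean Δ̂², L^∞ = max|Δ̂| — each with a global permutation
p-value from the recorded per-permutation norms (same add-one rule). Norms
average over the foreground only; including structurally-zero background
would dilute L¹/L² by an arbitrary box-size factor.

### Group meta-combination

Per-subject *raw* p-value maps on a common grid are combined voxel-wise with
an order-statistic beta test: combined p = Beta-CDF(p₍r₎; r, n−r+1), exactly
the probability that the r-th of n uniform order statistics is ≤ p₍r₎, hence
uniform under the global null. r = 1 recovers Tippett's minimum-p test;
larger r buys robustness — no single extreme subject can drive a rejection.
The default r = ⌈n/4⌉ demands signal in a quarter of subjects; r is exposed
in the API because the appropriate robustness level is a study decision. BH
is applied once, across voxels, at group level (combining raw maps and
adjusting once avoids double correction). Permutation p-values are discrete
(minimum 1/(K+1)); the beta CDF is applied to the lattice values without
continuity correction, which is conservative at the low end. Bringing
per-subject maps to one grid (registration) is the caller's responsibility.

## Preprocessing

Registered FA pairs show ringing near the brain edge. The cleanup step
removes every foreground voxel whose Euclidean distance (mm, center-to-center,
via a distance transform) to the nearest background voxel of the *original*
mask is ≤ 4 mm — a single pass, not an iterative erosion; re-applying it
removes more because the background has grown, so the operation is defined
against the input mask only. Volumes are then cropped to the tightest box
containing all nonzero FA, with the voxel offset kept so detections map back.
Foreground is defined as nonzero FA in either scan — the observable proxy for
a tissue mask when the tensor-fit mask is not available.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical skeleton the method relies on:

* a smooth shared baseline (white noise convolved with a Gaussian of width
  `smoothness_mm` = 6 mm, affinely rescaled to `baseline_mean` 0.5 ±
  `baseline_amplitude` 0.15 — mid-range FA with realistic spread);
* independent additive i.i.d. Gaussian voxel noise per scan
  (`noise_sd` = 0.02 FA);
* spherical lesions: `delta_fa` added inside a Euclidean ball on the post
  scan only, values clipped to [0, 1];
* a box foreground inset `mask_margin` = 6 voxels (room for bandwidth-15
  kernels on the default 48³ grid, which keeps permutation runs at
  minutes-scale on one CPU).

It deliberately has **no anatomical realism**: no tract geometry, no
registration error, and — most consequentially — no *spatial correlation in
the noise*. Real scan-pair differences carry correlated physiological and
registration noise that kernel smoothing cannot average away; i.i.d. noise
shrinks under an h = 5 kernel by a factor ≈ 45. Two corollaries for reading
the test results:

1. **Detection halos.** At contrast 0.1 on noise 0.02 the smoothed lesion
   signal stays far above the smoothed-noise level well beyond the lesion
   ball, so BH/WY detection recovers the lesion completely (TPR 1.0) but
   with a halo roughly one-to-two bandwidths thick: voxel-level FPR ≈ 0.2
   against a 36³ foreground. This is a property of the kernel statistic
   under these conditions, not an implementation artifact; on real data the
   much larger effective null level keeps halos tight.
2. **Bandwidth selection.** In the benchmark, the selected bandwidth is
   essentially constant (3) across lesion sizes: with i.i.d. noise even the
   smallest bandwidth has enough averaging power, and larger bandwidths only
   widen halos. The qualitative size-bandwidth scaling seen on real scans
   (larger lesions favor larger bandwidths) needs spatially correlated noise
   to emerge; the desk-scale check asserts only that the selected bandwidth
   does not *decrease* with size.

Impact logs: hit times uniform over a 90-day season; the five per-hit helmet
impact measures (LA, RA, HIC15, GSI, HITsp) share a lognormal severity factor
(correlation 0.7) with medians 20 g, 1400 rad/s², 6.5, 9 and 14 — typical
collegiate helmet-telemetry magnitudes — truncated below at the 10 g LA
recording threshold by whole-row redraw. The scan date falls 1–7 days after
season end.

## Benchmark design

The tuning study plants one centered lesion per pair and sweeps lesion radius
× bandwidth × multiple-testing procedure × threshold, sharing the permutation
plan across bandwidths within a pair. Scoring is voxel-level TPR/FPR against
the known ball. Defaults and their reasons:

* radii {3, 6, 12} on 48³ — the study's 5/12/48 ladder scaled to a desk
  volume (radius 48 needs ≳128³ grids);
* contrast ΔFA = −0.04 on noise 0.02: at −0.1 the post-smoothing contrast is
  ~50:1 and every cell saturates at TPR 1.0, leaving selection to noise-level
  FPR differences; −0.04 holds the smallest lesion at its detection margin
  (TPR ≈ 0.95), so TPR genuinely discriminates cells;
* selection maximizes TPR subject to an FPR cap, ties broken by lower FPR,
  then smaller bandwidth, then smaller threshold. The function default cap
  is 0.01 (appropriate when the foreground dwarfs the halo); the desk-scale
  constant `DESK_FPR_CAP` = 0.2 is used on 48³ grids, where a one-voxel
  dilation of a radius-12 ball alone costs FPR 0.05 and large-signal optima
  inherently operate near FPR 0.1–0.2;
* K = 200 permutations (p-value resolution 1/201, sufficient for WY-based
  selection at this scale; BH needs K ≳ 2000 to detect small lesions on 46k
  voxels and is carried in the grid for completeness).

## Exposure metrics

Season exposure per HIM: mean, peak, CUW = Σxᵢ, and three time-weighted sums
with exponential kernels (the canonical weighting laws are not public; these
forms are explicit stand-ins with the stated qualitative behavior):

* TBH: xᵢ · (1 + Σ_{j<i} (x_j/x_max) e^{−(t_i−t_j)/τ_b}) — prior hits, recent
  and large, amplify the current hit; weights ≥ 1 so TBH ≥ CUW. τ_b = 7 days
  (within-week accumulation).
* TUA: xᵢ · e^{−(t_scan−t_i)/τ_a} — recovery time before the scan discounts
  a hit; weights ≤ 1 so TUA ≤ CUW. τ_a = 30 days (weeks-scale recovery).
* TBH+TUA: both factors per hit.

Associations between the 30 metric × HIM exposures and each change-summary
column use Spearman rank correlation, two-sided: exact permutation null for
n < 10 (full enumeration of pairings, ties handled by Pearson-on-ranks),
t approximation otherwise. BH runs within each summary column (30 tests);
constant inputs yield undefined ρ, recorded as missing and excluded from the
BH family.

## Numerical and calibration choices

* Smoothing via cached real FFTs (kernel spectrum and foreground denominator
  precomputed per mask); zero-padding to fast lengths prevents wrap-around.
  Identity with the direct double-loop evaluation is asserted to 1e−10.
* Sub-voxel truncation radius reduces the kernel to the center voxel, making
  smoothing the identity — the bandwidth → 0 limit.
* Null calibration of the raw map is checked against the exact permutation-
  lattice expectation floor(α(K+1))/(K+1), with uncertainty taken as the
  empirical standard error across independent seed replicates: within one
  map the kernel makes voxel p-values strongly spatially correlated, so a
  pooled binomial standard deviation would be far too tight. Binomial bounds
  are used where draws are genuinely independent (family-wise rejection rate
  across runs, combination-test calibration, dose-response null).
* Degenerate inputs are rejected loudly: empty foreground, lesions leaving
  the foreground, emptied masks after edge removal, rank out of range, K < 1.

## Known limitations

* Two time points only; no multi-scan longitudinal modeling, no anisotropic
  (PDE-based) smoothing.
* The synthetic noise model understates real null levels (see above): TPR/FPR
  magnitudes measured here do not transfer to real scans, only the contracts
  and calibration properties do.
* The time-weighting laws for TBH/TUA are declared surrogates with
  configurable time constants, not reconstructions of any proprietary
  algorithm.
* Group combination assumes caller-registered common-grid maps and
  independent subjects.
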