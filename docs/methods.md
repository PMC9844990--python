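# Methods

## Coordinate model

Every labelled cell carries raw per-section coordinates: x medio-lateral
(μm, positive toward the injected side), y dorso-ventral (positive
dorsal), both with origin at the central canal, and z rostro-caudal
(increasing caudally). Input files may record anatomical left/right; the
reader reflects x for left-side injections so all downstream code is
side-agnostic. Raw values are never overwritten — normalized coordinates
live in separate columns.

### Landmark normalization

Transverse sections differ in size along the lumbar cord and deform
during histology, so each section is normalized independently using its
own white-matter landmarks: the lateral edge at central-canal level per
side (x), and the outermost dorsal and ventral white-matter points per
side (y). The map is linear per quadrant and fixes the origin:

    x_norm = x / |x_edge(side)| · 850
    y_norm = y / |y_extreme(side, half)| · |dv_extent(half)|

with the idealized frame 1700 μm wide and 900 μm tall. The dorso-ventral
split of the 900 μm is not anatomically pinned; the default is symmetric
(+450/−450 μm) and configurable. Because the map is sign-preserving and
the origin is fixed, quadrant membership (ipsi/contra × dorsal/ventral)
is invariant under normalization; the boundaries x = 0 and y = 0 are
assigned to ipsi and dorsal respectively — a deterministic rule with
zero-measure effect.

Sections lacking landmarks (damaged tissue in real exports) fall back to
the experiment-average geometry with a logged warning rather than being
dropped, so counts stay auditable.

### Rostro-caudal alignment and binning

Animals are registered along z on the widest medio-lateral section,
which marks the L4/L5 segment border at the lumbar enlargement; each
experiment receives one additive z offset placing that section at z = 0,
leaving within-animal spacings untouched. Ties break to the most rostral
maximal section (determinism). Experiments with fewer than two sections
cannot be aligned and keep offset 0 with a warning. An optional manual
override is unnecessary in the synthetic setting and deliberately not
modelled. Aligned positions are partitioned into half-open 800 μm bins
[k·w, (k+1)·w) for per-segment analyses; segment names (L1–L6) are
annotations on bins, not inputs.

## Density estimation

Each experiment's normalized (x, y) positions become a density matrix on
a regular grid (default 25 μm spacing over the full frame, i.e. 68×36
cells — at least 30 cells per axis while keeping every pairwise
correlation effectively instantaneous). Each cell contributes a
separable Gaussian kernel truncated at 4σ and renormalized, so the
matrix sums to exactly 1 by construction rather than within floating
tolerance; marginals (row/column sums, or direct 1D convolutions)
likewise sum to 1. The bandwidth is data-driven per axis:

    σ = SD(sample) · n^(−1/5)

a Scott-type rule — the standard one-dimensional shrinkage of the sample
SD, applied separately to x and y. It is configurable
(`density.bandwidth_rule: "fixed:<μm>"` pins a constant width, useful
for comparing cohorts of very different sizes). Degenerate samples
(n < 2, or zero SD) fall back to a 10 μm minimum bandwidth — about one
soma radius, the resolution floor of cell-detection coordinates — with a
warning.

### Median-centred correlation

Two density matrices on a shared grid are compared with a correlation
coefficient whose centring statistic is the **median over grid entries**,
not the mean. Anatomical density maps are mostly empty: the median
tracks the empty background, so r responds to where the labelled mass
sits rather than to overall occupancy. The implementation follows the
double sum over all (i, j) grid entries; it is symmetric, returns
exactly 1 for positive affine transforms, and raises an explicit error
when either matrix has zero median-centred variance (e.g. a constant
map), recorded as a missing entry in pairwise matrices. Group-level
("pooled") densities concatenate cells across experiments before
convolution — each animal contributes in proportion to its cell count —
rather than averaging per-experiment maps.

## Effect sizes

Positional contrasts are reported exclusively as effect sizes. With
coordinate samples of 10³–10⁴ cells, p-values flag micrometre-scale
median differences far below the soma-diameter resolution of the data,
and the nested animal/cell structure violates pooled-test independence
assumptions; the package therefore exposes no hypothesis tests at all.

Hedges' G is the bias-corrected standardized mean difference
g = J·(m_a − m_b)/s_pooled with
s_pooled² = ((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2) and
J = 1 − 3/(4(n_a+n_b) − 9). |G| bands: none < 0.2 ≤ small < 0.5 ≤
medium < 0.8 ≤ large.

Group comparisons use a two-level bootstrap: animals resampled with
replacement, then each drawn animal's coordinates resampled with
replacement at the animal's own sample size (preserving per-animal
weight), pooled into one replica sample; 5000 replicas per group.
Replica i of group A is paired with an independently drawn uniform
replica of group B — pairing is random across the replica sets rather
than index-locked — and g is computed per pair from the replicas'
sufficient statistics; the median and (25th, 75th) percentiles of the
5000 g values are reported. Everything is driven by one seed; the same
seed reproduces the result bit for bit. With a single animal per group
the procedure degrades gracefully to a flat bootstrap of that animal's
cells. Per-experiment-pair comparisons (the lower-triangular |G|
matrices) use plain, non-bootstrap G on the two experiments' quadrant
coordinates; the bootstrap is reserved for group-level contrasts —
where a reported pairwise summary is the median and IQR over the signed
per-pair values.

## Count analyses

Section-sampling tokens ("1/2 (30 μm)", "All (40 μm)", …) parse to
fractions; whole-cord totals are estimated as count/fraction. The
power-law fit of premotor-interneuron against starter-motor-neuron
counts is ordinary least squares on (log x, log y) — the conventional
meaning of "fitted by a power law with an R²" and the form matching the
log-log axes such data are plotted on; nonlinear least squares in linear
space would let the few largest experiments dominate. Both counts are
scaled by the sampling fraction before fitting (both are per-animal
totals undercounted by the same sampling); a config switch
(`counts.scale_both`) disables scaling of the x axis. Records with
unknown or zero motor-neuron counts — including all rows from the
laboratory that did not identify infected motor neurons — are excluded
and reported, never coerced to zero. On the shipped 51-record reference
subset this fit gives R² ≈ 0.49 with exponent ≈ 0.53.

Interneuron/motor-neuron ratios are summarized as median and IQR per
titre class (high ≥ 5×10⁹ IU/ml, low < 10⁹; intermediate titres
unclassified). The grouping is an explicit predicate argument because
published group summaries of this kind depend on exactly which
experiment subset enters, which is rarely fully recoverable; callers can
and should state their own subset. Starter-cell bookkeeping for double
injections selects, by default, experiments with both LG and TA rows
and a recorded double-labelled count, and sums per-muscle and
double-labelled motor neurons; selected rows with a missing count are
excluded with a warning.

## Synthetic cohorts

The generator emulates what the analysis assumes about real tracing
data: interneurons drawn from a four-component Gaussian mixture anchored
to the quadrants — dominant dorsal-ipsilateral cluster centred at
(320, 230) μm, matching the ~315–330 μm dorsal-ipsilateral medio-lateral
medians real experiments report; ventral-ipsilateral (300, −200);
ventral-contralateral (−250, −200); sparse dorsal-contralateral
(−300, 230) — with default weights 0.55/0.25/0.15/0.05 (ipsilateral
fraction ≈ 0.8, as in real count tables). Starter motor neurons (Poisson,
mean 30) sit in the ventral ipsilateral horn. GlyT2-on (glycinergic)
probability is quadrant-dependent (0.80 ventral-ipsi vs 0.20
ventral-contra), emulating the empirical inhibitory/excitatory
asymmetry. Cell counts per animal are negative-binomial (mean 800,
dispersion 10 → roughly 500–1200, inside the tens-to-thousands range of
real experiments). z is uniform over a 4800 μm lumbar extent (six
800 μm segments); sections are cut every 60 μm, landmark magnitudes
bulge ~12% at the centre (the lumbar enlargement the alignment step
keys on) with 4% multiplicative noise, and section subsampling keeps
every k-th section for fraction 1/k.

Cells are drawn in the idealized frame, folded into their cluster's
quadrant (reflection across the axes; negligible mass is affected at
these centre/SD combinations), and mapped into raw section coordinates
by inverting each section's normalization map — so generated files
exercise reading, normalization and alignment end-to-end, and
normalizing a generated experiment recovers the idealized draws exactly.
A `delta_ml_um` offset shifts the second muscle's clusters medio-
laterally, providing ground-truth segregation for power checks.

Two deliberate departures from realism, chosen once:

* **Per-animal jitter SD is 10 μm**, below the ~35 μm between-animal
  spread real per-experiment medians suggest. The generator's null
  cohorts are calibration objects: with 6 animals per group, a 35 μm
  animal effect would put the *realized* standardized difference of a
  truly null cohort near |g| ≈ 0.2 — indistinguishable from a small
  effect at feasible animal numbers, exactly the regime effect-size
  reporting is meant to expose, but useless for verifying that the
  pipeline reports null cohorts as null. 10 μm keeps the animal effect
  below the no-effect detection floor while still exercising the
  hierarchical structure.
* **Count dispersion is mild** (r = 10) so every animal's density map is
  estimated from hundreds of cells and pairwise correlations of
  same-distribution animals stay above 0.9; real cohorts include
  ~70-cell experiments whose maps are substantially noisier (real
  pairwise correlations go down to ~0.45–0.78).

Consequently, passing null-cohort tests demonstrates correctness of the
machinery, not that 6-animal studies of real variability resolve 0.1-SD
effects — they do not.

## Numerical choices

* Kernel truncation at 4σ with per-cell renormalization keeps the
  unit-mass invariant exact and the cost bounded; a cell whose 4σ window
  misses every grid centre (pathological bandwidths only) is assigned to
  its nearest centre rather than dropped.
* The bootstrap uses a fully vectorized path when all animals in a group
  have equal cell counts and a per-replica loop otherwise; both paths
  consume the generator identically seeded and are checked against each
  other statistically.
* Replica g values are computed from per-replica (n, mean, variance)
  sufficient statistics — exact, and memory-light at 5000 replicas.
* Degenerate inputs fail loudly and specifically: zero-magnitude
  landmarks, empty cell sets, zero pooled SD, zero median-centred
  variance and off-grammar sampling tokens each have a dedicated
  exception naming the offending object.
* Seeds: one root seed per run; child streams derive from
  (seed, muscle index, animal index) so any single experiment can be
  regenerated without its cohort.

## Limitations

* The normalization is piecewise-linear per quadrant; it corrects size,
  not shape — no nonlinear atlas registration is attempted, and
  systematic shape differences between cords survive normalization.
* Density maps are 2D projections along z; rostro-caudal structure is
  handled only by binning.
* The synthetic generator draws sections independently and omits
  double-labelled cells (cells carrying both tracer channels are
  supported by the data model and, per the default configuration, would
  contribute to each channel they carry, but the generator does not
  produce them).
* The reference count table supports count analyses only; per-cell
  coordinates of the original experiments are not included, so printed
  positional medians (e.g. 329 vs 315 μm for LG vs TA) are covered by
  parameter-recovery tests on synthetic cohorts rather than recomputed
  from raw data.
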