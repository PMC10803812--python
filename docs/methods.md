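# Methods

## Reactor model and number balances

The reactor is treated as a continuously stirred tank (CSTR): bulk water
of volume *V* (mL) at concentration C_AR (cells/mL), influent flow *Q*
(mL/min, converted to mL/day as Q×1440) at the tap-reservoir
concentration C_tap, and a wall biofilm pool with areal concentration
C_BF (cells/cm²) on colonizable area *A* (cm²). All balances run on
intact cell counts (ICC), the fraction of cells that still have an
intact membrane and therefore the most meaningful count in chloraminated
water. Growth/decay in the bulk and biofilm↔bulk transfer are not
separately identifiable from counts, so they are lumped into the Net
Growth/Transfer Rate (NGTR, cells/day):

    dN/dt = C_tap·Q − C_AR·Q + NGTR

**NSS estimator.** Between two biofilm sampling days t₁ < t₂,
accumulation is Δ[C_AR·V + C_BF·A]/(t₂−t₁) and the advective terms use
the arithmetic mean of all bulk events in the half-open window (t₁, t₂]
(half-open so adjacent windows partition a series without double
counting). The bulk concentration entering the storage term is taken
from the nearest reactor event within 3 days of each biofilm day —
biofilm coupons are pulled within 72 h of bulk sampling — with a
window-mean alternative available (`storage_concentration=
"window_mean"`), since either reading of "the concentration at t" is
defensible.

**ISS estimator.** At a single paired tap/reactor event, accumulation is
assumed zero and NGTR = (C_AR − C_tap)·Q. It needs no biofilm data, so
it produces many more estimates, at the cost of ignoring storage during
transients.

Both estimators store their terms, so the balance identity
(accumulation = tap − out + NGTR) can be re-verified on every estimate;
the test suite requires it to 1e-9 relative. Negative NGTR is reported,
not clamped (net decay is physically real under high chlorine); only the
tap-input/NGTR ratio is flagged undefined for NGTR ≤ 0.

**Defaults.** Q = 2.1 mL/min. V is rarely printed for annular reactors;
the default 1008 mL is back-derived as Q × 8 h HRT and logged in every
pipeline run. A defaults to 190 cm² and must be reviewed per rig: supply
the sampled-coupon area instead to restrict biofilm scaling to coupons.
Whether tap-reservoir concentrations may stand in for reactor influent
is a property of the rig (here the reservoir HRT is ~1 h and does not
measurably change water quality).

## Derived water metrics

Counts and ATP are lognormal in practice, so summaries are geometric:
geomean = exp(mean ln x), and the geometric CV is exp(sd ln x) − 1 with
the sample (n−1) sd — the conventional choice at the small n of
monitoring campaigns. Zeros are rejected, never silently substituted;
censored-value substitution (e.g. LoQ/2) is the caller's explicit move.
Phase-level ratios such as the intact fraction are exposed under both
conventions — ratio of geometric means (= geometric mean of per-sample
ratios) and arithmetic mean of per-sample ratios — because published
phase summaries do not always say which was used and the two can differ
by a point or two. ATPe = ATPt − ATPi is clamped to zero with a flag
when triplicate noise makes the difference negative. Chlorine below the
0.02 mg/L LoD is stored as 0 with a below-LoD flag (an empty CSV field
means below-LoD, not zero-as-measured). Rank correlation uses Kendall's
tau-b for its tie correction; monitoring series are full of ties.

## Imaging pipeline

Order of operations: per-slice in-plane median filter (default 3×3,
reflection at edges) → per-channel Otsu threshold computed on the
channel's **full 3-D histogram** → removal of the first four z slices →
OR-merge of channel masks → metrics. Choices worth stating:

- **Global, not per-slice, Otsu.** A per-slice threshold on an empty
  slice segments pure noise; one global threshold per channel keeps
  empty slices empty.
- **"Detected" means strictly above the threshold**; ties at the
  threshold are background. A constant channel has no threshold and
  yields an empty mask with a `degenerate` flag instead of an error —
  that is exactly what a blank control should do.
- **Base-slice removal happens after thresholding**, so the threshold
  statistics include the (later discarded) base slices. The first four
  slices are removed because dye binds the bare substrate there; the
  cut is a fixed count, not adaptive.
- **EPS metrics** merge only the protein and polysaccharide channels.
  Because that is a different channel subset, the EPS mask is not
  mathematically a subset of the three-channel mask, and
  eps_biovolume ≤ biovolume is deliberately not enforced. The EPS
  fraction is on a biovolume basis.
- MBH counts occupied slices even when non-contiguous (biofilms image
  hollow when dye penetration is limited; skipping gaps would
  understate height).
- Default geometry: 1024 px frames of 212.5 µm (pixel ≈ 0.2075 µm) at
  1 µm z steps; all configurable.

Known limitation: no bleed-over correction, registration, or
hollow-cluster volume correction — biovolume under-reports dense
biomass with poor dye penetration, as the degraded reliability of
biovolume at high biomass in real data reflects.

## Synthetic generators

**Series.** The CSTR ODE plus a biofilm pool (dN_bf/dt = B(t), with the
lumped source split into an NGTR profile and a biofilm-accumulation
profile) is integrated with classical RK4 at 1/100 of the sampling
interval — the dynamics are non-stiff (time constant V/Q ≈ 8 h), and
this satisfies the 1%-recovery requirement with margin. The cumulative
net influx is integrated with the same RK4 weights, so number
conservation holds to rounding and is asserted in tests. Measurement
noise is multiplicative lognormal with σ = ln(1 + gCV); the default
gCV = 0.1 is typical of triplicate cytometry/ATP measurements.
Infeasible scenarios (bulk concentration driven negative) raise rather
than truncate. Defaults mirror the study scale: tap ICC ~1e3 cells/mL,
reactor ICC ~1e4–1e5, NGTR ~5e7 cells/day.

**Stacks.** Clusters are hemispheres (or hollow shells) seated on the
substrate, rasterized at voxel centers. A target fraction of cluster
voxels (default 0.92) is EPS-only — protein and polysaccharide channels
— and the remainder is packed into compact spherical cell colonies
(radius 2.5 µm) carrying the nucleic-acid channel. Compactness matters:
salt-and-pepper cell voxels would be erased by the median filter,
whereas real colonies are spatially coherent. Background is sparse shot
noise (default: 2% of voxels, Gaussian amplitudes ~N(40, 10)) rather
than dense per-pixel Gaussian noise: dense unimodal noise would make a
global Otsu threshold "detect" roughly half of a blank frame, which is
not how sterile-control stacks behave; isolated bright pixels are the
noise class median filtering exists to remove. The optional base
artifact plants contiguous 3×3 patches (≥1% coverage) in slices 0–3 of
every channel, surviving the median filter so that only the base-slice
removal protects the metrics. Truth records exact voxel masks; truth
metrics are reported both for the full stack and after base-slice
removal, because a hemisphere loses its bottom four slices to the cut.

What passing on synthetic data does **not** show: robustness to
bleed-over between real fluorophores, non-uniform illumination and
depth-dependent attenuation, irregular (non-spherical) cluster
morphology, or autofluorescence — none of which the generator emulates.

## Numerical and testing notes

- Otsu is delegated to `skimage.filters.threshold_otsu` (exact integer
  histogram for 8-bit data); tests compare the resulting masks against
  an independent exhaustive 0–254 threshold search, and tau-b against
  brute-force pair counting.
- The exact-voxel-equality tests run with median kernel 1 on noise-free
  stacks: with no noise there is nothing to denoise, and any non-trivial
  kernel reshapes cluster boundaries by construction. The default kernel
  remains 3 everywhere else.
- Simulations in the test suite use 10-day series at 0.01-day sampling
  and 96–128 px stacks: large enough for sub-percent recovery and
  stable fractions, small enough that the whole suite runs in well
  under a minute.
- Determinism: every stochastic component takes an integer seed through
  `numpy.random.default_rng` seed sequences, with independent streams
  per component (clusters, background, artifact) so toggling one does
  not reshuffle another. Same seed, same bytes.
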