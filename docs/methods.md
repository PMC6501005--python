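# Methods

`periscope` implements two quantitation procedures used to ask where
heterochromatin sits in the nucleus and whether two chromatin factors
co-occupy the same megabase-scale genomic territory, together with a
synthetic-data generator that makes both procedures verifiable against
planted ground truth.

## Radial center-to-periphery profiling

### Model and procedure

A nucleus is a segmented region of a grayscale immunofluorescence image
(signal such as H3K9me2, in arbitrary fluorescence units). For each
nucleus:

1. the centroid of the binary mask is computed (unweighted by default;
   intensity-weighted available via `centroid_mode="intensity"`);
2. `n_lines = 200` rays are cast from the centroid at angles 2πk/200
   (angle 0 along the +column axis, counter-clockwise);
3. each ray's endpoint is the **last** mask pixel along the ray, located by
   marching at 0.25-px resolution — using the last rather than first
   boundary crossing means mildly non-convex nuclei are profiled out to
   their true boundary;
4. each ray is sampled at `n_points = 200` radius fractions
   f_j = j/199 ∈ [0, 1] by bilinear interpolation;
5. the per-nucleus profile is the arithmetic mean over the 200 rays at each
   f_j (the per-line 200×200 matrix is retained).

Cohorts are summarized point-wise by mean and **population** SD (stated in
output headers). The center-vs-periphery summary (MFI = mean fluorescence
intensity) averages the profile over f < 0.25 (center) and f ≥ 0.75
(periphery); the bands are configuration parameters — figures in the
literature typically plot "center versus periphery" without defining
bands, so the defaults simply split the radial axis into quartiles and use
the innermost and outermost. `peripheral_enrichment = periphery/center` is
flagged undefined when the center MFI is ≤ 0.

### Numerical choices

* **Boundary-aware sampling.** Before interpolation, every background pixel
  is replaced by its nearest in-mask value (Euclidean distance transform).
  Raw bilinear sampling at the nuclear edge averages with the zero
  background and biases the outer ~2% of the profile low by up to several
  percent; edge replication removes that bias exactly for flat fields.
  Samples landing in mask concavities likewise take the nearest boundary
  value.
* Ray endpoints at pixel precision imply a ±0.5 px jitter of the
  normalized-radius axis per ray; averaging over 200 rays reduces this to a
  sub-percent smoothing of sharp radial features.
* Degenerate inputs (mask < 4 px, centroid outside the mask, a ray finding
  no boundary) raise errors rather than returning NaN profiles.
* Profiles are rotation-invariant to < 0.1% RMS under 90° rotations and
  exactly translation-invariant under integer shifts.

## Genome-window co-enrichment

### Model and procedure

Peak sets (BED, 0-based half-open throughout) for two factors — e.g. a
histone methyltransferase and lamin B1, whose co-occupancy marks
lamina-associated-domain-like chromatin — are compared in two steps:

1. every chromosome is tiled with 1-Mb windows (last window may be short);
   each peak is assigned to exactly one window by its midpoint
   ⌊(start+end)/2⌋, so window counts sum to the peak count for any input,
   including peaks that straddle window boundaries (an `"overlap"`
   assignment that counts a peak in every window it touches is provided
   for sensitivity analysis and is documented as non-conserving);
2. the expected count of a window is its chromosome's total peak count
   divided by that chromosome's window count (ceil(L/width), including the
   short terminal window); the observed/expected ratio therefore averages
   exactly 1 per chromosome, and windows with ratio **strictly above**
   1.5-fold are flagged as enriched. Chromosomes with zero peaks yield
   undefined (NaN) ratios and are never flagged.

Association between the two factors is measured on the ratio tracks
(Spearman by default; Pearson available) over windows defined in both, and
tested by jointly permuting one track's values with a seeded RNG:
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_permutations), so p is never 0 and
equals 1/(n+1) when no permutation matches. Per-chromosome correlations
are reported on request. Note that with a minority of strongly enriched
windows, rank ties among the unenriched majority compress Spearman r
(≈0.4 in the planted scenario below) relative to Pearson r (≈0.74); the
permutation null makes either calibrated, which is why the statistic is a
configuration choice rather than a finding.

Peak-level summaries: `cobound` counts peaks of one factor whose overlap
with the **union** of the other's peaks reaches `min_overlap_bp` (each peak
counted once), via merged-interval prefix sums — verified exactly against
a per-bp brute force; because the A-side and B-side counts and the number
of co-occupied regions all differ in general, all three are reported.
`classify_peaks` assigns each peak midpoint one category with precedence
upstream > exon > intron > others, where "upstream" is a strand-aware
2-kb window ending at the TSS. `tss_composite` bins peak midpoints within
±5 kb of TSSs (100-bp bins, offsets sign-flipped on − strand genes),
normalized per 1,000 TSSs.

## Synthetic data

The generator emulates exactly the statistical structure the two analyses
assume, so recovery tests are well-posed:

* **Nuclei** are filled rotated ellipses; "normalized radius" is defined in
  the ellipse's own frame, so a planted ring at radius ≥ `ring_start`
  (default 0.75) aligns with the profiler's normalized-radius axis. Inside
  intensity is `base_intensity` (default 100 AFU) times `ring_contrast`
  (default 4) beyond the ring start; the transition is rendered as an erf
  edge of width `edge_sigma` (default 1 px) because diffraction-limited
  optics cannot produce a hard pixel step — `edge_sigma=0` gives the exact
  step for tests that need one. Additive Gaussian noise (default SD 10% of
  base) is applied inside the nucleus and clipped at 0; background is 0.
  Cohorts place non-overlapping nuclei (bounding-circle test, bounded
  retries) away from the image border. Defaults (semi-axes 45–65 px,
  axis ratio 0.7–1.0) were chosen for testability at typical confocal
  nucleus scales; the source imaging studies do not publish size or
  intensity distributions, so no claim of realism beyond that is made.
* **Peak sets**: per 1-Mb window, counts are Poisson(λ·m) with λ = 10 and
  multiplier m = 8 in a planted 20% of windows; a coupling ρ = 0.8 of
  factor A's enriched windows is shared (same multiplier) with factor B,
  the rest of B's enriched windows drawn independently. Peak starts are
  uniform within their window and never cross window edges, making planted
  per-window counts exact; the analysis side is nonetheless tested with
  boundary-crossing peaks. λ = 0 is rejected as a configuration error.
* **Annotations**: non-overlapping gene models with random strand and 1–5
  exons whose blocks span the gene body; introns are the inter-exon gaps.

What the generator does **not** emulate: optical blur beyond the ring
edge, uneven illumination, touching nuclei, chromatin texture; peak-width
distributions tied to fragment size, mappability gaps, copy-number bias,
or correlated window structure beyond the planted multipliers. Passing
recovery tests therefore demonstrates correctness of the quantitation,
not robustness to every artifact of real micrographs or real ChIP-seq.

## Verification scales

The self-calibration experiments (`periscope.evaluation`, run by the test
suite and `scripts/acceptance.py`) use: 4 mask shapes for the flat-field
identity; cohorts of 20 nuclei per contrast level {1, 2, 4, 8} with 10%
noise for recovery; 100 random fixtures each for count conservation and
overlap-oracle equality; 50 replicates × 1,000 windows for null flag-rate
calibration against the Poisson tail P(X > 1.5λ̂); 200 replicates × 200
windows (999 permutations) for p-value uniformity; and 100 replicates ×
500 windows (1,000 permutations) for power under the planted coupling.
These sizes give stable Monte-Carlo error at interactive runtimes.

## Known limitations

* The profiler assumes one connected mask component per nucleus and a
  centroid inside the mask; strongly non-star-shaped nuclei (where a ray
  crosses the boundary more than twice) are profiled along the full ray
  with nearest-boundary fill in the gaps, which flattens genuine intranuclear
  voids.
* The expected-count model treats windows within a chromosome as
  exchangeable; real genomes violate this (centromeres, assembly gaps), so
  absolute flag rates on real data inherit that bias by construction.
* The permutation test treats windows as exchangeable under the null;
  spatial autocorrelation along chromosomes would make it anticonservative.
  Block or rotation permutations would be the next step if real tracks
  showed strong autocorrelation.
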