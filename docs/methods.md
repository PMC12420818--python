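# Methods

This note documents the models, conventions and numerical choices behind
`kinetoquant`, and what the synthetic-data validation does and does not
establish about real microscope data.

## Image model and conventions

Images are `(channel, z, y, x)` arrays in raw detector units with isotropic
x/y pixel size in µm. Coordinates are `(row=y, col=x)`, 0-based, with pixel
centers at integer positions; all distances are center-to-center. The pixel
size is a required input because it varies with the microscope: the
widefield defaults in the synthetic generator use 0.1075 µm/px (6.45 µm
camera pixels behind a 60× objective) and STED-like scenes use 30 nm/px.
Quantification operates on sum projections of the full z-stack (the
widefield stacks emulated here are 2 µm at 0.2 µm intervals, 11 slices);
maximum projection is provided for display. Cells are analysed as square
crops, 250 px by default, zero-padded (and flagged) when the window crosses
the image border.

## Spot-level recruitment pipeline

The kinetochore mask is the white top-hat of the reference-marker channel
(image minus its grayscale opening by a disc) thresholded by the iterative
intermeans (isodata) rule. The structuring-element radius defaults to 5 px —
comfortably larger than the ~1 px widefield PSF sigma so spots pass while
extended background is removed; it is configurable because the optimal value
tracks the PSF scale. The isodata iteration starts at the global mean and
stops when the threshold moves by less than 0.5 intensity units for integer
data or 1e-6 of the dynamic range for float data; constant images raise an
error rather than returning an arbitrary threshold.

Spot selection takes local maxima of the top-hat image (not the raw image,
so tilted background cannot create false peaks), visits them in descending
intensity with ties broken in row-major order, and greedily accepts up to 20
maxima subject to a pairwise separation of at least the ROI diameter.
Requesting more spots than the image supplies is a warning, not an error.

ROI rasterization fixes a subtle counting convention: an even-diameter disc
is centered on the pixel **corner** nearest the detected maximum, so pixel
centers sit at half-integer offsets, and a diameter-8 disc contains exactly
4 × 13 = 52 lattice pixels (per quadrant, offsets {0.5, 1.5, 2.5, 3.5} with
dy² + dx² < 16). This makes the spot ROI and the 52-pixel background ROI the
same size by construction. Odd diameters center on the nearest pixel.

Background accrual visits candidate pixels in order of increasing Euclidean
distance from the ROI's rasterization center, ties broken row-major so the
result is platform-independent, skipping pixels inside the spot ROI or under
the kinetochore mask, and stops at the target size (52). The implementation
expands a search window geometrically but only ever accepts candidates
within the window's inscribed radius, so truncation can never reorder the
accrual; an exhaustive distance-sort oracle in the test suite verifies exact
agreement, masks included. Background candidates are enumerated per spot
(not shared across spots), so two nearby kinetochores may draw on the same
background pixels.

Per channel, `corrected = max(ROI mean − background mean, 0)`; the
zero-clipping follows the established convention for these assays but does
introduce a small positive bias when the true signal is near zero (visible
in the synthetic factor-0 condition, where noisy recruitment recovers ≈ 0.02
rather than exactly 0 — the noiseless render recovers 0 exactly). Ratios are
taken per kinetochore against the reference channel; a reference corrected
to zero flags that measurement invalid, and per-cell means are computed over
valid measurements with the exclusion count recorded. Because the 20
measured spots are the *brightest* by reference intensity, absolute per-cell
ratios carry a small selection bias (brighter reference in the denominator);
the bias is condition-independent and cancels when groups are scaled to the
control mean, which is how these measurements are reported.

## Region-level pipeline

The chromatin mask is the isodata threshold of the Gaussian-smoothed
(σ = 1 px) DNA channel, keeping the largest connected component. The
cytoplasm mask is the cell extent minus a 2-px dilation of the chromatin, so
the two regions cannot touch. How the cell extent is defined is genuinely
open; the default (crop bounds minus a 5-px border) is a reasonable stand-in
when crops tightly bound their cells, but for crops much larger than the
cell it dilutes the cytoplasmic estimate with empty background — pass an
explicit whole-cell mask (e.g. from a cytoplasmic channel threshold) in that
case, as the tests do with the generator's ground-truth cell extent.

CPC/Aurora-class channels subtract the mean cytoplasmic signal from the
chromatin mean (clipped at zero); H3pS10-class channels are taken
uncorrected, so a constant camera offset propagates into them — documented
and tested, and the reason offset-stable acquisition matters for that class.
The class map is configuration, not code, so either reading can be run. All
values are normalized by the mean DNA signal over the chromatin mask and
scaled so the control group's mean is exactly 1. Pericentromeric signals are
measured over the whole chromatin mask rather than a pericentric sub-mask.

## Line profiles and distances

Profiles are sampled with bilinear interpolation at `ceil(L) + 1` evenly
spaced points (spacing ≤ 1 px, endpoints included); widths above 1 px
average parallel lines at integer perpendicular offsets. All channels are
sampled at identical coordinates so per-channel peak positions are directly
comparable.

Group normalization maps the smallest sample value in the data set to 0 and
the peak of the group's mean curve to 100, so the mean curve peaks at
exactly 100 while individual profiles may exceed it. Group averaging
resamples every profile linearly to the median length before computing
mean ± SEM (SD/√n); this midpoint registration assumes the profiles were
drawn between corresponding landmarks and is a known limitation — no
feature-based alignment is attempted.

Gaussian fits use `offset + A·exp(−(x−μ)²/2σ²)` with initialization from
the sample extrema and second moment, bounded iterations (800 function
evaluations for the 4-parameter problem), and an explicit failure on
non-convergence. Pair separations are measured by sampling a profile along
the axis through the two detected spots (extended 8 px beyond each), fitting
each peak in a window of half-width `min(separation/2, 12)` px (at least
4 px), mapping the fitted means back to 2D and taking the Euclidean
distance × pixel size. At the STED-like sampling used here (σ ≈ 2 px) this
recovers separations down to ~0.4 µm with sub-percent mean error; strongly
overlapping peaks (separation ≲ 4σ) would require a double-Gaussian model,
which is out of scope. Intra-kinetochore distances difference the fitted
means of two markers on the same profile; fits carrying different profile
identities are rejected.

## Statistics

Distances use the classical pooled-variance Student's t-test (two-tailed);
zero pooled variance is handled by convention (equal means → p = 1, unequal
→ p = 0, flagged degenerate). Recruitment assays use Kruskal–Wallis (scipy,
tie-corrected) followed by Dunn's z on mid-rank means,
`SE² = (N(N+1)/12 − ΣT/(12(N−1)))(1/nᵢ + 1/nⱼ)` with `T = t³ − t` per tie
group, and Bonferroni adjustment over the *planned* comparisons only —
matching the practice of reporting adjusted p for the comparisons drawn on
graphs rather than all pairs. The exact multiplicity adjustment used by
common graphing software is not documented; Bonferroni-over-planned is a
deliberate, slightly conservative choice. Stars map p to
ns/*/**/***/**** at 0.05/0.01/0.001/0.0001, with boundary values assigned
to the weaker category. Replicate semantics are explicit: per-cell means for
recruitment, per-pair values for distances.

## Synthetic scenes and what they validate

Scenes are composed as expected photon fields — elliptical chromatin inside
a larger cell ellipse (edges softened by 1–2 px Gaussians), isotropic
Gaussian spots for kinetochore markers, an inner-centromere marker offset
0.12 µm inward of each outer-marker spot along the pair axis (the
experimentally observed 0.10–0.15 µm offset), and an elongated Gaussian
ridge between pair members for the pericentric CPC band — then Poisson
sampled, with additive zero-mean read noise (sd 2), a constant camera
offset (100) and unit gain. SNR is defined as peak amplitude over the noise
sd at the peak, `A/√(A + bg + σ_read²)`, and amplitudes are solved from the
requested SNR (default 10). Defocus across z uses
`σ(z) = σ₀√(1 + (z/z_R)²)` with `z_R = 0.6 µm` and peak rescaled to
conserve the in-plane integral — a documented stand-in, not an optics
simulation. Fixed seeds give byte-identical output.

Condition datasets emulate siRNA-depletion recruitment assays: 20 cells per
condition, ~30 kinetochores per cell scattered in the chromatin ellipse with
12 px minimum separation, per-kinetochore brightness jitter that is mostly
shared between channels (±30%, kinetochore size) with a smaller independent
per-channel component (±10%), and the condition factor scaling the measured
and pericentric channels only. Distance datasets render one pair per scene
at a fixed true separation with uniform orientation and jittered midpoint.

Passing tests on these scenes establishes that the pipeline recovers known
geometry and intensity scalings under Poisson + read noise at SNR 10, and
that the image-processing primitives match brute-force definitions exactly.
They do not establish robustness to features the generator omits:
chromosome texture, spectral bleed-through, photobleaching, stage drift,
overlapping/clustered kinetochores beyond the minimum-separation regime, or
mitotic-stage heterogeneity. Problem sizes in the test suite (50 pairs per
separation, 20 cells per condition, 200 Monte-Carlo fit replicates, 10,000
null t-test simulations) were chosen to make the statistical tolerances
meaningful at interactive runtimes.
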