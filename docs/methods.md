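# Methods

`punctacount` quantifies autophagosome puncta per cell in three-channel
fluorescence micrographs of cultured microglia, together with the two
companion analyses usually reported alongside such counts: immunoblot
densitometry normalized to an internal standard, and nonparametric group
statistics on the per-cell counts. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Physical calibration and the size gate

All geometric reasoning starts from the image scale, 5.62 px/μm by default
(a required configuration value, never read from image metadata).
Mammalian autophagosomes span 0.5–1.5 μm in diameter. Treating them as
spheres projected to discs, the diameter range is halved to radii
(0.25–0.75 μm), converted to pixels (1.405–4.215 px) and squared through
A = πr² to give real-valued area bounds (6.202–55.814 px²). The bounds are
rounded to the nearest integer — half away from zero, so 6.202 → 6 and
55.814 → 56 — and the resulting **inclusive** window [6, 56] px² is what
actually filters connected components: a 6-px² and a 56-px² object both
pass. The real-valued bounds are retained on the `SizeGate` object for
documentation and derived computations. A gate so narrow that both integer
bounds coincide cannot select anything on the pixel grid and is rejected as
a domain error.

The rolling-ball radius for puncta background subtraction is the largest
expected punctum radius (0.75 μm → 4.215 px): a ball of that size cannot
descend into a true punctum, so subtraction preserves puncta while removing
diffuse cytosolic staining and slow illumination gradients.

## Rolling-ball background subtraction

The background is the grayscale opening of the image with a *non-flat* ball
structuring element (heights √(r²−d²) on the disc d ≤ r): the surface traced
by rolling the ball beneath the intensity landscape. The result is
image − background, clipped at zero, and is therefore anti-extensive
(everywhere ≤ the input). Borders use edge replication. For radii above
16 px — used when flattening the structural red/blue channels with a ball of
10× the expected nucleus radius — the opening runs on a proportionally
down-sampled copy and the background is linearly up-sampled back and clipped
under the image; this is the standard large-ball shortcut and is accurate
precisely because such backgrounds are smooth by construction. The exact
(full-resolution) path is used for all puncta-channel work.

## Cell and nucleus segmentation

Each structural channel is median-filtered (3×3, one pass), rolling-ball
flattened, clipped back to 8 bit, Otsu-thresholded, cleaned by a 3×3 binary
closing then opening, filtered by a minimum area, and labelled with
8-connectivity. Watershed lines are 4-connected. Coordinates are 0-based
(row, col), pixel-centred.

Adherent objects are split by marker-controlled watershed. Markers are
local maxima of the Gaussian-smoothed, preprocessed but *unthresholded*
nuclear channel, kept only where they coincide with a labelled object;
the inverted intensity is flooded within the foreground. Regions containing
no marker pass through unchanged, so splitting never destroys objects.

A candidate cell region becomes a cell record only under the
mutual-exclusion rules:

* ≥ 1 nucleus centroid inside the region (otherwise it is anucleate debris);
* mean marker intensity ≥ the adequacy threshold (otherwise it is a bare
  nucleus without genuine marker staining);
* area ≥ the minimum cell area (40 μm² by default).

Regions holding several nucleus centroids are first re-split by watershed on
the Euclidean distance transform with the nucleus centroids as markers, so
each kept cell carries exactly one nucleus. Nucleus–cell pairing is decided
by centroid containment, with boundary ties going to the lower label id.

**Adequacy threshold.** The automatic default is Otsu over the sample of
per-candidate mean marker intensities *augmented with the field's background
marker level* (median marker intensity outside all candidate regions).
Otsu over candidate means alone has a failure mode: when a field happens to
contain no marker-negative object the means are unimodal and Otsu splits the
genuine cells in half. Appending the background level anchors the negative
class, so the threshold lands between background and cells in every field
composition. A fixed numeric threshold can be configured instead.

## Punctum detection

1. Rolling-ball subtraction (4.215 px) on the raw green channel.
2. Per-image threshold. The default is a **recursive Otsu**: plain Otsu is
   computed first, and while the resulting foreground exceeds 5% of the
   field — physically implausible for sparse spots, and the signature of
   Otsu splitting the background noise instead of separating the spots —
   the threshold is recomputed on the above-threshold pixels only (at most
   five iterations). On fields where plain Otsu already separates spots the
   recursion is a no-op; on sparse fields (few cells, few puncta) it moves
   the threshold from inside the noise (≈ 8 intensity units) to the correct
   spot/background boundary (≈ 50). A fixed-value mode exists for strict
   reproducibility.
3. Refinement at 4× resolution (nearest-neighbour replication up): holes
   filled, touching blobs split by watershed on the Euclidean distance
   transform with maxima at least one minimum punctum radius apart, then
   mapped back by per-block majority vote of basin labels with a one-pixel
   separating line between distinct basins. Area accounting stays in
   original-resolution pixels, so the size gate keeps its physical meaning.
4. Connected components (8-connectivity) outside the inclusive [6, 56] px²
   gate are discarded.
5. Each surviving punctum is assigned to the cell whose mask contains its
   rounded centroid; puncta outside every cell are non-cytosolic signal and
   are dropped. Counts are reported per cell, zeros included — the
   zero-inflation is real signal for the nonparametric tests.

## Densitometry

Film scans encode signal as darkness, so 8-bit intensities are inverted
(OD = 255 − I) before integration; a linear mode exists for scans already in
density units. A band's integrated optical density is the OD sum over its
rectangular region. Background is estimated per band, by default from the
rolling-ball opening of the OD image (a user-supplied background region,
median OD × band area, is the alternative; background subtraction can be
disabled). Each target band is divided by its lane's internal-standard band
(GAPDH) and expressed as percent of the control lane, which therefore reads
exactly 100 by construction. The chain is invariant to uniform exposure
scaling up to 8-bit quantization.

## Group statistics

Shapiro–Wilk screens each group (n ≥ 3 required). The screen is advisory:
both tracks are always computed and the normality rule merely flags which
one it selects. The parametric track is one-way ANOVA with Tukey's HSD
(used for densitometry and cells-per-field); the nonparametric track is
Kruskal–Wallis with Dunn's post-hoc z tests under Bonferroni adjustment
(used for per-cell counts). Per-cell counts are small integers, so ties
dominate; the tie correction Σ(t³−t) is applied both in H and in the Dunn
variance. Degenerate inputs are defined rather than erroring: fully tied
samples give H = 0 (p = 1), equal group means give F = 0, and a constant
sample is flagged non-normal. Percentiles (the 10–90 box whiskers) use
linear interpolation between closest ranks.

`power_check` calibrates the decision chain against the generator's count
model directly (negative-binomial draws, no image rendering), reporting the
rejection rate of the affected contrast's Bonferroni-adjusted Dunn p over
seeded simulations. Under a two-group null this estimates the type-I error,
which lands near the nominal α = 0.05.

## Synthetic scenes and what they show

The generator renders 8-bit RGB fields (600×600 px ≈ 107×107 μm at
5.62 px/μm) containing:

* star-convex cells (base radius 5.5–8 μm, mild second/third-harmonic
  lobes, marker level 130 ± 10% jitter) each around one nucleus rendered as
  a Gaussian intensity bump (diameter 5.5–7 μm, peak 210);
* diffuse cytosolic green signal (level 30) plus hard-disc puncta
  (diameter uniform on 0.5–1.5 μm, peak 160), 80% placed within one nucleus
  radius of the nuclear boundary (perinuclear), non-overlapping;
* anucleate marker-positive debris and marker-negative free nuclei as
  confounders, and 25% of cells placed as adherent pairs to exercise the
  splitting path;
* a 1-px Gaussian point-spread function and Gaussian read noise (σ = 8;
  SNR, defined as punctum peak over noise sigma, is 20 by default).

Puncta per cell follow a negative binomial (mean 8, dispersion 2) — counts
of discrete organelles are overdispersed, and the published summaries for
such data are medians and percentiles rather than distributions, so this is
a declared assumption, not a measured fact. The eight-group study layout
(control, LPS, RST, LPS+RST, each with and without bafilomycin A1
pretreatment) applies multiplicative effects: BAF multiplies expected cells
per field by 0.525 (emulating the reported ≈45–50% proliferation reduction)
and mean puncta per cell by 1.5 (fusion blockade accumulates
autophagosomes); treatment multipliers default to LPS 1.25, RST 0.8,
LPS+RST 1.5. These magnitudes are qualitative emulation only. Cells per
field are Poisson around the group expectation (minimum 1).

Scenes are bit-deterministic for a fixed seed (integer-grid rendering, one
PRNG, fixed operation order), and the ground truth lists exactly the placed
objects, so per-cell counts match the rendered puncta one-to-one. A field
too crowded for the separation constraints raises a placement error after
bounded retries rather than silently overlapping.

What passing recovery tests show: the pipeline's stages compose correctly,
the exclusion rules fire on the confounders they were designed for, and the
detector is unbiased at the study's noise level (per-cell count MAE ≈ 0.3,
group means within ≈5% of truth, exact cell counts). What they do not show:
performance on real micrographs — real microglia are ramified rather than
star-convex, real backgrounds are structured, puncta cluster and overlap,
and staining varies within cells. The synthetic study validates the
software, not the biology.

## Problem sizes

Defaults were chosen so a full validation cycle runs comfortably on a
single CPU: the recovery study uses 8 groups × 7 fields (56 fields, ≈ 480
cells); statistical calibration uses 500 null simulations and 200 power
simulations at 100 cells/group. All sizes are plain function arguments and
scale up directly.

## Known limitations

* Cell bodies only: ramified processes are neither rendered nor recovered,
  and puncta in thin processes of real cells would be missed when the
  marker threshold excludes faint processes from the cell mask.
* The per-image threshold assumes puncta occupy < 5% of the field; a field
  tiled wall-to-wall with signal would defeat the recursion guard.
* Densitometry models film scans as linear 8-bit inversions;
  chemiluminescence saturation is out of scope.
* Watershed splitting of punctum clumps larger than two or three organelles
  is unreliable at this resolution — inherent to the data, not the code.
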