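# Methods

This note records the models, the defaults that matter, the numerical
choices, and what the synthetic fixtures do and do not establish.

## Barcode geometry and codebook construction

A codebook assigns every gene (and every blank control) a binary word
of length `n_bits` with exactly four on-bits and pairwise Hamming
distance ≥ 4.  For constant-weight-4 words the distance between two
words is `8 − 2·overlap`, so MHD4 is equivalent to sharing at most two
on-bits — the test used by the greedy constructor.  MHD4 gives
single-bit error correction: after any one-bit flip the true codeword
remains the unique nearest word.

Construction is greedy-randomized: the enumeration of all C(n_bits, 4)
weight-4 words is shuffled and words are accepted if compatible with
everything accepted so far, with up to 10 restarts.  Greedy saturates
well below the true capacity at small `n_bits` (about 100 of the 140
possible words at 16 bits), so on failure the generator falls back to
the parity-closed pool — the weight-4 words whose on-bit indices XOR
to zero.  These are the weight-4 codewords of the (shortened) extended
Hamming code, hence pairwise distance ≥ 4 by linearity, and any subset
of them is a valid codebook (140 words at 16 bits).  Requests beyond
both routes raise a capacity error.

Metropolis–Hastings balancing permutes the gene↔barcode assignment to
spread high-expression genes across readout bits.  No cost function is
canonical here; we use the squared per-bit expression load
`Σ_bit (Σ_genes-with-bit-on prior_g)²`, which directly penalizes
co-occurrence of high expressors in one round.  Proposals swap the
barcodes of two random genes; acceptance is `min(1, exp(−Δ/T))` with
T = 1.0 in cost units, and the best state visited is returned, so the
result never costs more than the input.  Blanks keep zero prior load
but participate in all distance constraints.

## Pre-processing

* **Flat-field**: per-color per-pixel median across first-round fields
  of view, clamped below at 1% of its global median so division cannot
  blow up in dark corners.  Images are divided by the unit-mean field,
  which removes vignetting while preserving the photometric scale on
  which the brightness threshold (3600) is defined.
* **Deconvolution**: Wiener filtering with the supplied PSF; the
  regularization balance defaults to 0.05 and is exposed as a config
  scalar.  Output is clamped at zero.
* **High-pass**: subtractive Gaussian (`image − blur(image, σ=30)`)
  clamped at zero.  A Butterworth formulation would also fit the
  requirement; the subtractive form is chosen because it is exactly
  linear-shift-invariant before the clamp and trivially auditable.
* **Drift**: anchor extrema (DAPI local maxima) are rendered as sparse
  indicator volumes and registered by FFT phase correlation at integer
  pixel resolution, including z.  Drift is applied to coordinates
  downstream — images are never resampled, so brightness statistics are
  untouched.  Integer resolution is exact on the fixtures by
  construction; sub-pixel drift in real data would add a ≤ 0.5 px
  positional error this package does not model.

## Spot calling

A spot is a strict 26-connected 3D local maximum (plateaus collapse to
their lexicographically smallest voxel) passing the brightness
threshold, whose psf-window patch correlates with the PSF at ≥ 0.25
(Pearson; edge candidates use the valid overlap).  Brightness is the
pixel value at the maximum.  smFISH channels add a local-median
relative-background ratio test with per-channel configurable ratios.

## Decoding

Pixel path: each pixel's per-bit brightness vector is multiplied by the
per-bit scale factors, L2-normalized (pixels below norm 1e-9 stay
unassigned), and matched to the nearest L2-normalized barcode; matches
at distance ≤ 0.6 take that gene.  The cutoff is the single-bit error
margin: equal-amplitude words with one on-bit dropped lie at
√(2−√3) ≈ 0.5176, with two dropped at √(2−√2) ≈ 0.7654.  Same-gene
pixels merge under 6-connectivity (4 in-plane); components below
`min_pixels` are dropped.  Components report centroid, pixel count,
mean brightness (mean vector norm), minimum barcode distance, and RMS
spread.  Distance ties resolve to the lowest barcode index.

Scale factors are estimated by iterative decoding (default 10
iterations) of a z-slice sample, keeping molecules of ≥ 5 pixels and
equalizing mean on-bit brightness across bits; factors are rescaled to
geometric mean 1 each iteration so the global scale cannot drift.

Cluster path: per-bit spots are drift-corrected and linked within 2 px
(union-find over KD-tree pairs); clusters of ≥ 3 spots — the minimum
that still identifies a weight-4 barcode under one dropout — form a
per-bit brightness vector (summed spot brightness; a binary mode is
available) matched against the codebook the same way.

The fixed stage order is flat-field → deconvolve → high-pass → scale
factors → per-pixel L2 → decode.

## Quality control

Because blanks are never planted (nor probed, in real experiments),
blank detections measure the false-discovery process.  The
misidentification rate is normalized per barcode,
`MIR = (N_blank/B_blank)/(N_total/B_total)`, so it does not depend on
the gene-to-blank panel ratio.  The adaptive filter bins molecules in a
3D histogram over (pixel count, mean brightness, min distance) with
equal-occupancy edges (10 bins/axis; heavily tied axes fall back to one
bin per distinct value) and removes bins in ascending gene-to-blank
ratio until MIR ≤ 5%, flagging the result if the target is
unreachable.

Fisher scores combine three per-molecule metrics by
`S = −2 Σ ln p_i` where `p_i` is the empirical fraction of molecules at
least as *bad* on that metric (best molecule: p = 1 on all three,
S = 0; probabilities floored at 1/(n+1)).  Under independent uniform
metrics S is χ² with 6 df.  The gene/blank score threshold sits at the
KDE valley (Silverman bandwidth) between the two population modes,
falling back to the 25% blank quantile with a warning when the pooled
density has no interior valley.

Cell assignment rounds drift-adjusted coordinates (halves away from
zero) into the segmentation label mask; label 0 and out-of-bounds stay
unassigned.

## Spatial statistics

Neighborhoods are configurable as k-nearest (default k = 30, matching
the density k) or radius (default 30 μm, matching the enrichment
radius); both are first-class because no single definition is canonical
across the analyses.  Co-existence is the Pearson correlation between
two cell types' neighborhood-proportion columns; the graph keeps edges
at score ≥ 0.07 and the dendrogram is single-linkage over cityblock
distances between score rows.  kNN density divides the same-type
neighbor count within the k-th-neighbor radius by the sphere volume;
the radius is inflated by one ulp-scale epsilon so the k-th neighbor is
never lost to floating-point rounding.  Density-percentile filtering
removes `floor(f·n)` lowest-density cells per round for
f = 10%, 3%, 0.5%, recomputing densities each round (1000 → 900 → 873 →
869).  Gradient correlations are Pearson on log1p expression versus
min-max-normalized position.  Path enrichment bins cells within the
radius of a polyline by normalized arc length (20 bins) and divides
local type frequencies by background frequencies; zero-background types
present locally are reported missing with a warning.

## Vascular tree

Marker cells are the top 3% by MYH11 expression (ties at the cutoff all
included), density-filtered, then clustered per section with DBSCAN
(eps 50 μm, min_samples 5, in-plane coordinates, noise excluded); each
cluster is a cross-section node with the unweighted member centroid.
Trees build top-down: all nodes of the topmost nonempty section are
roots; later nodes (per section, by descending member count then id)
attach to the visited node minimizing
`w·ℒ_angle + (1−w)·ℒ_euc`, w = 0.5.  ℒ_angle = 1 − arccos(cos θ)/π
over three consecutive nodes (0 collinear, 0.5 right angle, 1
reversal); parentless candidates have no angle term.  ℒ_euc is the
squared centroid distance, which as printed lives in μm² and would
swamp the unit-interval angle term, so it is normalized per candidate
set.  Min-max rescaling was tried first and rejected: on a Y-shaped
fixture it made section-skipping links nearly free (the global range is
dominated by distant candidates) and produced spurious bifurcations.
The default is therefore the relative form `d²/d²_min − 1` — zero for
the nearest candidate, growing in units of the nearest squared distance
— which keeps distance decisive against skips while letting the angle
term arbitrate near-equidistant candidates at true branch points;
`minmax` and `raw` modes remain available.  Manual (child, parent)
edges override the loss where a vessel locally ascends against the
section order.  Every build asserts the forest invariants (in-degree ≤
1, acyclic, strictly top-down, no intra-section edges).

## Layer geometry

Layers are closed outward-oriented triangle meshes; thickness rays use
the negated vertex normal.  Ray casting is a vectorized Möller–Trumbore
intersector over the full face set (the meshes here are 10³–10⁴ faces;
a spatial index would add nothing), with origins nudged 1 μm·10⁻⁶ off
the surface, near-duplicate hits through shared edges deduplicated, and
grazing rays retried with a minutely perturbed direction.  Septum
classification first labels each endocardial vertex IVS if its outward
normal hits the opposite endocardium, then classifies epicardial
vertices by their inward-normal intersection pattern (no endocardial
hit, or a hit landing on an IVS-labeled region → IVS; a hit on a
non-IVS region of the right/left endocardium → right/left wall);
nearest hit wins when both endocardia are struck.  Layer thicknesses
are the differences of consecutive first-hit distances along one ray,
so they telescope exactly to the outer-to-inner total; inverted hit
order flags the vertex and its values are reported missing.

## Synthetic study conditions

The standard decoding conditions are a 16-bit codebook of 100 genes +
40 blanks (the full 140-word code at 16 bits) with 500 molecules
planted on a 3 × 400 × 400 px stack at peak amplitude 8000, PSF σ 1.2
px, and a minimum in-plane Chebyshev separation of 12 px — chosen
because decoding is scale-invariant after normalization, so even faint
PSF-tail overlap merges same-gene molecules.  The noisy variant adds
lognormal amplitude scatter (CV 0.5) and additive Gaussian background
(σ 300, ~4% of peak), which after high-pass filtering yields roughly
equal numbers of real and spurious decoded entries and an initial
misidentification rate near 50% — a deliberately harsh operating point
for the adaptive filter, which reaches ≤ 5% while retaining all
planted molecules.  Problem sizes throughout (hundreds of molecules,
10⁴ cells, icosphere meshes at subdivision 3) are chosen so any single
check completes in seconds on one core.

What the fixtures do not model: optical aberrations and z-extended
PSFs, autofluorescence and structured background, sub-pixel drift,
segmentation errors, and amplitude correlations across bits.  Passing
tests therefore establish correctness of the algorithms under their
stated assumptions, not performance on real tissue.

## Known limitations

* Drift is integer-pixel; sub-pixel registration is out of scope.
* The pixel decoder holds the whole stack in memory; fields of view
  larger than ~10⁸ voxels × bits should be tiled by the caller.
* DBSCAN cross-sections merge vessels that pass within ~eps of each
  other in one section, which delays detected bifurcations by about one
  section on diverging branches.
* Mesh reconstruction from point clouds is not provided; meshes are
  inputs.
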