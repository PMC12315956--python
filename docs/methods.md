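# Methods

## The measurement

In a wound-healing assay a confluent monolayer is interrupted by a
straight cell-free band. Cells adjacent to the band ("outer" cells)
polarise toward it; the position of the centrosome relative to the
nucleus is the readout. For each cell the pipeline computes the signed
angle θ between the nucleus→centrosome vector (2D; z is ignored for
orientation) and that cell's *wound normal* — the in-plane unit vector
from the nucleus toward the nearest point of the band. Angles are in
degrees in (−180°, 180°], counterclockwise positive. A centrosome is
*properly located* iff |θ| ≤ 75° (a 150° sector facing the wound;
boundary inclusive — a measure-zero convention declared for
determinism).

Per condition the pipeline reports: n (outer cells with an assigned
centrosome), the in-sector proportion, a rose histogram with 24 bins of
exactly 15° edge-aligned at multiples of 15° (so ±75° are bin edges and
the sector is exactly 10 bins; +180° folds into the top bin), the
circular mean direction and resultant length R, and Kuiper's test of
uniformity. Cells whose centrosome coincides with the nucleus centroid
have no defined angle and are excluded (counted). Inner cells are
excluded from the headline statistics by default and can be summarised
separately.

## Statistical procedures

**Kuiper's test.** Angles are mapped to u = (θ+180)/360 and sorted;
V = D⁺ + D⁻ with D⁺ = max(i/n − u₍ᵢ₎), D⁻ = max(u₍ᵢ₎ − (i−1)/n). V is
invariant to rotation of all angles (tested property). The p-value uses
Stephens' finite-sample modification V* = V(√n + 0.155 + 0.24/√n) and
the series p = 2Σ_{j≥1}(4j²V*² − 1)e^{−2j²V*²}, truncated when terms
fall below 1e-10 and clamped to [0, 1]. The approximation is coarse for
n < 8; callers should treat such p-values as indicative.

**Two-proportion comparison.** Pooled-variance normal approximation
with the Yates half-unit continuity correction,
z = (|p̂₁−p̂₂| − ½(1/n₁+1/n₂)) / √(p̂(1−p̂)(1/n₁+1/n₂)), the corrected
difference clamped at zero; the reported statistic is χ² = z², which
without the correction is algebraically the Pearson χ² of the 2×2 table
(checked numerically against an independent χ² implementation). Both
one- and two-sided p-values are reported: the worked 161/230 vs 167/309
example reproduces the reference value 1.24e-4 only in its one-sided
form, so both are always available to the caller.

**Welch's t test** (smFISH proximity comparison) uses the
unequal-variance statistic with Welch–Satterthwaite degrees of freedom,
one-sided with a configurable direction (default: control greater,
matching the hypothesis that depletion reduces centrosomal mRNA
localisation). The implementation delegates to scipy; the test suite
checks it against the closed-form expressions to 1e-10.

## The synthetic field generator

The generator is the package's ground-truth source; its defaults are
the study conditions used throughout the tests.

- **Geometry.** A straight band (default ±20 µm around the origin)
  separates two monolayer strips. Nuclei (radius 5 µm) are placed by
  rejection sampling with minimum centre distance 2.2 × radius,
  bounded at 10⁴ consecutive rejections (then a generation error).
  Nucleus centres keep one radius clear of the band.
- **Angular model.** Centrosome directions are von Mises(µ, κ) around
  each cell's wound normal; κ = 0 is circular uniform. The paperless
  choice here is deliberate: the von Mises family is the minimal
  unimodal circular family, and the generator makes no claim that real
  angular data follow it — it is the stand-in that lets sector
  proportions be dialled analytically. `sector_probability` integrates
  the density by adaptive quadrature (absolute error < 1e-8, with the
  exponentially-scaled Bessel normalisation for large κ);
  `calibrate_kappa` inverts it by Brent root-finding (|Δp| < 1e-6).
  Presets: control → κ = calibrate(0.70) ≈ 0.978, depleted →
  κ = calibrate(0.54) ≈ 0.399, uniform → κ = 0.
- **Centrosome offset.** 5 µm from the nucleus centroid — i.e. at the
  nuclear envelope, the juxtanuclear position centrosomes occupy. This
  also guarantees that each centrosome is geometrically closer to its
  own nucleus than to any neighbour at the minimum packing distance, so
  the nearest-centroid assignment rule is exact on ground truth.
- **Zone ground truth.** A cell is outer iff its nucleus centroid lies
  within d_outer = 1.5 × nucleus diameter (15 µm) of the nearer band
  edge. Nuclei are kept a 3 µm margin away from the d_outer line:
  the outer/inner boundary is an operational convention, so cells
  sitting exactly on it have no defined truth and would only measure
  the tie-break, not the classifier.
- **smFISH spots.** Per cell, Binomial(spots_per_cell, fraction) spots
  are placed uniformly in a 3D ball of 0.9 × the colocalization radius
  around the centrosome; the rest are scattered in the cytoplasm
  strictly outside 1.1 × the radius (the 10% guard bands keep the
  ground-truth near/far labels stable under sub-voxel localisation
  error). Defaults: 20 spots/cell, fraction 0.3, radius 2 µm.
- **Rendering.** Nuclei are smoothed disks (top-hat ⊗ 0.5 µm Gaussian,
  Gaussian axial profile) so the segmented equivalent diameter matches
  the true diameter; puncta are anisotropic 3D Gaussians
  (σ = 0.7/0.3/0.3 µm in z/y/x) normalised so each spot's integrated
  intensity equals its nominal amplitude (default 1000 counts ×
  lognormal(σ=0.15) per-cell variation). Background 20 counts; noise is
  Poisson on the scaled signal plus Gaussian read noise (sd 2), giving
  a punctum peak SNR ≈ 10. Voxels are anisotropic:
  (0.6, 0.2841, 0.2841) µm. All randomness derives from one master
  seed via SeedSequence children; identical config + seed gives
  byte-identical ground-truth tables.

What the generator does *not* emulate — and hence what passing
round-trip tests do not show about real data: irregular nucleus shapes
and intensity textures, overlapping or mitotic cells, curved or ragged
wound edges, uneven illumination, spectral bleed-through, clustered
transcription sites, and any microtubule or FLIM physics.

## Imaging-chain conventions

- **Projection.** Standard-deviation Z-projection with the *sample*
  (n−1) denominator, matching the common ImageJ projection; applied to
  all channels by default. A single-slice stack passes through with a
  warning.
- **Segmentation.** Otsu threshold on a 1 µm-smoothed image, hole
  filling, watershed on the distance transform seeded at maxima
  separated by at least the minimum-area-equivalent radius; regions
  outside [20, 400] µm² are discarded. Centroids are reported in µm
  (0-based, pixel-centre convention: position = index × voxel size).
- **Spot detection.** Anisotropy-corrected Laplacian-of-Gaussian at
  per-axis scales σ/voxel; maxima above median + k × (1.4826 × MAD) of
  the response, i.e. k is in robust-σ units (default k = 5). Maxima use
  a PSF-sized footprint, border voxels are excluded (the LoG response
  on the boundary slices is a filter artefact), and positions are
  refined per axis by a 3-point parabolic fit (sub-voxel). Requesting a
  scale below one voxel is an error.
- **Centriole pairing.** Detections closer than 1 µm (single linkage)
  merge to their amplitude-weighted centroid — unresolved centriole
  doublets count as one centrosome.
- **Assignment.** Each centrosome goes to its nearest nucleus centroid
  within 15 µm; a cell keeps only its brightest candidate; the result
  is order-independent. Unassigned centrosomes are logged.
- **Wound estimation.** Directions 0–180° are scanned in 1° steps; the
  wound normal is the direction with the largest interior gap in the
  projected centroids, accepted if it exceeds 3 × the median
  nearest-neighbour distance. Because centroids stand off the physical
  edge by about one nucleus radius, the pipeline shrinks the gap by the
  median nucleus radius per side (edge inset) before classifying zones.
- **Zone classification.** Outer iff distance to the nearer edge line
  ≤ d_outer (inclusive); d_outer defaults to 1.5 × the median nucleus
  equivalent diameter (cell-size–based, hence magnification
  independent); for coordinate tables without diameters, 1.5 × the
  median nearest-neighbour distance is the proxy.
- **Detectability.** A cell's marker signal is detectable iff its
  assigned centrosome's LoG response clears the detection threshold at
  the chosen k; the summary is the percentage among outer cells.

## Intensity quantification

ROI membership is a pixel-centre test (bit-stable areas; no
partial-pixel weighting). The local background is, by default, the mean
of the lowest-variance equal-size ROI among 16 candidates on a ring of
2 × the ROI radius around the centrosome (the deterministic reading of
"a nearby region with similar background intensity"); an annulus
(1.2–1.6 radii) strategy is available. Records whose ROI or background
cannot be measured (image edge, outside the cell mask) are flagged and
excluded from aggregation, and net values are never clamped at zero so
noise statistics stay unbiased. Centrosome ROIs default to Ø2 µm (no
published figure exists for this ROI; it is configurable), aster ROIs
to Ø5 µm — the same code path with a different diameter and channel.
Per-image aggregation flags images with fewer than 5 cells (bounds
configurable; detectability summaries conventionally use 7–15).
Quantification runs on the summed Z-projection of the marker channel,
which is linear in amplitude, so offset invariance and gain linearity
hold exactly.

## Proximity (smFISH) conventions

Distances are 3D Euclidean in µm after voxel-size conversion (the 0.6
µm axial step matters: a spot 1.2 µm lateral and 1.8 µm axial from the
centrosome is 2.16 µm away and does not colocalize at 2 µm); if either
object lacks z, the distance is 2D. The 2 µm boundary is inclusive.
Cells with zero spots are excluded (a proportion is undefined), not
scored as zero; cells without a centrosome likewise — both tallies are
reported. Per-cell proportions are the default unit of analysis, with
per-image aggregation available.

## Problem sizes and numerical choices in the test suite

The round-trip study renders 20 fields of 60 cells on a 400 × 25 µm
two-strip geometry — shallow strips put a third of the cells in the
first row, which both exercises the outer-cell statistics and
stabilises the wound-edge estimate; parameter-recovery runs use
single-row fields (every cell outer) at n = 300. Sector-proportion
reproduction averages 200 seeded replicates at the study sample sizes
(230 and 309 cells). Kuiper calibration uses 2000 null samples of
n = 50. These sizes are the package's choices for a desk-scale,
fully-reproducible suite.

## Known limitations

- The wound estimator assumes one straight band with cells on both
  sides; curved fronts or single-sided wounds need user-supplied
  geometry.
- Nucleus segmentation is classical (Otsu + watershed); heavily
  overlapping or low-contrast nuclei are better segmented externally
  and supplied as coordinate tables, which bypass the detectors.
- The Kuiper p-value is asymptotic-with-correction, not exact; n < 8
  is flagged as approximate.
- Replicate (experiment-level) structure is not modelled; angles are
  pooled per condition.
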