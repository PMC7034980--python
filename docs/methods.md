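# Methods

## The measurement model

`junctmorph` quantifies individual cell–cell junctions in single-channel
fluorescence images of a junctional marker (E-cadherin, VE-cadherin,
β-catenin, …).  The pipeline is semi-automated in the same sense as the
interactive tools used in the field: automatic boundary detection produces
a first skeleton, and every correction a user would make with a mouse is
expressed as a reproducible, declarative edit script instead.

Stages, each exposed as a library function:

1. **Edge map.**  The marker image is Gaussian-blurred, sharpened with an
   unsharp mask, and binarized by comparing each pixel against the mean of
   its local neighbourhood scaled by a threshold factor.  The local mean is
   taken on the *blurred* image: the unsharp ripple is zero-mean and would
   otherwise bias the reference downward next to bright ridges, marking
   flat background.  A ridge-suppression step removes pixels below a
   fraction of the local 5×5 maximum (the blur shoulders flanking a ridge),
   and small speckles are dropped.
2. **Skeleton.**  Morphological thinning to a 1-pixel-wide, 8-connected
   network; isolated pixels are removed and terminal spurs shorter than the
   prune length (default 5 px) are cut.  A post-pass guarantees the
   standard thinning criterion that no 2×2 block is fully set; at X-shaped
   crossings where no pixel is simple, one pixel is removed and any
   orphaned arm re-bridged so connectivity is preserved.
3. **Scripted edits and refinement.**  `add`/`remove` polyline edits
   rasterize with 8-connected line drawing (removals clear a 1-px Chebyshev
   halo), after which the skeleton is re-thinned.  Optional refinement
   snaps each skeleton pixel to the maximum-intensity pixel in its search
   window; a pixel that already attains the window maximum stays put, so a
   ridge-aligned or constant-intensity skeleton is a fixed point, and other
   ties resolve to the smallest (row, col).  If re-thinning the moved set
   would change the number of connected components, refinement backs off to
   the input skeleton.
4. **Topology.**  Cells are the 4-connected components of the skeleton
   complement (the skeleton itself is 8-connected; 4-connectivity stops
   cells leaking through diagonal steps).  A skeleton pixel is a corner
   candidate when ≥ 3 distinct cell labels occur within Chebyshev radius
   *r* (default 2 px); candidates within 2*r* merge into one corner at
   their centroid snapped to the nearest skeleton pixel.  A meeting point
   of four or more cells is a single corner.  Interfaces are the
   corner-free skeleton paths between corner zones, routed corner-to-corner
   by shortest path; each one records its flanking cell pair.  Dangling
   paths, loops, paths shorter than the minimum interface length (default
   5 px) and — by default — junctions touching a border-flagged cell are
   excluded, each with a logged reason.  Junctions are deduplicated by
   (corner pair, cell pair), so a junction shared by two cells is counted
   once.
5. **Measurement.**  Each interface is dilated into a Chebyshev band of
   1–9 px.  Primary parameters: interface contour (geodesic length of the
   path; 1 per orthogonal step, √2 per diagonal step), straight-line
   interface length (Euclidean corner-to-corner distance), interface area
   (band pixel count), fragmented junction contour (summed geodesic length
   of covered runs), junction contour and straight-line junction length
   (between the outermost covered path pixels), junction area (band pixels
   projecting onto the junction extent), marker area and intensity
   (above-threshold pixels inside the band and their summed intensity).
   "Covered" is decided per path pixel: it owns the band pixels nearest to
   it (squared-distance ties to the lower path index), and is covered iff
   that cross-section holds at least one above-threshold pixel.  The gap
   tolerance is zero — any uncovered pixel splits staining fragments.
6. **Secondary parameters.**  Linearity indices (contour / Euclidean
   length, ≥ 1 by construction), coverage index (% of the interface contour
   covered by fragments), interface occupancy (% of the band area occupied
   by marker pixels), intensity per interface area, and cluster density.
   Cluster density defaults to marker intensity / marker area — the mean
   above-threshold intensity, i.e. intensity within the area delimited by
   the staining itself; the junction-area denominator is available as a
   configuration switch because both stained-area conventions appear in
   practice.  Ratios with a zero denominator are reported as missing (NaN),
   not as errors.
7. **Second marker.**  A co-registered second channel is measured inside
   marker 1's band with its own threshold; the interface geometry is by
   construction that of marker 1.

Thresholding is strict (`intensity > t`): threshold 0 on a blank image
selects nothing, and raising the threshold can only shrink the selection.

## Quality control

PSNR between a reference and a degraded image is reported in dB
(`10·log10(max² / MSE)`; identical images report +∞, a pass).  Automatic
skeleton detection is reliable above ≈ 22 dB; the synthetic degradation
suite verifies boundary-pixel recall ≥ 95% down to that gate and reports
(without asserting) the decay below it.

## Statistics

Per-junction parameter distributions are non-normal, so two groups are
compared with the two-sided Mann-Whitney U test and three or more with
one-way ANOVA followed by Games-Howell post-hoc pairwise tests (Welch-type
statistic, studentized-range reference; robust to unequal n and variance —
implemented via `pingouin`).  Shapiro-Wilk and Kolmogorov-Smirnov
normality statistics are reported as diagnostics.  Phenotype fingerprints
normalise each parameter's treated-group **median** to the control median
(control = 100); medians, not means, because the per-junction data are
skewed.  Significance at p < 0.05 is flagged, never hard-coded into
conclusions.

## The synthetic monolayer generator

Scenes are Voronoi tessellations of a jittered hexagonal lattice of cell
centres (jitter 0.15 × spacing).  The hexagonal scaffold is deliberate: it
produces the tricellular-vertex topology of an epithelial sheet with
vertices far enough apart that corner counts are a property of the method
rather than of lucky geometry, while the jitter removes the degenerate
four-way vertices of a square lattice.  Each edge is rendered as a
staining band of configurable width/intensity over a cytoplasmic
background, with optional sinusoidal (or triangular, for endothelial
zigzag phenotypes) normal undulation pinned at the vertices, fragmentation
to a programmed coverage fraction (gaps ≥ 2 px, fragments ≈ 30 px by
default, cut perpendicular to the curve so programmed coverage is honoured
without protruding caps), and additive Gaussian noise applied last.
Boundary edges are rendered only inside the frame; peripheral cells open
onto the image border and are flagged as border cells, as in micrographs
where edge cells run off-frame.  A regular-grid variant (`generate_grid`)
provides the axis-aligned straight-junction fixture whose true linearity is
exactly 1.

**Ground truth describes the rendered scene.**  The true boundary of an
interface is the digitized pixel polyline actually painted (compressed to
the minimal 8-connected chain), and the recorded `contour_px` is that
polyline's arc length.  The continuous length of the ideal geometric
scaffold is stored alongside (`scaffold_length`); the two differ by
ordinary raster chord quantization — a pixel-step geodesic overestimates a
continuous segment at angle θ by up to ≈ 8% (mean ≈ 5% over uniform
angles), a property of raster morphometry itself, shared by any
pixel-step contour measure and cancelling in ratio parameters such as the
coverage index.  Recovery tests therefore compare measurements against the
rendered boundary, which is what any raster pipeline can recover.

What the generator does *not* emulate: microscope point-spread functions,
uneven illumination, intensity gradients within clusters, cytoplasmic
texture, and 3D/stratified topology.  Passing tests demonstrate the
correctness of the measurement machinery on known geometry, not robustness
to every imaging artifact; on real images the interactive edit script
remains the instrument for fixing detection failures.

Phenotype presets encode programmed effect directions used by the
fingerprint tests: `control_epithelial` (coverage 0.9, intensity 180,
mild undulation), `rac1_like` (coverage ↓ 0.55, intensity ↑ 240,
undulation unchanged — receptor redistribution into denser clusters) and
`ras_like` (coverage ↓ 0.55, intensity ↓ 140, undulation ↑ — fragmentation
with undulated contacts).

## Numerical choices and test scales

* Coordinates are 0-based (row, col), row increasing downward, everywhere.
* PSNR of identical images → +∞ sentinel (QC pass, not an error).
* Noise clips to the bit range (saturation), never wraps.
* Corner detection radius 2 px, merge distance 2× radius; corner zones of
  the same radius delimit interfaces.
* Spur prune length 5 px; minimum interface length 5 px; both configurable.
* Nearest-path-pixel assignment uses integer squared Euclidean distances,
  ties to the lower path index — deterministic across platforms.
* Isolated open paths (e.g. drawn between two manual corners inside one
  cell) are flanked by the same cell on both sides and recorded with a
  repeated cell pair rather than discarded.
* Dilation is restricted to 1–9 px, matching the tool's intended operating
  range.
* Test and acceptance scenes are 256–384 px with 12–50 cells, ≈ 20–70
  junctions per scene; coverage recovery uses 20 seeds per programmed
  level, fingerprints ≥ 50 junctions per group.  These sizes give stable
  statistics while keeping the full suite fast.

## Known limitations

* Contours are pixel-step geodesics; no sub-pixel fitting.  Absolute
  lengths carry the chord-quantization bias discussed above (ratios do
  not).
* Bands of adjacent interfaces may overlap near corners; each junction is
  measured independently, so marker signal in the overlap contributes to
  both junctions.  Fragmented-contour invariance under dilation holds for
  junctions whose staining lies inside the smallest band, and can be
  broken by a neighbouring junction's stain entering a large band near a
  corner — visible in dense monolayers at dilation ≥ 4.
* Closed boundary loops without corners are flagged, not measured.
* No tracking across time-lapse frames; no colocalization statistics
  between the two markers.
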