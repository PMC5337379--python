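# Methods

## Problem and scope

Ground biomass powders (e.g. knife-milled wheat straw) have needle-like,
strongly anisotropic particles whose length is poorly captured by sieving:
a sieve passes anything narrower than its mesh regardless of length, so
sieving classifies by *width*.  Image analysis recovers both dimensions.
grainmorph implements the full measurement chain for two acquisition
modes — flatbed scans of coarse fractions (bright particles on a dark
background, scale fixed by the scan resolution, `25400/dpi` μm per pixel)
and SEM backscattered-electron (BSE) micrographs of fine fractions (dark
organic particles on a brighter mica substrate, scale supplied by the
instrument calibration).  BSE mode is assumed because its grey level
tracks mean atomic number, giving flat particle contrast; the
secondary-electron edge effect is therefore *not* modelled anywhere.

## Pipeline

1. **Polarity normalization.** All processing assumes particles brighter
   than background; dark-particle (BSE) images are inverted on ingest
   (`v -> 255 - v`), an involution that preserves the histogram up to
   reversal.
2. **Denoising.** A Gaussian filter with default `sigma = 1.0` px,
   reflective boundaries.  This is the smallest sigma that suppresses
   single-pixel detector noise without bridging the ≥ 5 px gaps of a
   properly singulated sample.  `sigma = 0` disables it.
3. **Binarization.** A single global Otsu threshold over a fixed 256-bin
   histogram (real-valued images are linearly quantized to 256 bins
   first).  The threshold maximizes the between-class variance
   `w0*w1*(mu0-mu1)^2`; ties break toward the smallest threshold, and
   foreground is the class strictly above it.  Local/adaptive
   thresholding is deliberately out of scope: with BSE contrast a global
   threshold suffices and is easier to reason about.
4. **Hole filling.** Binarization can punch holes into large particles.
   A hole is a 4-connected background component not touching the image
   border (foreground uses 8-connectivity; the complementary pair avoids
   topological paradoxes).  A hole is filled iff its *depth* — the
   Euclidean distance from its closest pixel to the nearest
   outer-boundary pixel of the enclosing particle — is at least
   `tau_hole` (default 3 px).  Deep holes are artifacts; shallow,
   near-edge holes may be genuine silhouette concavities and are kept.
   `tau_hole = 0` reduces to classical hole filling.  Depth is measured
   from the hole's nearest pixel rather than its centroid so that an
   annular particle (outer radius 20, inner 5) has depth 15: the distance
   separating the hole from the outline, independent of hole size.
5. **Area filter.** Components below `min_area = 4` px are discarded as
   ultrafine debris below the reliable measurement limit; survivors are
   relabelled 1..n in raster order of first occurrence.
6. **Separation of touching particles** (below), followed by a second
   area filter.
7. **Morphometry and aggregation** (below).

Hole filling precedes separation so spurious interior holes cannot
masquerade as boundary concavities.  Morphological
erosion/dilation/opening/closing are never used: they change particle
dimensions, which defeats the purpose of dimensional measurement.

## Separation of touching particles

Agglomerated grains label as one component.  Where two convex grains
meet, the union silhouette has a pair of re-entrant "wedge" corners at
the ends of the contact neck.  Per component:

- **Contour.** Moore-neighbour tracing (8-connected, Jacob-style
  termination implemented as first repetition of the (pixel, backtrack)
  walk state, which also terminates correctly on one-pixel-thin spurs),
  oriented counter-clockwise, starting at the topmost-then-leftmost
  pixel.
- **Curvature.** At contour point *i*, the *k-cosine*: the cosine of the
  angle between the chords to the points *k* steps behind and ahead
  (default `wedge_k = 5`).  +1 means a needle-sharp corner, −1 a straight
  run.  The point is concave when the traversal turns clockwise there
  (cross-product sign on the counter-clockwise contour).
- **Candidates.** Concave points with k-cosine ≥ `cos_min`, thinned by
  non-maximum suppression within ±k contour steps.  Default
  `cos_min = -0.85`: measured on the k = 5 chords, genuine contact wedges
  between convex grains — including bluntly interpenetrated ones — read
  above about −0.8, while the shallow staircase concavities every
  rasterized convex outline exhibits read below −0.97.  The default sits
  between the two populations.  (A much stricter floor such as +0.3
  would only accept wedges sharper than ~73° and misses the blunt necks
  of partially merged grains entirely.)
- **Pairing.** A candidate pair is admissible when the two points are
  more than 2k contour steps apart, the Bresenham chord between them
  stays inside the particle, and the chord is at most `max_split_frac =
  0.6` of the particle's equivalent-circle diameter (a neck, not a cut
  across the body).  Admissible pairs are selected greedily by ascending
  chord length — true necks are the narrowest interior chords — each
  candidate used once.  Greedy selection is a deliberate simplification
  of optimal matching and is replaceable.
- **Cutting.** Each selected chord is erased (set to background) one
  pixel wide.  If the two halves remain 8-connected across a diagonal
  step of the chord, the chord is locally thickened into a 4-connected
  background line, which 8-connected foreground cannot cross.  A cut
  that would erase a whole component is undone.  The only foreground
  pixels ever lost are the recorded chord pixels.
- **Iteration.** Split-and-relabel repeats on the new components until
  no admissible pair remains or `max_iter = 10` (fixpoint iteration;
  multi-grain clusters resolve one neck at a time).

The particle count never decreases.  Watershed and morphological
splitting are intentionally absent; only *touching* (lightly
interpenetrating) grains are in scope, not occluding ones.

## Morphometry

Width *w* is the minimum Feret breadth: the smallest distance between two
parallel tangent lines to the outline.  Length *l* is the tangent extent
measured *perpendicular to the width tangents* — not the maximum Feret
diameter; the two differ on some shapes.  AR = l/w ≥ 1, equal to 1 for
circles and squares.

Tangents touch only the convex hull, so both quantities are computed on
the hull (Andrew's monotone chain, collinear vertices dropped) of the
traced boundary pixels.  The minimum breadth of a convex polygon is
attained with one tangent flush against a hull edge, so scanning hull
edge normals (rotating calipers) is exact; tests verify it against a
0.05°-grid projection oracle.

**Footprint correction.** Pixel coordinates address pixel centres, so raw
projected extents underestimate the physical silhouette by one pixel;
+1 px is added to both l and w before scaling to μm.  This also gives a
single-pixel particle w = l = 1 px and a defined AR.  Degenerate
collinear "shapes" get w = 1 px.  If floating-point noise ever orders
l < w on a degenerate shape the values are swapped with a warning.

## Aggregation

Size classes are summarized by arithmetic means and sample standard
deviations (n−1; a single particle reports SD 0 with a warning) of
length, width and AR.  The mean AR is the mean of per-particle ratios,
*not* mean length over mean width — the distinction matters and is
tested.  Distribution curves are the raw empirical display: a dimension
sorted ascending against rank 1..n, with a semilog recommendation for
sizes.  No parametric fitting (lognormal, Rosin–Rammler) is performed.
Sieve-class mass fractions normalize recorded masses to percentages
summing to 100.  An optional seeded subsample-to-n supports
fixed-sample-size reporting; the default uses all particles.

## Synthetic scenes and what they do (not) show

No reference micrographs ship with the package, so correctness is
established on rendered scenes with exact ground truth:

- **Shapes**: rectangles, capsules, ellipses, discs — convex and
  elongated (AR 1–4), mimicking knife-milled fragments.
- **Contrast**: uniform grey 60 vs 200 (swapped per polarity), which is
  what BSE imaging of a homogeneous organic material on mica provides;
  additive Gaussian noise (seeded) stands in for detector noise.
- **Rasterization**: a pixel belongs to a shape if its centre is covered.
  Flat-sided rectangles use the closed interval of half-extent (l−1)/2,
  which is *exact* under the +1 px footprint model; curved shapes
  rasterize their full continuous silhouette, which is phase-averaged
  unbiased under the same model (about ±0.7 px residual scatter at the
  tips).
- **Placement**: dimensions are drawn once per shape (so length/AR
  distributions are exactly the requested uniforms) and only the
  placement is rejection-sampled, enforcing a ≥ 5 px surface gap — the
  singulated arrangement of a well-prepared sample.  The gap test uses a
  circumscribing capsule per shape (radius w/2, or w/√2 for rectangles
  whose corners protrude).
- **Touching fixtures** are constructed deliberately: disc dumbbells with
  centre distance (r1+r2)(1−f) and analytic neck width recorded, and
  coaxial tip-to-tip ellipse pairs interpenetrating by a stated fraction
  of the smaller minor axis.

Default study conditions: 300 particles, lengths uniform in [20, 200] px,
AR uniform in [1, 4], noise SD 10 grey levels on a 140-level contrast
gap; the separation benchmark uses 50 ellipse-pair scenes with minor axes
U[12, 20] px, AR U[1.5, 3], overlap U[0.1, 0.3] of the smaller minor
axis.  These sizes keep a full run in seconds while giving stable rates.

What passing these tests does **not** show: real micrographs have uneven
illumination, partial occlusion, out-of-focus edges, non-convex particle
outlines and heavier agglomeration than pairwise contact.  The synthetic
suite validates the geometry and bookkeeping of the method, not its
robustness to those effects.

## Known limitations

- Chord splitting truncates interpenetrating grains: a straight cut
  through the neck assigns the shared lens to the two sides, so each
  recovered particle loses up to about half the overlap depth plus the
  one-pixel chord.  At the deep end of the benchmark range (~30% of the
  minor axis) individual length errors can slightly exceed 3 px; the
  error is structural, not statistical.  Truly *touching* grains
  (overlap → 0) do not suffer from it.
- The k-cosine wedge detector needs the neck corners to be sharper than
  `cos_min`; very blunt contacts between large flat-sided grains can
  evade it.  All four separation knobs are exposed in the config.
- Measurements assume particles lie flat; no stereological or 3-D
  correction is applied, and no perimeter/circularity descriptors are
  computed.
- The two SEM scale factors commonly quoted for 200x and 300x (1.46 and
  0.971 μm/px) are mutually inconsistent under exact inverse
  proportionality; scale factors are therefore always taken as
  user-supplied constants, never derived from magnification.
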