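# Methods

## Scope and conventions

The package scores a candidate binary contour map Dc against a ground-truth
map Gt of the same pixel grid.  Coordinates are 0-based `(row, col)` with the
row axis pointing down; all distances are Euclidean, in pixel units, computed
with an exact Euclidean distance transform (`scipy.ndimage.
distance_transform_edt`) — chamfer or quasi-Euclidean approximations are
deliberately not used.  Pixels are strictly binary after loading; soft
(probabilistic) boundary maps, edge *detection*, Hausdorff-family measures,
Earth Mover's and Chamfer matching scores are out of scope.

A scored pair must have matching dimensions and a nonempty ground truth
(every measure divides by |Gt|).  An empty candidate is legal and each measure
defines its own degenerate value for it, via the limit of infinite
false-negative distances: FoM, F, Dice, EMM and M all go to 0, Dp to 1/2 (its
false-negative term saturates at its supremum while its false-positive term
vanishes), and RDE diverges — the direct call raises, while a trajectory
records +inf for that step.

## The measures

Confusion sets follow pixelwise intersection: TP = Gt∩Dc, FP = ¬Gt∩Dc,
FN = Gt∩¬Dc, TN elsewhere.  d_Gt(p) and d_Dc(p) denote the minimum Euclidean
distance from p to the respective map.

* **Dice** = 2TP/(2TP+FN+FP).  Counts only; no notion of displacement.
* **FoM** = 1/max(|Gt|,|Dc|) · Σ_{p∈Dc} 1/(1+κ·d_Gt(p)²).  Since TP pixels
  contribute 1 each, FP = 0 collapses it to TP/|Gt| exactly — an identity the
  tests assert bit-for-bit.
* **F** = 1/(|Gt|+β·FP) · Σ_{p∈Gt} 1/(1+κ·d_Dc(p)²).  The mirror image:
  FN distances recorded, FP only counted (β defaults to 1, exposed as a flag).
* **d4** = 1 − ½·√( [(TP−max)²+FN²+FP²]/max² + (1−FoM)² ).  The printed form
  of this formula is typographically ambiguous; the adopted parenthesization
  is the one under which each ratio term is ≤ 1, the bracket ≤ 4 and the score
  stays in [0,1], consistent with the measure being three-quarters statistics
  and one-quarter FoM.
* **Dp** = 1 − 1/(2(|I|−|Gt|))·Σ_{FP}(1−1/(1+κ·d_Gt²))
         − 1/(2|Gt|)·Σ_{FN}(1−1/(1+κ·d_TP²)), where d_TP is the distance from
  a missed pixel to the nearest *correctly detected* pixel.  With no TP at
  all, each FN summand is set to its supremum 1 (d_TP = ∞): maximal penalty,
  score still in [0,1].
* **EMM** = TP / ( TP + ω·(Σ_{FN} δ_Dc + ε·Σ_{FP} δ_Gt) ), δ(d) = d below the
  threshold Mdist and the cap Dmax above it.  ω is applied to the whole
  penalty: it is the global |I|-based normalizer, while ε is the relative FP
  weight — the alternative grouping (ω on the FN sum only) would make ε
  dimensionally inconsistent.  Defaults follow the published schedule
  Mdist = |I|/40, Dmax = |I|/10, ω = 10/|I|, ε = 2, with |I| the *pixel
  count*; for megapixel images the resulting Mdist exceeds any realizable
  pixel distance, so the cap never fires.  The schedule is implemented as
  published and the caveat documented rather than silently "fixed".
* **RDE** = (1/|Dc| · Σ_{Dc} d_Gt^k)^{1/k} + (1/|Gt| · Σ_{Gt} d_Dc^k)^{1/k},
  k = 2 by default.  The source formulation prints the two power means
  without roots; the rooted form is the measure's established shape and keeps
  its unit in pixels, so roots are the default with `rde_root=False`
  reproducing the literal printed equation.
* **M**: see README for the formula.  Both sums run over the *entire* Dc and
  Gt (TP pixels contribute 1 to each), the per-side sums are weighted by the
  share of mistakes FP/|Dc| and FN/|Gt|, and 1/(FP+FN) normalizes the result
  into (0,1], with M = 1 exactly when FP = FN = 0.

## Automatic parameters

κ defaults to 1/9 for the FoM family.  M's scales default to the automatic
delta mode (μFP, μFN) = (1/Δ², 1/Δ): Δ is defined as the maximum of d_Gt over
**all image pixels**, not over the candidate's pixels.  The two definitions
coexist in the source material; the image-wide one is adopted because it
depends only on the ground truth, keeping the normalization constant across
every frame of a sequence (the candidate-restricted variant remains available
through `delta_max(gt, over=dc)`).  The diagonal mode (1/D², 1/D) and fully
fixed values are selectable; D = √(H²+W²) (rather than √((H−1)²+(W−1)²)) so
that Δ < D holds strictly for any nonempty ground truth.  Whenever Δ > 1 the
automatic ordering μFP < μFN holds, which is what makes missed edges cost
more than spurious ones.

## The synthetic benchmark

The generator emulates a moving-object video scored against a fixed
reference: a closed 1-pixel contour (square, ellipse, or star polygon) is
translated along +col, rotated about its outline centroid, or scaled about it,
in `steps` linear increments from identity (step 0) to full magnitude (last
step).  Transforms act on the *continuous* outline, which is re-rasterized at
every step with Bresenham segments — rotating the raster itself would punch
holes into a thin contour and fabricate false negatives.  Pixels leaving the
canvas are clipped; the canvas never changes size.  Detector imperfections
are emulated by speckle (uniformly placed false-positive pixels) and dropout
(uniform removal of a fraction of contour pixels); both take explicit seeds
(default 0) and trajectories derive one sub-seed per step.

The default benchmark shape is a concave five-armed star centered on a
100×100 canvas (outer radius 30 % of the canvas side, inner radius 45 % of the
outer) — concave, so rotation genuinely changes the occupied pixels.  The
benchmark experiments rerun the translation/rotation/scale protocols on this
shape with 25–37 steps: translation magnitude 1.5× the canvas width (the
shape fully exits), rotation through 360°, scaling up to 8×.  These sizes keep
a full trajectory under a second while sampling the curves densely enough to
detect non-monotonicity.

What the generator does *not* emulate: real edge-detector artifacts
(correlated fragmentation, double edges, texture-induced clutter), occlusion,
perspective distortion, or SNR-calibrated sensor noise.  Passing the benchmark
therefore shows that a measure behaves correctly under clean geometric
alteration with idealized noise — not that it is robust to every real video.

## Numerical choices and edge cases

* Distance fields are exact; measure implementations are vectorized over the
  fields, and every measure is cross-checked to 1e-9 against a brute-force
  min-over-points oracle with no shared code.
* Binarization threshold on reading defaults to half the dtype's dynamic
  range; files with more than two gray levels and no explicit threshold are
  rejected as ambiguous.  An `--invert` flag handles dark-on-light encodings.
* Downscaling of binary maps uses block-maximum, never subsampling: an output
  pixel is marked iff its source block contains a marked pixel, which
  preserves 1-px contours.  Multiscale runs recompute Δ and the μ parameters
  from the *reduced* ground truth at each factor — each scale is an
  independent evaluation.
* A 3×3 dilation is sometimes applied to contour overlays for display; it is
  visualization-only and excluded from every scoring path here.
* The speckle-perturbation bound (adding k false positives moves M by at most
  k/(FP+FN)) holds only when the added pixels leave every miss's
  nearest-detection distance unchanged — noise landing *near* the ground
  truth shortens FN distances and can move M upward by more than that.  The
  property test constructs noise in the far regime, where the bound follows
  from the FP-side structure of the formula and holds with wide margin.
* Rotation of an axis-aligned square by a full turn reproduces the raster
  exactly; intermediate angles are only rasterization-equal up to Bresenham
  rounding, which is why the benchmark tolerances admit sub-0.01 blips.

## Known limitations

* EMM's published |I|-based schedule makes its distance cap inoperative on
  large images (see above); results with default parameters on megapixel
  frames should be interpreted accordingly.
* Scores are pixel-count-based: extremely sparse ground truths (a few pixels)
  make Δ, and hence M's automatic parameters, sensitive to where those pixels
  sit in the frame.
* The CLI consumes pre-extracted binary frames; it does not decode video or
  run an edge detector.
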