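# Methods

This note documents the model assumptions, parameter choices and
numerical decisions behind the `pombex` pipeline, and what the synthetic
fixtures do and do not establish about behaviour on real microscope
data.

## Imaging model and assumptions

Near focus, a bright-field image of a rod-shaped yeast cell shows a dark
membrane ring and a bright cytoplasm on a flat background. Defocus
moves both regions' mean intensities in opposite directions,
approximately symmetrically about the background mean μ_B: positively
defocused cells have interior > μ_B > membrane, negatively defocused
cells the reverse. Two assumptions make this correctable:

* the specimen plane is flat, so defocus z varies bilinearly across the
  frame, z(x, y) = a + bx + cy, and changes sign along a straight line;
* for moderate defocus, a nucleus' bright-field intensity difference to
  background is linearly related to z, so nucleus centroids (from the
  fluorescence channel) provide (x, y, z) samples for the plane fit.

Complementing intensities about μ_B (j = 2μ_B − i) wherever the fitted
z < 0 then restores a single contrast polarity. Because μ_B is a fixed
point of the map, intensity stays C⁰-continuous across the z = 0 line;
cells that straddle the line are still locally distorted — a known
limitation with no fix here. The nucleus z-values are in practice
nearly sign-valued (±contrast), so the least-squares plane recovers the
*sign structure* of the tilt reliably but not its magnitude; the
pipeline only consumes the sign.

**Gradient-detection rule.** An image "has a focus gradient" when the
fitted plane (i) takes both signs within the frame — otherwise there is
nothing to complement — and (ii) explains at least R² = 0.3 of the
nucleus-z variance, which guards against noise-driven sign flips when
the field is uniformly focused. `focus_correction_mode` = `on`/`off`
overrides the automatic decision.

**Target contrast.** The global affine adjustment anchored at μ_B sets
μ_N − μ_B to a dataset-wide constant; the default is 15% of the working
image's dynamic range, exposed as `target_contrast`. Because the map is
affine about μ_B, downstream intensity features normalised by μ_N − μ_B
are invariant to this choice.

## Pixel classification

With polarity normalised, the four-class rule is threshold-based:
background is the low-texture mask (Otsu on the Sobel gradient-
magnitude image), membrane is everything below the Otsu threshold of
the sub-histogram of pixels darker than μ_B (the only concrete reading
of an "adaptive" membrane threshold consistent with Otsu), interior is
everything strictly brighter than μ_N, and the rest is ambiguous.
Precedence on overlap: background, then membrane, then interior.

Two practical refinements to the background mask: the candidate
low-gradient mask is opened with a 1-px disk (the trough line of a
membrane ring is locally flat and can otherwise bridge into the
background component), and only components that touch the image border
or cover ≥ 1% of the frame are kept, so enclosed flat cell interiors
are never absorbed into background. Otsu's threshold itself is
computed exactly on the empirical sample (midpoints between consecutive
distinct values, maximum between-class variance, lowest midpoint on a
tie) rather than on a binned histogram, so it is reproducible and
agrees with exhaustive maximisation by construction.

Ambiguous pixels are resolved iteratively: recompute Euclidean distance
transforms D_b, D_c, D_m of the background, interior and membrane sets;
move an ambiguous pixel to background if D_b ≤ D_c and D_b < D_m (ties
to background), to interior if D_c < D_b and D_c < D_m; repeat until
nothing changes; the survivors (nearer membrane than either region)
become membrane. Only ambiguous pixels are ever relabelled, so the
procedure terminates in at most |X₀| iterations.

## GVF snakes

The membrane edge map f is the membrane indicator smoothed with a σ = 1
Gaussian and rescaled to [0, 1]. The GVF field minimises

    E(u, v) = Σ μ (|∇u|² + |∇v|²) + |∇f|² ((u − f_x)² + (v − f_y)²)

with forward-difference gradients and replicate boundary; the solver is
the explicit diffusion–reaction iteration with dt = 0.9/(4μ) (inside
the stability bound 1/(4μ)) initialised at ∇f. Tests verify the
iterate matches a sparse direct solve of the stationarity system to
1e-6 RMS and that the energy is monotone non-increasing.

Two calibration choices matter and are deliberate:

* **Force normalisation.** With an edge map in [0, 1] and μ = 0.8 the
  raw GVF magnitudes are O(0.1); the published tension/rigidity weights
  (α = 0.03, β = 0.2) are calibrated against an O(1) external force, as
  in the reference GVF snake implementations, so the field is rescaled
  to unit maximum magnitude before use. Without this every snake loses
  to its own internal forces and collapses.
* **GVF iteration count.** Default 20 iterations give the force field a
  diffusion reach of ≈ 3 px, matching the distance between the interior
  components that seed the snakes and the membrane ridge. Longer
  diffusion (it is configurable) only flattens the near-ridge force
  profile, which measurably biases the equilibrium contour inward.

The snake itself evolves semi-implicitly: the pentadiagonal system from
the periodic second/fourth-difference stencils (weighted λ₁) is solved
exactly per step, the external force λ₂·(u, v) is sampled at vertices
by bilinear interpolation, vertices are resampled to ≈ 2 px spacing
every 10 iterations and clamped to the frame, and evolution stops after
200 iterations or when the largest vertex displacement drops below
0.05 px. A contour whose perimeter collapses below the 8-vertex
minimum is flagged degenerate (and later classified as an artifact)
rather than raising. When several contours claim a pixel at
rasterisation, the smaller contour wins, preserving small cells next to
large merged contours pending validation.

## Contour validation

Each contour yields a fixed-order 10-feature vector: area, perimeter,
eccentricity, solidity, major/minor axis lengths, mean intensity of a
2-px band inside the contour, interior mean minus μ_B (both intensity
features divided by μ_N − μ_B so models transfer across contrast
settings), fraction of vertices within 1 px of the frame edge, and a
nucleus-overlap flag. The error types are geometrically separable:
merged contours have large area, long axis and a low-solidity waist;
partial contours are truncated with a bright cut edge; artifacts have
near-zero interior contrast and no nucleus.

Three binary classifiers are trained on labelled examples —
valid-vs-partial and valid-vs-merged SVMs (RBF kernel, C = 1,
γ = "scale", standardised features) and a valid-vs-artifact decision
tree — and composed with fixed precedence: artifact, then merged, then
partial, else valid. Contours touching the image boundary share a
truncated cell's signature and are routed to the partial verdict
directly (threshold: border-contact fraction > 0.05). Degenerate
contours are artifacts outright. Stratified 5-fold CV accuracy is
recorded per task; training is seeded and exactly reproducible.

Training data come from the synthetic generator: ground-truth outlines
(valid), septating-pair unions and bridged nearest-neighbour unions
(merged), cells cut across the long axis (partial), and background
blobs (artifact) — ≈ 400 samples from 18 small scenes. Labels are
correct by construction; hand-labelled data can be supplied instead as
a CSV (`pombex train-validator --labels`).

## The synthetic scenes

`SceneSpec` defaults emulate a 60× screen image at 0.2 μm/px: rods
7–14 μm long and 17 px (3.4 μm) wide with a 3-px membrane ring, placed
without overlap (≥ 4 px gaps); noiseless levels μ_B = 120, membrane
μ_B − 30, cytoplasm μ_B + 30, nucleus-in-trans μ_B + 20 (so the
measured nucleus contrast is +20 and cytoplasm sits 10 units above
μ_N); additive Gaussian noise σ = 3; fluorescence as Gaussian nucleus
blobs over a dim baseline. Cells are rasterised at 4× supersampling,
giving anti-aliased sub-pixel edges that make the ≤ 1 px contour
accuracy tests meaningful. Interior speckle (correlated, amplitude 2σ)
stands in for cytoplasmic texture so that gradient-based background
detection behaves as it does on real cells; at σ = 0 scenes are exactly
piecewise-constant. Presets: `wildtype` (25 short rods), `cdc`
(elongated), `mixed` (varied sizes, 80% fluorescent), `septating` (half
the rods carry a central septum splitting them into two instances), and
`gradient` (wildtype with the plane −256 + x embedded, i.e. polarity
inverted on the left half).

What the fixtures do *not* model: Poisson/camera noise, the
point-spread function and true defocus blur (contrast inversion is
applied as an exact intensity flip), organelle structure, touching
cells without a membrane gap, and debris. Passing tests therefore
demonstrate the algorithmic contracts — polarity correction, class
growing, snake convergence, validation filtering — not performance on
any particular microscope's data; the validator especially should be
retrained on hand-labelled contours for production use.

## Evaluation conventions

A predicted contour *correctly segments* a cell when its Dice overlap
with that cell is ≥ 0.7 under greedy one-to-one matching and it does
not also cover ≥ 50% of a second cell. The bar sits between the score
of a faithful contour tracking the membrane midline (≈ 0.86 against the
full-body truth mask, whose boundary is the membrane's outer edge) and
the ≈ 2/3 scored by a merged pair or a half cell. Detection recall and
contour precision count correct contours against truth cells and
against emitted contours respectively; `mean_dice` averages over
correctly segmented cells, while `mean_dice_all` spreads the same sum
over all truth cells (undetected cells contribute 0) and is the fair
quantity when comparing runs with different recall, e.g. with versus
without fluorescence.

The validation benchmark injects deliberately wrong contours (merged
neighbours, truncated cells, background blobs) alongside the pipeline's
own output, because on well-separated synthetic scenes the snakes alone
rarely err; precision before versus after filtering measures exactly
the validator's contribution.

Problem sizes used by the test suite and the acceptance script —
512×512 scenes with 14–25 cells, ≈ 400 training contours, 32×32 GVF
oracle grids — were chosen so every oracle comparison and end-to-end
run completes in seconds while leaving the measured quantities stable
across seeds (recall and Dice vary by < 0.01 between seeds at these
sizes).

## Known limitations

* Cells crossing the estimated z = 0 line are complemented on one side
  only and can be lost or distorted; warping the boundary around cells
  is out of scope.
* The bilinear plane cannot represent curved specimen planes.
* Touching interior components are not split (no watershed); merged
  cells are removed by validation rather than rescued.
* The complement j = 2μ_B − i is an exact involution only up to one ulp
  on arbitrary float64 intensities (double rounding); tests assert
  bit-identity only on exactly representable values.
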