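# Methods

## Model and assumptions

`stackalign` assumes the only instrument-induced frame motion is a
global lateral translation: the stage moves in x and y, optics do not
rotate, shear or scale the image, and focus is held constant. Under that
assumption every pixel shares one displacement per frame pair, while
moving cells contribute sparse, incoherent outlier motion. The
translation estimate must therefore be robust, not least-squares: the
component-wise median of a dense flow field tolerates up to half the
pixels moving arbitrarily, so the stage motion survives any sub-majority
amount of cell motility. Holomorphic (off-axis) solvers are deliberately
excluded — when the true off-axis terms are zero a higher-degree-of-
freedom fit still produces nonzero off-axis estimates and destabilises
the result.

Corrections are composed before application: each frame receives one
bilinear sub-pixel translation by its negated cumulative displacement,
never a chain of per-step warps, so interpolation smoothing is incurred
exactly once per frame.

## Coordinate and sign conventions

x is the column index (rightward), y the row index (downward); all pairs
are ordered (dx, dy). `(dx, dy)` is the apparent motion of the second
(moving) frame relative to the first; applying the translation
(−dx, −dy) to the moving frame aligns it. These conventions are enforced
by shared sign tests across all backends.

## Displacement backends and their parameters

**Phase cross-correlation (PCC)** estimates the translation from the
cross-power spectrum with local DFT upsampling; resolution is
`1/upsample_factor` pixels. Default `upsample_factor = 81`: on the
synthetic benchmark the error dispersion fluctuates strongly at low
factors and is essentially stable from ~81 upward, so the default sits
at the start of the stable plateau.

*Spectrum weighting.* The classical normalised ("phase-only")
cross-power spectrum gives every frequency equal weight. Microscopy
frames are band-limited, and bilinear resampling additionally distorts
the phase of the highest frequencies, so phase whitening amplifies
exactly the bands that carry no trustworthy signal; on sub-pixel
benchmarks this costs up to ~0.1 px. The default is therefore the
magnitude-weighted cross-correlation (`normalization=None` in
`pcc_shift`), which weights bands by their actual energy; the whitened
variant remains available via the `normalization` parameter.

**Dense Lucas–Kanade** solves, at every pixel, the brightness-constancy
least squares over a uniform window (iterative refinement, via
scikit-image's `optical_flow_ilk`). Default window `radius = 23` px: the
benchmark error dispersion is minimal there and flat for larger radii.
Pixels with a rank-deficient structure tensor (no gradient information)
are assigned zero flow — neutral under the median as long as flat
regions are sparse. A single pyramid level is used; only the radius is
treated as the method's free parameter.

**Deep flow (optional plugin)** runs a pretrained recurrent all-pairs
field transform network for a configurable number of refinement
iterations (default 12; the displacement error depends only weakly on
this). It requires torch/torchvision plus downloadable weights, so it is
gated behind a capability check: without the plugin the backend raises a
`CapabilityError` directing the caller to PCC or Lucas–Kanade, and no
test or benchmark depends on it.

**Reducer.** The flow field is collapsed by the marginal median per
component. The histogram mode (bin width default 0.1 px, bins centred on
the data minimum) is provided for comparison; median and mode agree for
symmetric unimodal displacement histograms, but the median characterises
flat-topped histograms better and is the default.

**Precision.** `precision='float16'` casts input frames to half
precision before estimation while all accumulation stays in float32; the
induced displacement difference is below ~0.1 px, which matches the
tolerance used in its test.

## Framing

Frame t's corrected footprint is the box `[c(t), c(t) + (W, H))` with
`c(t)` its correction. Canvas modes: union of boxes (maximum),
intersection (minimum; an empty intersection raises with the overlap
deficit), an H×W box centred on the *mean* corrected position (the
anchor is a design choice; median would differ only for skewed
trajectories), or the designated reference frame's box. Fractional
bounds are expanded outward (floor/ceil) so no valid pixel is clipped;
consequently the minimum-mode canvas contains no fill pixels at all.
Fill intensity is each frame's own median brightness (per frame, not per
stack, since each incomplete frame is filled independently), or a
constant. The trajectory is always anchored at frame 0 and re-offset at
reframing time for reference mode.

## Jitter synthesis

Per-step displacement δ(t) = A(t)·cos(ω₁t)·cos(ω₂t) per axis, with A(t)
redrawn uniformly in [0, amplitude_max] per axis and step. Defaults
ω₁ = 0.5, ω₂ = 1.2 rad/frame, amplitude_max = 120 px reproduce the
beat-modulated quasi-periodic stage jitter of an uncompensated plate
scanner (primary amplitude ~100 px). Two readings of the model's algebra
are possible; the additive one — δ is a per-step translation independent
of the current position — is adopted, since the recursion is a pure
translation and observed jitter is bounded. The jittered stack is
rendered once per frame by the cumulative displacement onto a canvas
enlarged by an explicit margin (error if the trajectory exceeds it), so
ground truth is never destroyed at the borders.

## Synthetic scenes

The generator emulates the two properties registration actually relies
on in bright-field culture imaging: a static gradient-rich background
and sparse independently motile, shape-changing objects. The background
is band-limited periodic noise (correlation length `background_grain`,
default 2 px — small enough that the Lucas–Kanade structure tensor is
full-rank almost everywhere). Blobs are soft radial profiles with a
faint dark rim (default 10 cells of radius 4–8 px on a 256² frame ≈ 7%
footprint), following seeded random walks (speed 0.5–2 px/frame) with
optional shared drift for adversarial group motion, and a per-frame
radius perturbation (`morph_rate`, default 5%) standing in for
morphological change. Positions wrap periodically, matching the periodic
background, so scene evolution is stationary and cyclic ground-truth
shifts are exact. The generator reports the exact rendered footprint
fraction (pixels within two radii of a centre) and refuses to build
scenes beyond 50% footprint, where the median's breakdown point would be
violated by construction.

What the generator does **not** emulate: illumination drift and
photobleaching, focus (z) changes, realistic cell morphology or
division, imaging noise beyond additive Gaussian (default σ = 0.01).
Passing benchmarks on these scenes therefore demonstrates correctness of
the translation-estimation machinery under sparse incoherent motion, not
performance on arbitrary real recordings.

## Benchmark problem sizes

The shipped benchmarks use desk-scale stacks chosen to exercise every
mechanism: 64–128 px frames for single-pair recovery, a 50-frame 256²
scene with amplitude-20 jitter for the end-to-end round trip, a 10-frame
all-pairs matrix for anti-symmetry, and a 24-frame 128² slowly evolving
scene (blob speed ≲0.1 px/frame, 2% morph rate, ~160 sampled pairs) for
the coherence-versus-distance analysis. On the slow-evolution benchmark
the mean absolute pairwise error grows near-monotonically with frame
distance (Spearman ρ ≈ 1); notably, *fast* coherent blob motion shows
the opposite pattern, because widely displaced objects become clean
outliers that the median rejects, while sub-pixel object displacement
biases the estimate from within the peak.

## Numerical details

- Intensities are normalised by the source dtype's theoretical maximum
  (255, 65535), never the observed maximum, preserving inter-frame
  brightness drift that flow estimation is sensitive to. RGB collapses
  via Rec.601 luma weights.
- Warping uses `scipy.ndimage.map_coordinates` order-1 (bilinear) with
  constant fill; output pixel (y, x) samples the input at (y−dy, x−dx).
- Pairwise matrices accept a deterministic pair budget: unordered pairs
  ordered by (distance, index) are strided down to the budget and both
  orders of each kept pair are evaluated, preserving distance coverage
  and keeping the commutativity diagnostic well-defined; skipped entries
  are NaN and excluded from aggregation.
- PCC refuses zero-variance frames (degenerate input) rather than
  returning an arbitrary peak.
- The mode reducer's histogram starts half a bin below the sample
  minimum so constant fields map to themselves exactly.

## Known limitations

Translation-only: rotation, shear, scale and non-rigid deformation are
out of scope by design. Registration accuracy decays with temporal
distance on evolving scenes, so corrections are always built from
nearest-neighbour steps; the all-pairs machinery is diagnostic only. The
method registers the scene, not its parts — it is unsuitable for cell
tracking, since individual cell motion is precisely what the median
discards. Variable-frame-rate video is rejected rather than resampled.
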