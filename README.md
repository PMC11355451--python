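# stackalign

Fiduciary-free stage-drift and jitter correction for multi-sample
time-lapse microscopy.

## The problem

Simultaneous multi-sample time-lapse microscopy (SMSTM) scans many wells
of a plate with a single microscope, relocating the motorized stage
between every acquisition. Limited actuator precision means each sample's
time-lapse carries a random lateral offset per frame — jitter plus slow
directional drift — so the region of interest wanders across the
recording. Instruments can fix this actively with fiduciary sample
holders ("image lock-plates"), but those are not always available or
usable. `stackalign` aligns the frames passively, in software, using only
the image content.

The obstacle is that the content itself moves: cells are motile and
change shape from frame to frame. A global registration step must
therefore separate the stage's motion (shared by every pixel) from the
cells' motion (sparse, incoherent). `stackalign` does this with a robust
reduction of a dense optical-flow field.

## The method

For each consecutive frame pair the displacement field
A ∈ ℝ^(H×W×2) is estimated (dense Lucas–Kanade, an optional pretrained
deep-flow plugin, or — bypassing the field — direct phase
cross-correlation). The global per-step translation is the marginal
median of the field's components,

    Δ(t) = ( median A_x ,  median A_y ),

which ignores up to 50% contaminated pixels (the moving cells): the
stage's translation is recovered even while every cell drifts
independently. The per-frame correction is the cumulative sum of the
steps, applied as a single sub-pixel bilinear translation per frame,

    I′(t, x, y) = I(t, x, y) shifted by −Σ_{s≤t} Δ(s),

followed by reframing onto one of four canvases (maximum = union of
footprints, minimum = intersection, center, or a reference frame's
footprint), with out-of-footprint pixels filled by each frame's median
brightness.

A parametric jitter synthesiser, δ(t) = A(t)·cos(ω₁t)·cos(ω₂t) with
A(t) drawn uniformly per axis (defaults ω₁ = 0.5, ω₂ = 1.2 rad/frame,
amplitude ≤ 120 px), and a synthetic bright-field-like scene generator
provide exact ground truth for benchmarking every stage of the pipeline.

## Worked example

Stabilise a synthetic 30-frame benchmark and measure the recovery error:

```python
import numpy as np
from stackalign import (BackendConfig, FramingSpec, JitterParams, SceneParams,
                        accumulate, apply_jitter, dispersion_summary,
                        generate_scene, offset_errors, stabilize,
                        synthesize_displacements)

scene, info = generate_scene(T=30, H=256, W=256, params=SceneParams(n_cells=10, seed=0))
print(f"blob footprint: {info.footprint_fraction:.1%}")

series = synthesize_displacements(30, JitterParams(amplitude_max=20.0, seed=0))
margin = int(np.ceil(np.abs(accumulate(series).cumulative).max())) + 2
jittered, truth = apply_jitter(scene, series, canvas_margin=margin)

corrected, est, traj = stabilize(jittered,
                                 BackendConfig(method="pcc", upsample_factor=100),
                                 FramingSpec(mode="reference"))
print(dispersion_summary(offset_errors(est, truth)).to_string(index=False))
rmse = np.sqrt(np.mean((traj.cumulative - accumulate(truth).cumulative) ** 2))
print(f"trajectory RMSE: {rmse:.3f} px")
```

Output:

```
blob footprint: 7.4%
axis   median       q1       q3      max  n
   x 0.014423 0.005479 0.020371 0.030390 29
   y 0.023401 0.010052 0.034547 0.064992 29
trajectory RMSE: 0.045 px
```

The injected jitter (steps up to 20 px) is recovered with a median
per-step error of ~0.02 px and the reconstructed drift trajectory is
accurate to ~0.05 px RMS — well below the pixel scale, despite ten
motile, shape-changing cells in the field of view.

The same pipeline is available from the shell:

```sh
stackalign scene scene.tif --frames 30 --n-cells 10 --seed 0
stackalign synth scene.tif jittered.tif --truth-csv truth.csv --amplitude-max 20 --seed 0
stackalign stabilize jittered.tif stable.tif --trajectory-csv est.csv --framing reference
stackalign evaluate --estimated-csv est.csv --truth-csv truth.csv
```

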