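# gala

Landmark-free, coarse-to-fine alignment of spatial transcriptomics slices —
across platforms, resolutions and modalities, with or without full tissue
overlap.

Spatial transcriptomics platforms (Visium, Xenium, MERFISH, …) measure gene
expression at known positions in a tissue section, but two sections almost
never share a coordinate frame: sectioning and mounting introduce rotation,
shift, stretch, reflection and smooth local warping, and one slice may
cover only part of the other. `gala` registers a *source* slice onto a
*target* slice (or onto a co-registered histology image) without any manual
landmarks, for spot-to-spot, cell-to-cell, cell-to-spot and
transcriptomics-to-histology settings.

## Method in brief

Each slice is rasterized onto a shared grid Ω (spacing `dx`): every
selected gene g becomes an image channel
`I_g(x) = Σ_i y_i^g exp(−‖x − x_i‖²/2σ²)` (σ = 2·dx by default), plus a
total-expression channel; histology becomes a Sobel gradient-magnitude
contrast channel. Alignment genes are the top-3 by spatial predictability
(leave-self-out kNN-regression R² of expression from coordinates).

The estimator couples three unknowns under one objective — a global affine
`A` (rotation, anisotropic scale, reflection, translation), a local
diffeomorphism `φ` (endpoint of a flow driven by a kernel-smoothed,
time-discretized velocity field `v_t`), and a per-pixel match posterior
`P_M` from a two-class Gaussian mixture that separates matched tissue from
background or cropped-away regions:

    L(A, φ, P_M) = α/(2σ_M1²) Σ_g Σ_x P_M(x) ‖I_st^g(φ(A(x))) − J_st^g(x)‖²
                 + (1−α)/(2σ_M2²) Σ_x P_M(x) ‖I_histo(φ(A(x))) − J_histo(x)‖²
                 + 1/(2σ_R²) ∫₀¹ ‖v_t‖_V² dt

Optimization alternates a genetic-algorithm search over the affine (robust
to large rotations and reflections, and the stage that finds the
overlapping region) with an EM-like flow refinement (E-step: update `P_M`
from the residual kernels; M-step: kernel-smoothed gradient steps on
`v_t`). Two such global–local episodes suffice, with the second episode's
affine search narrowed around the incumbent and weighted by the current
`P_M`. The diffeomorphism's numerical inverse gives point transfer in both
directions. Evaluation metrics (MNN label-consistency accuracy, joint-GMM
ARI/NMI, Gaussian-weighted spatial cross-correlation, pseudo-spot cosine
similarity, landmark MAE) are included; landmarks are never used for
fitting. Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Align a synthetic slice pair with a known rotation + smooth warp and score
the recovery:

```python
import numpy as np
from gala import (AffineTransform, AlignConfig, SynthSpec, align,
                  generate_pair, landmark_mae)

truth_A = AffineTransform(theta=0.8, log_sx=np.log(1.1), tx=4.0, ty=-3.0)
spec = SynthSpec(seed=3, true_affine=truth_A, warp_amplitude=1.5)
source, target, truth = generate_pair(spec)

result = align(source, target, AlignConfig(seed=0))
lm = truth["landmarks"]
print("informative genes:", result.diagnostics["genes"])
print("recovered rotation:", round(result.affine.theta, 3))
print("pre-alignment  MAE:", round(landmark_mae(lm).value, 2))
print("post-alignment MAE:", round(landmark_mae(lm, result=result).value, 2))
```

Output:

```
informative genes: ['marker_0', 'marker_1', 'marker_2']
recovered rotation: 0.804
pre-alignment  MAE: 30.68
post-alignment MAE: 0.79
```

The generator distorted the source by a 0.8-rad rotation, 10% stretch, a
translation and a smooth warp; the ground-truth probe landmarks start
30.7 world units (≈16 grid pixels) from their true positions and end 0.79
units (≈0.4 pixels) away after alignment — the affine stage recovered the
rotation to 0.004 rad and the flow absorbed the residual warp.

The same pipeline is available from the shell:

```bash
gala simulate --preset partial60 --seed 7 --out sim/
gala align --source-coords sim/source_coords.csv --source-expr sim/source_expr.csv \
           --target-coords sim/target_coords.csv --target-expr sim/target_expr.csv \
           --seed 0 --out aligned/
gala metrics --metric accuracy --aligned-dir aligned/ \
             --source-coords sim/source_coords.csv --source-expr sim/source_expr.csv \
             --source-labels sim/source_labels.csv \
             --target-coords sim/target_coords.csv --target-expr sim/target_expr.csv \
             --target-labels sim/target_labels.csv
```

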