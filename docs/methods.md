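# Methods

## Problem and model

Two spatial-omics slices of the same (or adjacent) tissue rarely share a
coordinate frame: sectioning and mounting introduce rotation, translation,
anisotropic stretch, occasional reflection, and smooth local warping, and
the slices may cover only partially overlapping tissue. `gala` estimates a
composite map from target world coordinates **x** to source world
coordinates,

    x  ↦  φ( A(x) ),

where `A` is an invertible affine (rotation θ, anisotropic scales
e^{log sx}, e^{log sy}, optional x-reflection applied before rotation, and
translation t) and `φ` is a diffeomorphism — the endpoint of a flow
ẋ = v_t(x), t ∈ [0,1], driven by a time-discretized velocity field. The
source raster is *pulled back* through this map (backward warping): the
predicted target intensity at pixel x is the source sampled at φ(A(x)).

### Rasterization

Both slices are rendered onto regular grids with a shared spacing `dx` in a
common world frame (y increases downward, matching image row order). Each
selected gene g contributes a channel

    I_g(x) = Σ_i y_i^g · exp(−‖x − x_i‖² / 2σ²),

plus one channel carrying each point's total expression over *all* genes.
Kernels are truncated at 4σ (≈3·10⁻⁴ of peak) for O(n) splatting. σ
defaults to 2·dx per slice and may be widened on the finer-resolution side
so cell- and spot-level data reach comparable effective resolution.
Histology becomes a structural-contrast channel: luma greyscale → Sobel
gradient magnitude (normalized so a unit-intensity-per-pixel ramp reads 1)
→ Gaussian blur → area-weighted resampling to the grid.

Corresponding channels of the source/target pair are rescaled by their
**joint** maximum. A per-slice maximum would silently inflate a channel
whose peak region is cropped away from one slice, and that inflation is
enough to make a degenerate "shrink the whole target into the cropped
source" affine outscore the true one on partial-overlap data. The
standalone `concat_modalities` helper still offers plain per-channel
normalization for single-tensor use.

### Gene selection

Alignment channels are the top-p genes (default p = 3) by spatial
predictability: leave-self-out k-nearest-neighbour regression (k = 10,
unweighted mean of the k nearest other points by coordinate distance),
scored by R², ties broken lexicographically. Genes with zero variance score
zero. Genes absent from the target are replaced by the next-ranked shared
gene, since the objective compares channels one-to-one.

### Matching model

Within the estimated overlap region each target pixel either matches the
warped source or belongs to an unmatched class (background, missing or
artefactual tissue) with mean intensity μ_N. Both classes use isotropic
Gaussian kernels K(J, μ, σ) = exp(−‖J−μ‖²/2σ²) on the c-channel intensity;
with priors π_M + π_N = 1 the match posterior is

    P_M(x) = π_M K(J, I∘φ∘A, σ_M) / [ π_M K(J, I∘φ∘A, σ_M) + π_N K(J, μ_N, σ_N) ].

P_M weights every fidelity sum, which is what makes partial overlap work.
The E-step posterior and the μ_N/π_M updates are exact coordinate descents
of the functional Σ P(‖r_M‖²/2σ_M² − log π_M) + (1−P)(‖r_N‖²/2σ_N² −
log π_N) + entropy; the σ_M/σ_N refresh is a residual-scale recalibration
outside that functional (with unnormalized kernels it has no interior
optimum). π_M is clamped to [0.05, 0.95] so neither class can empty.

Initialization matters: seeding both classes from the overall residual RMS
is class-symmetric and collapses the EM into "everything matched"
(posterior ≈ constant, overlap AUC ≈ 0.5). The mixture is therefore seeded
from the residual distribution under the affine-only warp — σ_M from the
best-fitting half of pixels, σ_N and μ_N from the worst quartile — which
places the EM in the intended basin on both full- and partial-overlap
inputs.

### Objective

    L = α/(2σ_M1²) Σ_g Σ_x P_M (I_st^g(φ(A(x))) − J_st^g(x))²
      + (1−α)/(2σ_M2²) Σ_x P_M (I_histo(φ(A(x))) − J_histo(x))²
      + 1/(2σ_R²) ∫₀¹ ‖v_t‖_V² dt ,

summed over overlap ∩ warp-validity pixels. α = 1 without histology, 0.5
with. Defaults σ_M1 = σ_M2 = 0.1, σ_R = 10 on max-normalized channels —
chosen so fidelity and regularization both move visibly on the synthetic
fixtures. The mixture's σ_M/σ_N are separate knobs from σ_M1/σ_M2: the
former shape the posterior, the latter the fidelity/regularization
trade-off. In transcriptomics-to-histology mode the objective is the
single-σ variant — the lone total-expression channel against the lone
contrast channel, weight 1/(2σ_M1²), no α split. In that mode both
channels are additionally **rank-equalized** over their foregrounds
(intensities replaced by empirical quantiles): expression mass and
gradient contrast have incomparable intensity profiles, and without this
standard cross-modality intensity standardization the squared error is
dominated by the tissue footprint, leaving rotation under-determined
whenever the outline has an approximate symmetry. Same-modality channels
are already commensurable and are not equalized.

### Global stage: genetic-algorithm affine search

Chromosome (θ, log sx, log sy, u, v, reflect) with the translation genes
expressed as offsets from the map that carries the target grid centre onto
the source grid centre, so rotations pivot about the tissue. Bounds:
θ ∈ [−π, π], log-scales ∈ [log 0.5, log 2], translations from the grid
extents. Generational GA: population 64, 60 generations, tournament
selection (size 3), blend crossover (rate 0.7), per-parameter Gaussian
mutation (rate 0.3) whose scale anneals from 10% of each bound range down
to 1%, elitism 2, followed by a Nelder–Mead polish of the winner. The
initial population contains the bounds midpoint and a coarse rotation
sweep (a third of the population, up to 24 candidates) at neutral
scale/offset, giving every rotation basin a foothold — without it, large
rotations occasionally lose to premature convergence.
The fitness is −(mean over overlap pixels of the P_M- and channel-weighted
squared discrepancy) − λ_ov · scale · max(0, f_min − overlap fraction),
with λ_ov = 1, f_min = 0.2, and `scale` the channel-weighted mean squared
target intensity over foreground, making the penalty invariant to the
fidelity weighting. The mean (not sum) keeps candidates with different
overlap sizes comparable; the penalty blocks the degenerate optimum of
shrinking overlap to a few well-matched pixels.

The overlap mask requires target foreground (total channel > 1% of max)
whose affine image lands on *eroded* source foreground (> 10% of max,
2-pixel binary erosion). The stricter source side exists because the 4σ
splat tail forms a halo past a crop boundary: bright target tissue mapped
onto that near-empty halo would otherwise dominate the overlap mean and
favour shrink degeneracies.

### Local stage: EM-like flow refinement

The velocity field (T = 10 time slices) lives on a grid covering the
affine image of the target footprint — the domain φ actually acts on. Each
of `em_iters` (default 5; 3 in the benchmark configuration) sweeps runs an
E-step and nuisance M-step, then `lddmm_iters` (default 50; 25 in
benchmarks) velocity updates. One update: compute the Eulerian force
(residual × warped-source spatial gradient, weighted by P_M and the
channel weights), deposit it at the affine-image positions by bilinear
splatting, convolve with the metric kernel K_V, add the regularizer
gradient v/(σ_R²T), and take a normalized step (initial length 0.5·dx)
with halving on objective increase and 10% growth on success. The force is
applied identically to all time slices — a time-constant (greedy)
approximation appropriate for the small residual deformations left after
the global stage.

K_V is an isotropic Gaussian of width a = 4·dx, applied **spectrally**
with its eigenvalues floored at 10⁻¹². Smoothing and the V-norm
‖u‖_V² = Σ_ω |û(ω)|²/K̂(ω)/(HW) then form a consistent metric pair: the
smoothed field has finite V-norm by construction. (A spatially truncated
filter paired with the exact spectrum is catastrophically inconsistent —
round-off in the spectral tail, divided by e^{−79} at Nyquist, dominates
the energy and freezes the optimization.)

Flows are integrated by forward-Euler particle tracing with Δt = 1/T and
edge-clamped bilinear sampling of v; the inverse map re-integrates with
time reversed and velocity negated, and its accuracy is asserted
(composition error < 0.1·dx for fields with per-step magnitude ≤ 0.5·dx),
not assumed.

### Episode coupling

Two global–local episodes by default. Episode 2 re-runs the GA with
bounds narrowed around the incumbent (±0.1 rad, ±10% scale, ±5·dx
translation, reflection frozen) and with the current P_M as pixel weights —
the concrete realization of local-to-global feedback. φ is reset to
identity after each affine update to keep A and φ identifiable. An
episode's result is **accepted only if its final total does not exceed the
incumbent's** (monotone acceptance); this guard, rather than hope, is what
makes the cross-episode objective trace non-increasing, since an affine
re-search plus φ reset can transiently raise the full objective.

Point transfer uses the numeric maps only: source→target applies A⁻¹∘φ⁻¹,
target→source applies φ∘A, with φ evaluated as identity plus interpolated
displacement (identity extension outside the deformation grid; such points
are flagged). No landmark-based fallback exists anywhere.

## Synthetic fixtures

The generator builds a base tissue (700 points by default on a 60-unit
extent; jittered square lattice for spot-level data, uniform points for
cell-level) inside an irregular section outline — a per-seed rotated
ellipse with wavy boundary. Real sections are never symmetric phantoms,
and an outline with an exact symmetry would make footprint-dominated
(single-channel) alignment rotationally ambiguous by construction. Domains
are horizontal bands, or Voronoi cells of random centres for blobs, and
expression is drawn log-normally: each domain
over-expresses its marker (median 5.0 vs 0.5 outside, log-sd 0.3), plus
i.i.d. noise genes. The source slice is a resampling of the same tissue
(coordinate jitter sd 0.3, multiplicative expression noise log-sd 0.2)
pushed through a known smooth warp (Gaussian-filtered lattice noise with
stated amplitude and correlation length; amplitude < length/3 keeps it
diffeomorphic, enforced), then a known affine, then an axis-aligned crop
whose cut sits at the point quantile that retains exactly the stated
fraction. A probe-grid landmark set carried through
the same maps makes the generator its own oracle. Cell-vs-spot pairs bin
the cell side into a coarse lattice with summed expression. Pseudo-histology
renders total expression at 4× grid resolution, applies a gamma map (0.7)
and fine-grained multiplicative texture (log-sd 0.1): the texture emulates
cellular/stain micro-structure and makes the gradient-contrast map light up
the whole tissue mass, as real H&E does — the property the printed
cross-modality objective (raw expression raster vs contrast map) actually
relies on. A smooth or absent texture leaves only boundary ridges and makes
that scenario unidentifiable in practice.

What the fixtures do **not** emulate: platform-specific noise (transcript
misassignment, lateral diffusion), batch effects between slices,
topology-breaking damage (tears, folds), or histology that disagrees with
expression. Passing benchmarks therefore demonstrate correct recovery of
smooth geometric distortions under realistic expression noise — not
robustness to every artefact of real data.

Partial-overlap benchmarks use the blob layout deliberately: a purely
banded tissue is *genuinely* unidentifiable under an x-crop combined with
an x-scale (expression carries no x-information), so no method could
recover the truth there.

## Benchmark conditions and scale

Benchmark trials (in `gala.benchmarks`) use 700-spot slices, ~48-pixel
rasters, the package defaults for the coupled stages with 3 EM sweeps × 25
velocity steps, and GA defaults for the affine stage. Distortions: rotation
up to π (π/2 for partial and cross-modality), scales 0.8–1.25 (0.9–1.1),
translation up to 30% of the extent, warp amplitude 1.5 (1.0) units,
reflection on a quarter of the affine-recovery seeds. One trial runs in a
few seconds on one CPU; success means mean point-mapping error ≤ 2·dx
(affine stage) or post-alignment landmark MAE below 25% of the
pre-alignment MAE (full pipelines), plus match-posterior AUC > 0.9 against
the true overlap for partial crops.

## Numerical choices and degenerate inputs

- Bilinear sampling everywhere, zero padding with explicit validity masks;
  validity excludes padded samples from all fidelity sums.
- Grids snap outward to multiples of dx and are at least 4×4; a single
  point yields the minimal grid around it.
- `dx` defaults to (joint extent)/64 when unspecified; the physical-scale
  conventions (≈1 unit for spot data, 30 µm for cell data) are passed
  explicitly when coordinates are in physical units.
- Posterior denominators are floored at 10⁻³⁰⁰; mixture σ's at 10⁻³ of the
  channel scale; empty unmatched class retains previous parameters.
- All randomness flows from explicit integer seeds (NumPy Generator); a
  run is bit-reproducible given its inputs and seed.
- MNN ties are broken by smallest point index; gene-ranking ties
  lexicographically.
- Landmark MAE reads |·| as the per-landmark Euclidean norm (a distance
  between coordinate pairs); a per-axis variant sits behind a flag.

## Known limitations

- The affine fitness is raster-based; below ~0.3·dx the residual floor is
  set by pixelization and resampling, so reported errors should be read in
  units of dx.
- The greedy time-constant force approximation cannot realize very large
  diffeomorphic deformations (those needing genuinely time-varying
  velocity); the global stage is expected to remove gross misalignment
  first.
- Cross-modality alignment leans on the mass correlation between total
  expression and histology contrast; tissues where morphology and
  transcription decouple will violate that assumption.
- Metrics assume comparable expression scales between slices; no batch
  correction is performed anywhere.
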