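"""Seeded synthetic slice pairs with known ground truth.

The generator emulates the study conditions every scenario needs: spatially
structured expression (layered bands or blob domains, one log-normally
over-expressed marker gene per domain plus i.i.d. noise genes), platform
resolution differences (dense cell-level vs sparse spot-level point sets,
the spot side built by binning cells), histology as a gamma-mapped noisy
texture of total expression, known affine distortions and known smooth
(diffeomorphic) warps, and partial crops with a stated retained fraction.
Because the true maps are available as functions, the generator is its own
oracle: probe-grid landmarks carried through those maps define the exact
pre- and post-alignment errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .affine_ga import AffineTransform
from .io_formats import HistologyImage, LandmarkSet, PointDataset
from .rasterize import make_grid, rasterize_expression

__all__ = ["SynthSpec", "generate_pair", "generate_histology", "random_affine"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic slice pair.

    Distances are world units; with the default extent of 60 units and the
    default spot grid this corresponds to a small tissue section at Visium-
    like spot pitch. The warp amplitude must stay below one third of its
    correlation length so the ground-truth deformation is diffeomorphic.
    """

    n_points: int = 700
    extent: float = 60.0
    layout: str = "layers"           # layers | blobs
    n_domains: int = 4
    n_noise_genes: int = 5
    marker_high: float = 5.0         # log-normal median of in-domain markers
    marker_low: float = 0.5
    marker_sd: float = 0.3           # log-scale sd of expression draws
    noise_sd: float = 0.2            # per-point multiplicative noise (log sd)
    jitter_sd: float = 0.3           # source point resampling jitter
    true_affine: AffineTransform = field(default_factory=AffineTransform)
    warp_amplitude: float = 0.0
    warp_length: float = 15.0        # correlation length of the warp field
    crop_side: str = "none"          # none | left | bottom
    crop_fraction: float = 1.0       # retained fraction of the extent
    resolution: str = "both-spot"    # both-spot | both-cell | cell-vs-spot
    spot_pitch: Optional[float] = None  # lattice pitch; default extent/24
    histology: bool = False
    hist_gamma: float = 0.7
    hist_noise: float = 0.1
    landmark_grid: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("retained fraction must be in (0,1]")
        if self.warp_amplitude > 0 and \
                self.warp_amplitude >= self.warp_length / 3.0:
            raise ValueError(
                "warp amplitude must stay below correlation length / 3 "
                "for the warp to remain diffeomorphic")
        if self.layout not in ("layers", "blobs"):
            raise ValueError("layout must be 'layers' or 'blobs'")
        if self.crop_side not in ("none", "left", "bottom"):
            raise ValueError("crop side must be none, left or bottom")
        if self.resolution not in ("both-spot", "both-cell", "cell-vs-spot"):
            raise ValueError("unknown resolution setting")


def random_affine(rng: np.random.Generator, max_rotation: float = np.pi,
                  scale_range: tuple = (0.8, 1.25),
                  max_shift: float = 0.0,
                  allow_reflection: bool = False) -> AffineTransform:
    """Draw a random ground-truth affine distortion."""
    theta = rng.uniform(-max_rotation, max_rotation)
    lsx = np.log(rng.uniform(*scale_range))
    lsy = np.log(rng.uniform(*scale_range))
    tx, ty = rng.uniform(-max_shift, max_shift, size=2)
    refl = bool(rng.random() < 0.5) if allow_reflection else False
    return AffineTransform(theta, lsx, lsy, tx, ty, refl)


def _tissue_outline(spec: SynthSpec, rng: np.random.Generator):
    """Irregular section outline: a rotated ellipse with boundary waviness.

    Real sections are never symmetric phantoms; an irregular outline also
    keeps the footprint from having accidental rotational symmetry, which
    would make single-channel (footprint-dominated) alignment ambiguous.
    """
    E = spec.extent
    beta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(beta), np.sin(beta)

    def inside(pts):
        d = np.asarray(pts, float) - E / 2
        u = d[..., 0] * c + d[..., 1] * s
        w = -d[..., 0] * s + d[..., 1] * c
        phi = np.arctan2(w, u)
        rr = np.sqrt((u / 0.50) ** 2 + (w / 0.40) ** 2) / E
        bound = 0.95 + 0.10 * np.sin(3 * phi + phase) \
            + 0.06 * np.sin(2 * phi - phase)
        return rr <= bound

    return inside


def _base_points(spec: SynthSpec, rng: np.random.Generator,
                 cell_level: bool, inside) -> np.ndarray:
    E = spec.extent
    if cell_level:
        pts = np.empty((0, 2))
        while pts.shape[0] < spec.n_points:
            cand = rng.uniform(0.0, E, size=(2 * spec.n_points, 2))
            pts = np.vstack([pts, cand[inside(cand)]])
        return pts[:spec.n_points]
    # spot-like jittered square lattice clipped to the outline
    m = int(np.ceil(np.sqrt(spec.n_points / 0.55)))  # ~outline fill factor
    pitch = E / m
    gx, gy = np.meshgrid(np.arange(m), np.arange(m))
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1) * pitch + pitch / 2
    pts = pts + rng.normal(0.0, 0.08 * pitch, size=pts.shape)
    pts = pts[inside(pts)]
    if pts.shape[0] > spec.n_points:
        keep = rng.permutation(pts.shape[0])[:spec.n_points]
        pts = pts[np.sort(keep)]
    return pts


def _domain_labels(spec: SynthSpec, pts: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    E = spec.extent
    if spec.layout == "layers":
        band = np.clip((pts[:, 1] / E * spec.n_domains).astype(int),
                       0, spec.n_domains - 1)
        return band
    centers = rng.uniform(0.15 * E, 0.85 * E, size=(spec.n_domains, 2))
    d = ((pts[:, None, :] - centers[None]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def _expression(spec: SynthSpec, labels: np.ndarray,
                rng: np.random.Generator) -> tuple[np.ndarray, list]:
    n = labels.shape[0]
    G = spec.n_domains + spec.n_noise_genes
    expr = np.empty((n, G))
    names = [f"marker_{d}" for d in range(spec.n_domains)] + \
            [f"noise_{k}" for k in range(spec.n_noise_genes)]
    for d in range(spec.n_domains):
        med = np.where(labels == d, spec.marker_high, spec.marker_low)
        expr[:, d] = rng.lognormal(np.log(med), spec.marker_sd)
    for k in range(spec.n_noise_genes):
        expr[:, spec.n_domains + k] = rng.lognormal(
            np.log(1.0), spec.marker_sd, size=n)
    return expr, names


def _make_warp(spec: SynthSpec, rng: np.random.Generator) -> Callable:
    """Smooth static displacement field w(x) = x + D(x); identity if amp=0."""
    if spec.warp_amplitude <= 0:
        return lambda pts: np.asarray(pts, float)
    E = spec.extent
    margin = 0.5 * E
    node = spec.warp_length / 3.0
    ax = np.arange(-margin, E + margin + node, node)
    D = rng.normal(0.0, 1.0, size=(ax.size, ax.size, 2))
    sig = spec.warp_length / node
    for k in range(2):
        D[:, :, k] = ndimage.gaussian_filter(D[:, :, k], sig, mode="reflect")
    mx = np.abs(D).max()
    if mx > 0:
        D *= spec.warp_amplitude / mx
    interp = RegularGridInterpolator((ax, ax), D, bounds_error=False,
                                     fill_value=0.0)

    def warp(pts):
        pts = np.asarray(pts, float)
        # interpolator axes are (y, x) ordered (rows, cols) = (ax, ax)
        disp = interp(np.stack([pts[..., 1], pts[..., 0]], axis=-1))
        return pts + disp

    return warp


def _crop_threshold(spec: SynthSpec, base_pts: np.ndarray):
    """Axis cut retaining exactly crop_fraction of the base points."""
    if spec.crop_side == "none" or spec.crop_fraction >= 1.0:
        return None
    if spec.crop_side == "left":
        return float(np.quantile(base_pts[:, 0], spec.crop_fraction))
    # bottom: y increases downward, so "bottom" is large y
    return float(np.quantile(base_pts[:, 1], 1.0 - spec.crop_fraction))


def _crop_keep(spec: SynthSpec, pts: np.ndarray, threshold) -> np.ndarray:
    pts = np.asarray(pts, float)
    if threshold is None:
        return np.ones(pts.shape[0], dtype=bool)
    if spec.crop_side == "left":
        return pts[:, 0] <= threshold
    return pts[:, 1] >= threshold


def _bin_to_spots(coords: np.ndarray, expr: np.ndarray, labels: np.ndarray,
                  pitch: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate cell-level points into a coarse spot lattice (summed expr)."""
    origin = coords.min(axis=0)
    idx = np.floor((coords - origin) / pitch).astype(int)
    out_c, out_e, out_l = [], [], []
    for b in sorted(set(map(tuple, idx))):
        m = (idx[:, 0] == b[0]) & (idx[:, 1] == b[1])
        out_c.append(origin + (np.array(b) + 0.5) * pitch)
        out_e.append(expr[m].sum(axis=0))
        vals, cnt = np.unique(labels[m], return_counts=True)
        out_l.append(vals[cnt.argmax()])
    return np.array(out_c), np.array(out_e), np.array(out_l)


def generate_pair(spec: SynthSpec) -> tuple[PointDataset, PointDataset, dict]:
    """Build a (source, target, truth) triple for one scenario.

    The target is the base tissue; the source is an independent resampling
    (point jitter + expression noise) pushed through the true warp, then the
    true affine, then cropped. ``truth`` carries the forward maps, a probe-
    grid landmark set, the domain labels of both slices and a crop predicate
    over base (target-frame) coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    cell = spec.resolution in ("both-cell", "cell-vs-spot")
    inside = _tissue_outline(spec, rng)
    base = _base_points(spec, rng, cell_level=cell, inside=inside)
    labels = _domain_labels(spec, base, rng)
    expr, names = _expression(spec, labels, rng)
    warp = _make_warp(spec, rng)
    A = spec.true_affine

    if spec.resolution == "cell-vs-spot":
        pitch = spec.spot_pitch or spec.extent / 24.0
        t_coords, t_expr, t_labels = _bin_to_spots(base, expr, labels, pitch)
        target = PointDataset(t_coords, t_expr, names, labels=t_labels,
                              resolution_hint="spot")
    else:
        target = PointDataset(base, expr, names, labels=labels,
                              resolution_hint="cell" if cell else "spot")

    jit = base + rng.normal(0.0, spec.jitter_sd, size=base.shape)
    s_expr = expr * rng.lognormal(0.0, spec.noise_sd, size=expr.shape)
    thr = _crop_threshold(spec, base)
    keep = _crop_keep(spec, base, thr)
    s_coords = A.apply(warp(jit[keep]))
    source = PointDataset(s_coords, s_expr[keep], names, labels=labels[keep],
                          resolution_hint="cell" if cell else "spot")

    m = spec.landmark_grid
    g = np.linspace(0.1 * spec.extent, 0.9 * spec.extent, m)
    probes = np.array([[x, y] for y in g for x in g])
    pk = _crop_keep(spec, probes, thr)
    landmarks = LandmarkSet(probes[pk], A.apply(warp(probes[pk])))

    truth = {
        "affine": A,
        "warp": warp,
        "forward_map": lambda pts: A.apply(warp(np.asarray(pts, float))),
        "overlap_fn": lambda pts: _crop_keep(spec, pts, thr),
        "inside_fn": lambda pts: inside(np.asarray(pts, float)),
        "crop_threshold": thr,
        "landmarks": landmarks,
        "labels": labels,
        "kept": keep,
    }
    return source, target, truth


def generate_histology(ds: PointDataset, spec: SynthSpec) -> HistologyImage:
    """Render co-registered pseudo-histology from total expression.

    The total-expression raster is rendered at 4× the reference grid
    resolution, gamma-mapped and multiplied by log-normal texture noise,
    then emitted with the matching world scale/offset.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    dx_ref = spec.extent / 64.0
    dx = dx_ref / 4.0
    grid = make_grid([ds.coords], dx, pad_fraction=0.05)
    tot = rasterize_expression(ds, [], grid, sigma=2.0 * dx_ref).total_channel
    m = tot.max()
    img = (tot / m) ** spec.hist_gamma if m > 0 else tot
    if spec.hist_noise > 0:
        # fine-grained multiplicative texture, emulating cellular/stain
        # micro-structure: it makes the gradient-contrast map light up the
        # whole tissue mass (as real H&E does), not just domain boundaries
        img = img * rng.lognormal(0.0, spec.hist_noise, size=img.shape)
        img = np.clip(img / max(img.max(), 1e-12), 0.0, 1.0)
    return HistologyImage(img, scale=dx, offset=np.array(grid.origin))
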