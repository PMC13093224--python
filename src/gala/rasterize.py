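"""Modality-aware rasterization of point data and histology onto a shared grid.

Point measurements are splatted with Gaussian kernels,

    I_g(x) = sum_i y_i^g * exp(-||x - x_i||^2 / (2 sigma^2)),

producing image-like channels on a regular grid Omega with spacing ``dx``.
A total-expression channel (the per-point sum over *all* genes) stabilizes
regions where the selected genes are weak. Histology is converted to a
gradient-magnitude greyscale map (or smoothed RGB) on the same grid so the
two modalities can be compared channel-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import HistologyImage, PointDataset

__all__ = [
    "RasterGrid",
    "RasterTensor",
    "make_grid",
    "rasterize_expression",
    "rasterize_histology",
    "concat_modalities",
]

TRUNCATION_SIGMAS = 4.0  # kernel support radius; exp(-8) ~ 3e-4 of peak


@dataclass(frozen=True)
class RasterGrid:
    """A regular 2D grid: origin = world coords of pixel (0,0) centre."""

    origin: tuple
    dx: float
    H: int
    W: int

    def __post_init__(self):
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        if self.H < 4 or self.W < 4:
            raise ValueError("grid must be at least 4×4")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    def world_to_grid(self, pts: np.ndarray) -> np.ndarray:
        """World (x, y) → fractional (col, row)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / self.dx

    def grid_to_world(self, colrow: np.ndarray) -> np.ndarray:
        colrow = np.asarray(colrow, dtype=float)
        return colrow * self.dx + np.asarray(self.origin)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of pixel-centre world coordinates, each H×W."""
        xs = self.origin[0] + self.dx * np.arange(self.W)
        ys = self.origin[1] + self.dx * np.arange(self.H)
        return np.meshgrid(xs, ys)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """True where world points fall inside the pixel-centre hull."""
        cr = self.world_to_grid(pts)
        return (
            (cr[..., 0] >= 0) & (cr[..., 0] <= self.W - 1)
            & (cr[..., 1] >= 0) & (cr[..., 1] <= self.H - 1)
        )


@dataclass
class RasterTensor:
    """A c×H×W channel stack with channel-role metadata.

    Roles are ``("gene", <name>)``, ``("total",)`` or ``("histology", <k>)``.
    """

    data: np.ndarray
    grid: RasterGrid
    channel_roles: list

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("raster data must be c×H×W")
        if self.data.shape[1:] != (self.grid.H, self.grid.W):
            raise ValueError("raster shape does not match grid")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("one role per channel required")

    @property
    def c(self) -> int:
        return self.data.shape[0]

    def role_index(self, kind: str) -> list:
        return [i for i, r in enumerate(self.channel_roles) if r[0] == kind]

    @property
    def total_channel(self) -> np.ndarray:
        idx = self.role_index("total")
        if not idx:
            raise ValueError("raster has no total channel")
        return self.data[idx[0]]


def make_grid(coords_list: Sequence[np.ndarray], dx: float,
              pad_fraction: float = 0.1) -> RasterGrid:
    """Build a grid covering the bounding box of one or more point sets.

    The joint bounding box is expanded by ``pad_fraction`` of its span per
    side and snapped outward to integer multiples of ``dx``; grids smaller
    than 4×4 are symmetrically enlarged to the 4-pixel minimum.
    """
    if not dx > 0:
        raise ValueError("dx must be positive")
    coords_list = [np.asarray(c, float).reshape(-1, 2) for c in coords_list]
    if not coords_list or any(c.shape[0] == 0 for c in coords_list):
        raise ValueError("empty coordinate set")
    allc = np.vstack(coords_list)
    lo = allc.min(axis=0)
    hi = allc.max(axis=0)
    span = hi - lo
    lo = lo - pad_fraction * span
    hi = hi + pad_fraction * span
    lo_s = dx * np.floor(lo / dx + 1e-9)
    hi_s = dx * np.ceil(hi / dx - 1e-9)
    n = np.rint((hi_s - lo_s) / dx).astype(int) + 1  # (nx, ny)
    # enforce the 4-pixel minimum, expanding symmetrically (low side first)
    for ax in range(2):
        if n[ax] < 4:
            deficit = 4 - n[ax]
            lo_s[ax] -= dx * ((deficit + 1) // 2)
            n[ax] = 4
    return RasterGrid(origin=(lo_s[0], lo_s[1]), dx=float(dx),
                      H=int(n[1]), W=int(n[0]))


def _splat(coords: np.ndarray, values: np.ndarray, grid: RasterGrid,
           sigma: float, truncate: float = TRUNCATION_SIGMAS) -> np.ndarray:
    """Gaussian-splat per-point values (n×c) onto the grid → c×H×W."""
    n, c = values.shape
    out = np.zeros((c, grid.H, grid.W), dtype=float)
    rad = truncate * sigma / grid.dx  # support radius in pixels
    cr = grid.world_to_grid(coords)  # (col, row) fractional
    xs = grid.origin[0] + grid.dx * np.arange(grid.W)
    ys = grid.origin[1] + grid.dx * np.arange(grid.H)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for i in range(n):
        col, row = cr[i]
        c0 = max(0, int(math.ceil(col - rad)))
        c1 = min(grid.W - 1, int(math.floor(col + rad)))
        r0 = max(0, int(math.ceil(row - rad)))
        r1 = min(grid.H - 1, int(math.floor(row + rad)))
        if c0 > c1 or r0 > r1:
            continue
        dx2 = (xs[c0:c1 + 1] - coords[i, 0]) ** 2
        dy2 = (ys[r0:r1 + 1] - coords[i, 1]) ** 2
        k = np.exp(-(dy2[:, None] + dx2[None, :]) * inv2s2)
        out[:, r0:r1 + 1, c0:c1 + 1] += values[i][:, None, None] * k
    return out


def rasterize_expression(ds: PointDataset, genes: Sequence[str],
                         grid: RasterGrid, sigma: float,
                         truncate: float = TRUNCATION_SIGMAS) -> RasterTensor:
    """Splat the selected genes plus a total-expression channel onto ``grid``.

    The total channel uses each point's summed expression over *all* genes in
    the dataset, not just the selected ones. Kernels are truncated at
    ``truncate``·sigma (default 4σ) for O(n) cost.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    idx = [ds.gene_index(g) for g in genes]
    totals = ds.expr.sum(axis=1, keepdims=True)
    vals = np.hstack([ds.expr[:, idx], totals]) if idx else totals
    data = _splat(ds.coords, vals, grid, sigma, truncate)
    roles = [("gene", g) for g in genes] + [("total",)]
    return RasterTensor(data, grid, roles)


def _grey(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels
    # Rec.709 luma
    return pixels @ np.array([0.2126, 0.7152, 0.0722])


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, normalized so a unit-slope ramp reads 1.

    The raw Sobel kernel ([-1,0,1]⊗[1,2,1]) responds with 8× the per-pixel
    slope on a linear ramp, hence the /8.
    """
    gx = ndimage.sobel(img, axis=1, mode="nearest") / 8.0
    gy = ndimage.sobel(img, axis=0, mode="nearest") / 8.0
    return np.hypot(gx, gy)


def _resample_to_grid(channel: np.ndarray, img: HistologyImage,
                      grid: RasterGrid) -> np.ndarray:
    """Area-weighted resampling: average image pixels falling in each cell."""
    h, w = channel.shape
    xs, ys = img.pixel_world_coords()
    # grid-cell index of every image pixel (cells are dx-squares on centres)
    ci = np.floor((xs - grid.origin[0]) / grid.dx + 0.5).astype(int)
    ri = np.floor((ys - grid.origin[1]) / grid.dx + 0.5).astype(int)
    okc = (ci >= 0) & (ci < grid.W)
    okr = (ri >= 0) & (ri < grid.H)
    if not okc.any() or not okr.any():
        raise ValueError("histology image does not overlap the grid")
    sub = channel[np.ix_(okr, okc)]
    rr = np.repeat(ri[okr], okc.sum())
    cc = np.tile(ci[okc], okr.sum())
    flat = rr * grid.W + cc
    sums = np.bincount(flat, weights=sub.ravel(), minlength=grid.H * grid.W)
    cnts = np.bincount(flat, minlength=grid.H * grid.W)
    out = np.zeros(grid.H * grid.W)
    nz = cnts > 0
    out[nz] = sums[nz] / cnts[nz]
    return out.reshape(grid.H, grid.W)


def rasterize_histology(img: HistologyImage, grid: RasterGrid,
                        sigma_h: float, mode: str = "gradient_grey") -> RasterTensor:
    """Turn a histology image into structural-contrast raster channels.

    ``gradient_grey`` (default): greyscale → Sobel gradient magnitude →
    Gaussian blur with width ``sigma_h`` (world units) → area-weighted
    resampling onto the grid; one channel. ``rgb``: three smoothed colour
    channels resampled the same way.
    """
    if mode not in ("gradient_grey", "rgb"):
        raise ValueError(f"unknown histology mode {mode!r}")
    sig_px = max(sigma_h / img.scale, 0.0)
    if mode == "gradient_grey":
        g = _grey(img.pixels)
        mag = sobel_magnitude(g)
        if sig_px > 0:
            mag = ndimage.gaussian_filter(mag, sig_px, mode="nearest")
        chans = [mag]
        roles = [("histology", "gradient_grey")]
    else:
        pix = img.pixels
        if pix.ndim == 2:
            pix = pix[:, :, None].repeat(3, axis=2)
        chans = [
            ndimage.gaussian_filter(pix[:, :, k], sig_px, mode="nearest")
            if sig_px > 0 else pix[:, :, k]
            for k in range(3)
        ]
        roles = [("histology", k) for k in ("r", "g", "b")]
    data = np.stack([_resample_to_grid(ch, img, grid) for ch in chans])
    return RasterTensor(data, grid, roles)


def bilinear_sample(data: np.ndarray, grid: RasterGrid, pts: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample c×H×W channels at world points by bilinear interpolation.

    Out-of-bounds samples read 0; the returned boolean mask marks points that
    fell inside the pixel-centre hull (valid samples). ``pts`` has shape
    (..., 2); values come back as (c, ...).
    """
    pts = np.asarray(pts, dtype=float)
    cr = grid.world_to_grid(pts)
    col = cr[..., 0]
    row = cr[..., 1]
    valid = (col >= 0) & (col <= grid.W - 1) & (row >= 0) & (row <= grid.H - 1)
    coords = np.stack([row.ravel(), col.ravel()])
    out = np.empty((data.shape[0],) + pts.shape[:-1], dtype=float)
    for k in range(data.shape[0]):
        out[k] = ndimage.map_coordinates(
            data[k], coords, order=1, mode="constant", cval=0.0
        ).reshape(pts.shape[:-1])
    return out, valid


def normalize_channels(t: RasterTensor) -> RasterTensor:
    """Rescale each channel to maximum 1; all-zero channels are left as-is."""
    data = t.data.copy()
    for k in range(data.shape[0]):
        m = data[k].max()
        if m > 0:
            data[k] = data[k] / m
    return RasterTensor(data, t.grid, list(t.channel_roles))


def stack_modalities(st: RasterTensor,
                     histo: Optional[RasterTensor] = None) -> RasterTensor:
    """Stack transcriptomic and histology channels without rescaling."""
    if histo is None:
        return st
    if histo.grid != st.grid:
        raise ValueError("modalities must share one grid")
    return RasterTensor(
        np.concatenate([st.data, histo.data], axis=0), st.grid,
        list(st.channel_roles) + list(histo.channel_roles),
    )


def normalize_pair(I: RasterTensor, J: RasterTensor,
                   ) -> tuple[RasterTensor, RasterTensor]:
    """Rescale corresponding channels of a raster pair by their joint max.

    Using one scale per channel *pair* keeps intensities comparable when a
    channel's peak region is cropped away from one slice — a per-slice max
    would silently inflate that slice's channel.
    """
    if I.c != J.c:
        raise ValueError("pair normalization needs matching channel counts")
    di, dj = I.data.copy(), J.data.copy()
    for k in range(I.c):
        m = max(di[k].max(), dj[k].max())
        if m > 0:
            di[k] /= m
            dj[k] /= m
    return (RasterTensor(di, I.grid, list(I.channel_roles)),
            RasterTensor(dj, J.grid, list(J.channel_roles)))


def equalize_channels(t: RasterTensor, frac: float = 0.02) -> RasterTensor:
    """Rank-equalize each channel over its foreground (background stays 0).

    Foreground intensities are replaced by their empirical quantiles, giving
    every channel the same (uniform) intensity distribution on tissue. This
    is the cross-modality intensity standardization used when comparing an
    expression raster against a histology contrast map: a squared-error
    objective on equalized channels matches structure rather than the
    incomparable raw intensity profiles of the two modalities.
    """
    data = t.data.copy()
    for k in range(data.shape[0]):
        ch = data[k]
        m = ch.max()
        if m <= 0:
            continue
        fg = ch > frac * m
        vals = ch[fg]
        ranks = vals.argsort().argsort()
        eq = np.zeros_like(ch)
        eq[fg] = (ranks + 1) / vals.size
        data[k] = eq
    return RasterTensor(data, t.grid, list(t.channel_roles))


def concat_modalities(st: RasterTensor,
                      histo: Optional[RasterTensor] = None) -> RasterTensor:
    """Stack transcriptomic and histology channels, then max-normalize each.

    Per-channel normalization to [0, 1] makes a single residual scale
    meaningful across genes and histology.
    """
    if histo is None:
        return normalize_channels(st)
    if histo.grid != st.grid:
        raise ValueError("modalities must share one grid")
    merged = RasterTensor(
        np.concatenate([st.data, histo.data], axis=0), st.grid,
        list(st.channel_roles) + list(histo.channel_roles),
    )
    return normalize_channels(merged)
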