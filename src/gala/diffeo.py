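"""Diffeomorphic deformation: time-varying velocity field and its flow.

The local deformation φ is the endpoint of the flow ẋ = v_t(x), t ∈ [0, 1],
with v discretized on a raster grid at T time steps. Smoothness of v is
induced by a Gaussian metric kernel K_V of width ``a`` (world units): the
Hilbert-space gradient used during optimization is the Eulerian force field
convolved with K_V, and the regularization energy ∫‖v_t‖_V² dt is evaluated
spectrally through the kernel's Fourier eigenvalues. The inverse map comes
from re-integrating the flow with time reversed and velocity negated, and
its accuracy is asserted rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .affine_ga import AffineTransform
from .rasterize import RasterGrid, RasterTensor, bilinear_sample

__all__ = [
    "VelocityField",
    "DiffeoMap",
    "smooth_velocity",
    "integrate_flow",
    "reg_energy",
    "warp_raster",
    "identity_map",
]

DEFAULT_T = 10          # time steps of the flow discretization
DEFAULT_KERNEL_FACTOR = 4.0  # metric kernel width a = 4·dx by default


@dataclass
class VelocityField:
    """T×H×W×2 velocities (world units per unit time) on ``grid``."""

    v: np.ndarray
    grid: RasterGrid
    kernel_width: float  # metric kernel width a (world units)

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 4 or self.v.shape[3] != 2:
            raise ValueError("velocity must be T×H×W×2")
        if self.v.shape[1:3] != (self.grid.H, self.grid.W):
            raise ValueError("velocity shape does not match grid")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity must be finite")
        if not self.kernel_width > 0:
            raise ValueError("kernel width must be positive")

    @property
    def T(self) -> int:
        return self.v.shape[0]

    @classmethod
    def zeros(cls, grid: RasterGrid, T: int = DEFAULT_T,
              kernel_width: Optional[float] = None) -> "VelocityField":
        a = kernel_width if kernel_width is not None \
            else DEFAULT_KERNEL_FACTOR * grid.dx
        return cls(np.zeros((T, grid.H, grid.W, 2)), grid, a)


@dataclass
class DiffeoMap:
    """Forward and inverse flow-endpoint maps sampled on a grid.

    ``phi``/``phi_inv`` are H×W×2 world-coordinate maps; evaluating at
    arbitrary world points interpolates the displacement field (zero
    displacement outside the grid, so the map degrades to the identity
    away from the modelled domain).
    """

    phi: np.ndarray
    phi_inv: np.ndarray
    grid: RasterGrid

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.phi_inv = np.asarray(self.phi_inv, dtype=float)
        for m in (self.phi, self.phi_inv):
            if m.shape != (self.grid.H, self.grid.W, 2):
                raise ValueError("map shape does not match grid")
            if not np.all(np.isfinite(m)):
                raise ValueError("maps must be finite")

    def _eval(self, disp_grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        disp, _ = bilinear_sample(
            np.moveaxis(disp_grid, -1, 0), self.grid, pts
        )
        return pts + np.moveaxis(disp, 0, -1)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """φ at arbitrary world points (identity + interpolated displacement)."""
        X, Y = self.grid.world_coords()
        disp = self.phi - np.stack([X, Y], axis=-1)
        return self._eval(disp, pts)

    def apply_inverse(self, pts: np.ndarray) -> np.ndarray:
        X, Y = self.grid.world_coords()
        disp = self.phi_inv - np.stack([X, Y], axis=-1)
        return self._eval(disp, pts)

    def composition_error(self) -> float:
        """max‖φ⁻¹(φ(x)) − x‖ over interior grid pixels."""
        X, Y = self.grid.world_coords()
        pts = np.stack([X, Y], axis=-1)
        back = self.apply_inverse(self.apply(pts))
        err = np.linalg.norm(back - pts, axis=-1)
        return float(err[2:-2, 2:-2].max()) if min(err.shape) > 4 \
            else float(err.max())

    @classmethod
    def identity(cls, grid: RasterGrid) -> "DiffeoMap":
        X, Y = grid.world_coords()
        ident = np.stack([X, Y], axis=-1)
        return cls(ident.copy(), ident.copy(), grid)


def identity_map(grid: RasterGrid) -> DiffeoMap:
    return DiffeoMap.identity(grid)


SPECTRUM_FLOOR = 1e-12  # keeps the inverse metric bounded at high frequency


def _kernel_spectrum(grid: RasterGrid, a: float) -> np.ndarray:
    """Fourier eigenvalues of the Gaussian metric kernel K_V (floored).

    The floor bounds the inverse metric so round-off noise in the far tail
    of the spectrum cannot dominate the V-norm.
    """
    fy = np.fft.fftfreq(grid.H, d=grid.dx)
    fx = np.fft.fftfreq(grid.W, d=grid.dx)
    F2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.maximum(np.exp(-2.0 * np.pi ** 2 * a ** 2 * F2), SPECTRUM_FLOOR)


def smooth_velocity(raw: np.ndarray, a: float, grid: RasterGrid) -> VelocityField:
    """Convolve each time slice/component with the metric kernel K_V.

    Implemented spectrally (periodic Gaussian of width ``a``), using the same
    kernel eigenvalues as :func:`reg_energy`, so smoothing and the V-norm
    form a consistent metric pair. This is the K∘gradient step of the flow
    optimization: ``raw`` holds Eulerian force fields and the returned field
    is their image under K_V.
    """
    if not a > 0:
        raise ValueError("kernel width must be positive")
    raw = np.asarray(raw, dtype=float)
    Khat = _kernel_spectrum(grid, a)
    out = np.empty_like(raw)
    for t in range(raw.shape[0]):
        for k in range(2):
            out[t, :, :, k] = np.real(
                np.fft.ifft2(np.fft.fft2(raw[t, :, :, k]) * Khat))
    return VelocityField(out, grid, a)


def _sample_velocity(v_slice: np.ndarray, grid: RasterGrid,
                     pts: np.ndarray) -> np.ndarray:
    """Sample one velocity time slice at world points (edge-clamped)."""
    cr = grid.world_to_grid(pts)
    coords = np.stack([cr[..., 1].ravel(), cr[..., 0].ravel()])
    out = np.empty(pts.shape, dtype=float)
    for k in range(2):
        out[..., k] = ndimage.map_coordinates(
            v_slice[:, :, k], coords, order=1, mode="nearest"
        ).reshape(pts.shape[:-1])
    return out


def integrate_flow(v: VelocityField, direction: str = "both") -> DiffeoMap:
    """Integrate ẋ = v_t(x) from every grid pixel over t ∈ [0, 1].

    Forward Euler particle tracing with Δt = 1/T and bilinear (edge-clamped)
    sampling of v along each trajectory. The inverse map uses the same
    stepping with time reversed and velocity negated. With v = 0 the result
    is the identity exactly; a constant field translates exactly.
    """
    if direction not in ("forward", "inverse", "both"):
        raise ValueError("direction must be forward, inverse or both")
    grid = v.grid
    X, Y = grid.world_coords()
    ident = np.stack([X, Y], axis=-1)
    dt = 1.0 / v.T

    def trace(sign: float) -> np.ndarray:
        pos = ident.copy()
        steps = range(v.T) if sign > 0 else range(v.T - 1, -1, -1)
        for t in steps:
            pos = pos + sign * dt * _sample_velocity(v.v[t], grid, pos)
        return pos

    phi = trace(+1.0) if direction in ("forward", "both") else ident.copy()
    phi_inv = trace(-1.0) if direction in ("inverse", "both") else ident.copy()
    return DiffeoMap(phi, phi_inv, grid)


def reg_energy(v: VelocityField) -> float:
    """Discretized ∫₀¹ ‖v_t‖_V² dt, evaluated spectrally.

    ‖u‖_V² = Σ_ω |û(ω)|² / K̂_V(ω) / (H·W) per component (Parseval scaling),
    i.e. the quadratic form of the inverse metric kernel; always ≥ 0 and
    exactly quadratic in v.
    """
    grid = v.grid
    Khat = _kernel_spectrum(grid, v.kernel_width)
    total = 0.0
    for t in range(v.T):
        for k in range(2):
            u = np.fft.fft2(v.v[t, :, :, k])
            total += float(np.sum(np.abs(u) ** 2 / Khat)) / (grid.H * grid.W)
    return total / v.T


def warp_raster(I: RasterTensor, A: AffineTransform, phi: Optional[DiffeoMap],
                out_grid: Optional[RasterGrid] = None,
                ) -> tuple[RasterTensor, np.ndarray]:
    """Pull back source raster I through the composite map φ(A(x)).

    For each output pixel x the channel value is the bilinear sample of I at
    the world point φ(A(x)); out-of-bounds samples read 0 and are marked
    invalid in the returned mask. The affine is applied to output-grid
    coordinates first, then the flow (backward-warping convention).
    """
    if out_grid is None:
        if phi is None:
            raise ValueError("need an output grid when phi is None")
        out_grid = phi.grid
    if abs(I.grid.dx - out_grid.dx) > 1e-9:
        raise ValueError("rasters must share dx")
    X, Y = out_grid.world_coords()
    pts = np.stack([X, Y], axis=-1)
    mapped = A.apply(pts.reshape(-1, 2)).reshape(pts.shape)
    if phi is not None:
        mapped = phi.apply(mapped)
    vals, valid = bilinear_sample(I.data, I.grid, mapped)
    out = RasterTensor(vals, out_grid, list(I.channel_roles))
    return out, valid
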