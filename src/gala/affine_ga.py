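"""Global affine stage: genetic-algorithm search over rigid+scale+reflection.

The affine A maps target-grid world coordinates into source world
coordinates, A(x) = R(theta) · F(reflect) · S(sx, sy) · x + t, and is scored
by the match-weighted squared raster discrepancy over the estimated overlap
region. A population-based search (tournament selection, blend crossover,
Gaussian mutation, elitism) avoids the local minima that defeat
gradient-based affine registration under large rotations or reflections,
and a simplex polish sharpens the winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .rasterize import RasterGrid, RasterTensor, bilinear_sample

__all__ = [
    "AffineTransform",
    "GAConfig",
    "affine_apply",
    "ga_fitness",
    "ga_search",
]

FOREGROUND_FRACTION = 0.01  # total-channel threshold defining tissue pixels
# The source-side mask is stricter: thresholded higher and eroded by the
# splat kernel's reach, so target pixels landing on the source's kernel-tail
# halo (bright target vs near-empty source) are treated as non-overlap
# instead of poisoning the discrepancy mean.
SRC_FOREGROUND_FRACTION = 0.1
SRC_FOREGROUND_ERODE_PX = 2
OVERLAP_PENALTY = 1.0       # lambda_ov, in units of the data discrepancy scale
MIN_OVERLAP_FRACTION = 0.2  # f_min


@dataclass(frozen=True)
class AffineTransform:
    """2D affine: rotation, anisotropic scale, optional x-flip, translation.

    Composes as A(x) = R(theta)·F(reflect)·S(e^log_sx, e^log_sy)·x + t, which
    is invertible by construction (scales are strictly positive).
    """

    theta: float = 0.0
    log_sx: float = 0.0
    log_sy: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    reflect: bool = False

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        F = np.diag([-1.0 if self.reflect else 1.0, 1.0])
        S = np.diag([np.exp(self.log_sx), np.exp(self.log_sy)])
        return R @ F @ S

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    def apply_inverse(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.translation) @ self.inverse_matrix().T

    def to_dict(self) -> dict:
        return {
            "theta": self.theta, "log_sx": self.log_sx, "log_sy": self.log_sy,
            "tx": self.tx, "ty": self.ty, "reflect": bool(self.reflect),
        }


def affine_apply(A: AffineTransform, pts: np.ndarray) -> np.ndarray:
    """Apply A to world points (exact linear map + translation)."""
    return A.apply(pts)


@dataclass
class GAConfig:
    """Genetic-algorithm settings and affine parameter bounds.

    Translation bounds are offsets (world units) from the translation that
    maps the target grid centre onto the source grid centre, so rotations
    pivot around the tissue rather than the world origin.
    """

    pop_size: int = 64
    n_generations: int = 60
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    elitism_count: int = 2
    seed: int = 0
    theta_bounds: tuple = (-np.pi, np.pi)
    log_scale_bounds: tuple = (np.log(0.5), np.log(2.0))
    translation_bounds: Optional[tuple] = None  # ((txlo,txhi),(tylo,tyhi))
    allow_reflection: bool = False
    init_reflect: bool = False  # reflection bit used when search is disabled
    mutation_scales: Optional[np.ndarray] = None  # per continuous parameter
    polish: bool = True

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")


def foreground_mask(t: RasterTensor, frac: Optional[float] = None,
                    erode_px: int = 0) -> np.ndarray:
    """Pixels carrying tissue mass: total-channel value > frac of its max.

    Falls back to the mean over all channels when no total channel exists
    (e.g. pure-histology rasters). ``erode_px`` binarily erodes the mask,
    which pulls tissue edges in past the splatting kernel's tail so that
    partially supported boundary pixels are not mistaken for tissue.
    """
    if frac is None:
        frac = FOREGROUND_FRACTION
    try:
        ch = t.total_channel
    except ValueError:
        ch = t.data.mean(axis=0)
    m = ch.max()
    if m <= 0:
        return np.zeros_like(ch, dtype=bool)
    fg = ch > frac * m
    if erode_px > 0 and fg.any():
        from scipy import ndimage as _ndi
        eroded = _ndi.binary_erosion(fg, iterations=erode_px)
        if eroded.any():
            fg = eroded
    return fg


def _centered_affine(params: np.ndarray, reflect: bool,
                     tgt_center: np.ndarray, src_center: np.ndarray) -> AffineTransform:
    """Chromosome → canonical AffineTransform.

    The chromosome's translation genes are offsets on top of the
    centre-to-centre map: A(x) = M(x - c_t) + c_s + u.
    """
    theta, lsx, lsy, ux, uy = params
    A0 = AffineTransform(theta, lsx, lsy, 0.0, 0.0, reflect)
    t = src_center + np.array([ux, uy]) - A0.matrix @ tgt_center
    return AffineTransform(theta, lsx, lsy, t[0], t[1], reflect)


class _FitnessEvaluator:
    """Precomputes the pieces of the affine fitness that do not depend on A."""

    def __init__(self, I: RasterTensor, J: RasterTensor,
                 P_M: Optional[np.ndarray] = None,
                 channel_weights: Optional[np.ndarray] = None):
        if abs(I.grid.dx - J.grid.dx) > 1e-9:
            raise ValueError("rasters must share dx")
        self.I, self.J = I, J
        H, W = J.grid.H, J.grid.W
        self.P_M = np.ones((H, W)) if P_M is None else np.asarray(P_M, float)
        X, Y = J.grid.world_coords()
        self.pts = np.stack([X, Y], axis=-1).reshape(-1, 2)
        self.shape = (H, W)
        self.src_fg = foreground_mask(
            I, frac=SRC_FOREGROUND_FRACTION,
            erode_px=SRC_FOREGROUND_ERODE_PX).astype(float)[None]
        self.tgt_fg = foreground_mask(J)
        self.n_fg = max(int(self.tgt_fg.sum()), 1)
        self.weights = (None if channel_weights is None
                        else np.asarray(channel_weights, float)[:, None, None])
        # penalty scale uses the same channel weighting as the discrepancy
        Jd2 = J.data ** 2
        if self.weights is not None:
            Jd2 = Jd2 * self.weights
        self.scale = (float(Jd2[:, self.tgt_fg].sum(axis=0).mean())
                      if self.tgt_fg.any() else 1.0)

    def __call__(self, A: AffineTransform) -> tuple[float, np.ndarray]:
        mapped = A.apply(self.pts).reshape(self.shape + (2,))
        vals, valid = bilinear_sample(self.I.data, self.I.grid, mapped)
        src_fg_s, _ = bilinear_sample(self.src_fg, self.I.grid, mapped)
        overlap = valid & (src_fg_s[0] > 0.5) & self.tgt_fg
        if not overlap.any():
            return -np.inf, overlap
        diff2 = (vals - self.J.data) ** 2
        if self.weights is not None:
            diff2 = diff2 * self.weights
        disc = diff2.sum(axis=0)
        mean_disc = float((self.P_M * disc)[overlap].mean())
        frac = overlap.sum() / self.n_fg
        penalty = OVERLAP_PENALTY * self.scale * max(
            0.0, MIN_OVERLAP_FRACTION - frac)
        return -(mean_disc + penalty), overlap


def ga_fitness(A: AffineTransform, I: RasterTensor, J: RasterTensor,
               P_M: Optional[np.ndarray] = None,
               channel_weights: Optional[np.ndarray] = None,
               ) -> tuple[float, np.ndarray]:
    """Score an affine candidate; higher is better.

    fitness = −mean over overlap pixels of P_M·Σ_c w_c (I(A(x)) − J(x))²
              − λ_ov·scale·max(0, f_min − overlap_fraction)

    The overlap mask marks target pixels whose A-image lands on source
    foreground while the target itself is foreground; out-of-bounds samples
    are excluded. Returns (fitness, overlap_mask); an empty overlap yields
    −inf (candidate rejected).
    """
    return _FitnessEvaluator(I, J, P_M, channel_weights)(A)


def _default_bounds(cfg: GAConfig, I: RasterTensor, J: RasterTensor) -> tuple:
    if cfg.translation_bounds is not None:
        return cfg.translation_bounds
    ext = 0.5 * max(I.grid.W * I.grid.dx, I.grid.H * I.grid.dx,
                    J.grid.W * J.grid.dx, J.grid.H * J.grid.dx)
    return ((-ext, ext), (-ext, ext))


def ga_search(I: RasterTensor, J: RasterTensor, cfg: GAConfig,
              P_M: Optional[np.ndarray] = None,
              channel_weights: Optional[np.ndarray] = None,
              ) -> tuple[AffineTransform, np.ndarray, list]:
    """Generational GA over affine parameters, then a simplex polish.

    Tournament selection (size 3), blend crossover, per-parameter Gaussian
    mutation and elitism; the best-fitness trace is non-decreasing. Fully
    reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tb = _default_bounds(cfg, I, J)
    lo = np.array([cfg.theta_bounds[0], cfg.log_scale_bounds[0],
                   cfg.log_scale_bounds[0], tb[0][0], tb[1][0]])
    hi = np.array([cfg.theta_bounds[1], cfg.log_scale_bounds[1],
                   cfg.log_scale_bounds[1], tb[0][1], tb[1][1]])
    span = hi - lo
    if cfg.mutation_scales is None:
        mut = 0.1 * span
    else:
        mut = np.asarray(cfg.mutation_scales, dtype=float)

    def center(t: RasterTensor) -> np.ndarray:
        g = t.grid
        return np.array([g.origin[0] + 0.5 * (g.W - 1) * g.dx,
                         g.origin[1] + 0.5 * (g.H - 1) * g.dx])

    c_src, c_tgt = center(I), center(J)
    evaluate = _FitnessEvaluator(I, J, P_M, channel_weights)

    def decode(params, refl):
        return _centered_affine(params, bool(refl), c_tgt, c_src)

    def fit(params, refl):
        f, _ = evaluate(decode(params, refl))
        return f

    pop = lo + rng.random((cfg.pop_size, 5)) * span
    refl = (rng.random(cfg.pop_size) < 0.5) if cfg.allow_reflection \
        else np.full(cfg.pop_size, cfg.init_reflect, dtype=bool)
    # structured seeds: the bounds midpoint (identity-like on a wide search,
    # the incumbent on a narrowed re-search) plus a coarse rotation sweep at
    # neutral scale/offset, so every rotation basin has a foothold
    mid = np.clip(0.5 * (lo + hi), lo, hi)
    pop[0] = mid
    n_sweep = min(cfg.pop_size // 3, 24)
    thetas = np.linspace(cfg.theta_bounds[0], cfg.theta_bounds[1],
                         n_sweep, endpoint=False)
    for j, th in enumerate(thetas):
        cand = mid.copy()
        cand[0] = th
        pop[1 + j] = np.clip(cand, lo, hi)
        if cfg.allow_reflection:
            refl[1 + j] = bool(j % 2)
    fits = np.array([fit(pop[i], refl[i]) for i in range(cfg.pop_size)])
    if not np.isfinite(fits).any():
        raise RuntimeError("no feasible affine under bounds")

    trace = [float(fits.max())]
    for gen in range(cfg.n_generations):
        # anneal mutation from full scale down to 10% across the run
        anneal = 0.1 ** (gen / max(cfg.n_generations - 1, 1))
        mut_gen = mut * anneal
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[:cfg.elitism_count]]
        new_refl = [refl[i] for i in order[:cfg.elitism_count]]

        def tournament():
            cand = rng.integers(0, cfg.pop_size, size=3)
            return cand[np.argmax(fits[cand])]

        while len(new_pop) < cfg.pop_size:
            a, b = tournament(), tournament()
            pa, pb = pop[a].copy(), pop[b].copy()
            ra, rb = refl[a], refl[b]
            if rng.random() < cfg.crossover_rate:
                # BLX-style blend: child on the segment between parents
                u = rng.random(5)
                child = u * pa + (1 - u) * pb
                crefl = ra if rng.random() < 0.5 else rb
            else:
                child, crefl = pa, ra
            if rng.random() < cfg.mutation_rate:
                child = child + rng.normal(0.0, mut_gen)
            if cfg.allow_reflection and rng.random() < 0.1:
                crefl = not crefl
            new_pop.append(np.clip(child, lo, hi))
            new_refl.append(crefl)
        pop = np.array(new_pop)
        refl = np.array(new_refl, dtype=bool)
        fits = np.array([fit(pop[i], refl[i]) for i in range(cfg.pop_size)])
        trace.append(max(trace[-1], float(fits.max())))

    best = int(np.argmax(fits))
    best_params, best_refl = pop[best].copy(), bool(refl[best])
    best_fit = float(fits[best])
    if cfg.polish:
        def neg(params):
            p = np.clip(params, lo, hi)
            f = fit(p, best_refl)
            return 1e12 if not np.isfinite(f) else -f

        res = minimize(neg, best_params, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-10})
        cand = np.clip(res.x, lo, hi)
        f_cand = fit(cand, best_refl)
        if f_cand > best_fit:
            best_params, best_fit = cand, f_cand
    trace.append(max(trace[-1], best_fit))

    A = decode(best_params, best_refl)
    _, overlap = evaluate(A)
    return A, overlap, trace


def narrowed_config(cfg: GAConfig, incumbent: AffineTransform, dx: float,
                    tgt_center: np.ndarray, src_center: np.ndarray) -> GAConfig:
    """Bounds shrunk around an incumbent affine for a feedback re-search.

    ±0.1 rad, ±10% scale and ±5·dx translation around the incumbent; the
    reflection bit is frozen.
    """
    u = incumbent.translation + incumbent.matrix @ tgt_center - src_center
    d = np.log(1.1)
    return replace(
        cfg,
        theta_bounds=(incumbent.theta - 0.1, incumbent.theta + 0.1),
        log_scale_bounds=(min(incumbent.log_sx, incumbent.log_sy) - d,
                          max(incumbent.log_sx, incumbent.log_sy) + d),
        translation_bounds=((u[0] - 5 * dx, u[0] + 5 * dx),
                            (u[1] - 5 * dx, u[1] + 5 * dx)),
        allow_reflection=False,
        init_reflect=bool(incumbent.reflect),
        n_generations=max(10, cfg.n_generations // 3),
    )
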