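"""Coupled coarse-to-fine alignment of two slices.

The full objective couples a global affine A, a diffeomorphic deformation φ
and the match posterior P_M:

    L = α/(2σ_M1²) Σ_g Σ_x P_M(x) (I_st^g(φ(A(x))) − J_st^g(x))²
      + (1−α)/(2σ_M2²) Σ_x P_M(x) (I_histo(φ(A(x))) − J_histo(x))²
      + 1/(2σ_R²) ∫₀¹ ‖v_t‖_V² dt

Optimization alternates global episodes (genetic-algorithm affine search,
first over wide bounds and then over bounds narrowed around the incumbent —
the local-to-global feedback) with local episodes (EM-like flow refinement:
E-step updates P_M from the residual kernels; the M-step takes
kernel-smoothed gradient steps on the velocity field and refreshes the
unmatched-class nuisance parameters). An episode's result is accepted only
if it does not increase the total objective, so the trace is non-increasing
across episodes by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from .affine_ga import (AffineTransform, GAConfig, _FitnessEvaluator,
                        foreground_mask, ga_search, narrowed_config)
from .diffeo import (DiffeoMap, VelocityField, integrate_flow, reg_energy,
                     smooth_velocity, warp_raster)
from .gene_select import rank_genes, shared_informative
from .io_formats import HistologyImage, PointDataset
from .match_em import MatchField, e_step, init_match_field, m_step_nuisance
from .rasterize import (RasterGrid, RasterTensor, bilinear_sample,
                        concat_modalities, equalize_channels, make_grid,
                        normalize_channels, normalize_pair,
                        rasterize_expression, rasterize_histology,
                        stack_modalities)

logger = logging.getLogger("gala")

__all__ = [
    "AlignConfig",
    "AlignmentResult",
    "objective",
    "local_refine",
    "align",
    "align_st_to_histology",
    "transfer_points",
]


@dataclass
class AlignConfig:
    """Hyper-parameters of the coupled optimization.

    alpha weights transcriptomic vs histological fidelity (1.0 when no
    histology); sigma_M1/sigma_M2/sigma_R set the fidelity/regularization
    trade-off on max-normalized channels; n_episodes global–local rounds
    (two suffice); em_iters E/M sweeps per episode with lddmm_iters velocity
    gradient steps each.
    """

    alpha: float = 1.0
    sigma_M1: float = 0.1
    sigma_M2: float = 0.1
    sigma_R: float = 10.0
    n_episodes: int = 2
    em_iters: int = 5
    lddmm_iters: int = 50
    lddmm_step_size: Optional[float] = None  # world units; default 0.5·dx
    flow_T: int = 10
    kernel_factor: float = 4.0   # metric kernel width a = kernel_factor·dx
    n_genes: int = 3
    knn_k: int = 10
    dx: Optional[float] = None   # default: joint extent / grid_pixels
    grid_pixels: int = 64
    sigma_factor: float = 2.0    # rasterization σ = sigma_factor·dx
    sigma_src_factor: Optional[float] = None
    pad_fraction: float = 0.1
    histology_mode: str = "gradient_grey"
    sigma_h: Optional[float] = None  # histology smoothing; default = dx
    log1p: bool = True
    mode: str = "spot-spot"      # spot-spot | cell-cell | cell-spot | st-histo
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    pi_M_init: float = 0.7
    require_shared_genes: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if min(self.sigma_M1, self.sigma_M2, self.sigma_R) <= 0:
            raise ValueError("all sigma weights must be positive")
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")


@dataclass
class AlignmentResult:
    """Everything the coupled optimizer produced."""

    affine: AffineTransform
    diffeo: DiffeoMap
    velocity: Optional[VelocityField]
    match: MatchField
    match_grid: RasterGrid             # target grid carrying P_M
    overlap_mask: np.ndarray
    objective_trace: list              # per-iteration dicts
    aligned_source_coords: np.ndarray
    config: dict
    diagnostics: dict


def _channel_weights(roles: Sequence, cfg: AlignConfig) -> np.ndarray:
    """Per-channel weights: α/(2σ_M1²) for st, (1−α)/(2σ_M2²) for histology.

    In st-histo mode the objective is the single-σ_M variant: the lone
    channel pair is weighted 1/(2σ_M1²) with no α split.
    """
    if cfg.mode == "st-histo":
        return np.full(len(roles), 1.0 / (2.0 * cfg.sigma_M1 ** 2))
    w_st = cfg.alpha / (2.0 * cfg.sigma_M1 ** 2)
    w_h = (1.0 - cfg.alpha) / (2.0 * cfg.sigma_M2 ** 2)
    return np.array([w_h if r[0] == "histology" else w_st for r in roles])


def _fidelity(I: RasterTensor, J: RasterTensor, A: AffineTransform,
              phi: Optional[DiffeoMap], P_M: np.ndarray, mask: np.ndarray,
              cfg: AlignConfig) -> tuple[float, float, np.ndarray]:
    """(fidelity_st, fidelity_histo, validity) for the current transforms."""
    warped, valid = warp_raster(I, A, phi, out_grid=J.grid)
    m = mask & valid
    w = P_M * m
    diff2 = (warped.data - J.data) ** 2
    if cfg.mode == "st-histo":
        fid_st = float((diff2.sum(axis=0) * w).sum()) / (2 * cfg.sigma_M1 ** 2)
        return fid_st, 0.0, valid
    st_idx = [i for i, r in enumerate(J.channel_roles) if r[0] != "histology"]
    h_idx = [i for i, r in enumerate(J.channel_roles) if r[0] == "histology"]
    fid_st = cfg.alpha / (2 * cfg.sigma_M1 ** 2) * float(
        (diff2[st_idx].sum(axis=0) * w).sum()) if st_idx else 0.0
    fid_h = (1 - cfg.alpha) / (2 * cfg.sigma_M2 ** 2) * float(
        (diff2[h_idx].sum(axis=0) * w).sum()) if h_idx else 0.0
    return fid_st, fid_h, valid


def objective(A: AffineTransform, v: Optional[VelocityField], mf: MatchField,
              I: RasterTensor, J: RasterTensor, cfg: AlignConfig,
              mask: Optional[np.ndarray] = None,
              phi: Optional[DiffeoMap] = None,
              ) -> tuple[float, float, float, float]:
    """Evaluate the full objective; returns (total, fid_st, fid_histo, reg).

    Fidelity sums run over the overlap mask intersected with the warp
    validity mask; the regularizer is 1/(2σ_R²)·∫‖v_t‖_V² dt.
    """
    if I.data.shape[0] != J.data.shape[0]:
        raise ValueError("channel mismatch between source and target rasters")
    if mask is None:
        mask = np.ones((J.grid.H, J.grid.W), dtype=bool)
    if phi is None and v is not None:
        phi = integrate_flow(v, "forward")
    fid_st, fid_h, _ = _fidelity(I, J, A, phi, mf.P_M, mask, cfg)
    reg = reg_energy(v) / (2 * cfg.sigma_R ** 2) if v is not None else 0.0
    return fid_st + fid_h + reg, fid_st, fid_h, reg


def _phi_grid_for(A: AffineTransform, J_grid: RasterGrid,
                  pad: float = 0.15) -> RasterGrid:
    """Grid (same dx) covering the A-image of the target footprint.

    The velocity field lives on the affine-transformed coordinate domain, so
    its grid must contain A(x) for every target pixel x.
    """
    xs = [J_grid.origin[0], J_grid.origin[0] + (J_grid.W - 1) * J_grid.dx]
    ys = [J_grid.origin[1], J_grid.origin[1] + (J_grid.H - 1) * J_grid.dx]
    corners = np.array([[x, y] for x in xs for y in ys])
    return make_grid([A.apply(corners)], J_grid.dx, pad_fraction=pad)


def local_refine(I: RasterTensor, J: RasterTensor, A: AffineTransform,
                 mf: Optional[MatchField], cfg: AlignConfig,
                 mask: Optional[np.ndarray] = None,
                 ) -> tuple[VelocityField, DiffeoMap, MatchField, list]:
    """EM-like flow refinement with the affine held fixed.

    Each sweep runs an E-step (posterior P_M from the current residual
    kernels, nuisance M-step for μ_N/π/σ) followed by ``lddmm_iters``
    velocity updates: the Eulerian fidelity force — residual times warped
    source gradient, deposited at the affine-image positions — is smoothed
    by the metric kernel, combined with the regularizer gradient, and
    applied with step-size halving whenever the objective would increase.
    """
    dx = J.grid.dx
    if mask is None:
        _, mask = _FitnessEvaluator(I, J)(A)
        if not mask.any():
            raise RuntimeError("empty overlap under the supplied affine")
    vgrid = _phi_grid_for(A, J.grid)
    a = cfg.kernel_factor * dx
    v = VelocityField.zeros(vgrid, T=cfg.flow_T, kernel_width=a)
    phi = integrate_flow(v, "forward")

    warped0, _ = warp_raster(I, A, phi, out_grid=J.grid)
    if mf is None:
        mf = init_match_field(J, warped0, mask, pi_M=cfg.pi_M_init)

    wch = _channel_weights(J.channel_roles, cfg)
    X, Y = J.grid.world_coords()
    tgt_pts = np.stack([X, Y], axis=-1).reshape(-1, 2)
    mapped_A = A.apply(tgt_pts).reshape(J.grid.H, J.grid.W, 2)

    # spatial gradients of the source channels (per world unit)
    gIy = np.stack([np.gradient(I.data[c], I.grid.dx, axis=0)
                    for c in range(I.c)])
    gIx = np.stack([np.gradient(I.data[c], I.grid.dx, axis=1)
                    for c in range(I.c)])

    step = cfg.lddmm_step_size if cfg.lddmm_step_size is not None else 0.5 * dx
    trace = []

    def total_of(v_field, phi_field, match):
        t, fs, fh, rg = objective(A, v_field, match, I, J, cfg,
                                  mask=mask, phi=phi_field)
        return t, fs, fh, rg

    for sweep in range(cfg.em_iters):
        warped, _ = warp_raster(I, A, phi, out_grid=J.grid)
        mf = e_step(warped, J, mf, mask)
        mu_N, pi_M, s_M, s_N = m_step_nuisance(J, mf.P_M, mask, warped, mf)
        mf = MatchField(mf.P_M, pi_M, mu_N, s_M, s_N)

        cur_total, fs, fh, rg = total_of(v, phi, mf)
        trace.append({"fidelity_st": fs, "fidelity_histo": fh,
                      "regularization": rg, "total": cur_total,
                      "sweep": sweep, "stage": "e_step"})

        for it in range(cfg.lddmm_iters):
            warped, valid = warp_raster(I, A, phi, out_grid=J.grid)
            w = (mf.P_M * (mask & valid)).ravel()
            # composite sample points z = φ(A(x)) and source gradients there
            z = phi.apply(mapped_A.reshape(-1, 2))
            gx, _ = bilinear_sample(gIx, I.grid, z)
            gy, _ = bilinear_sample(gIy, I.grid, z)
            resid = (warped.data - J.data).reshape(I.c, -1)
            coef = (wch[:, None] * resid) * w[None, :]
            fx = (coef * gx).sum(axis=0)
            fy = (coef * gy).sum(axis=0)
            # deposit force at the affine-image positions on the velocity grid
            raw = np.zeros((1, vgrid.H, vgrid.W, 2))
            cr = vgrid.world_to_grid(mapped_A.reshape(-1, 2))
            c0 = np.floor(cr).astype(int)
            fc = cr - c0
            for dy in (0, 1):
                for dxi in (0, 1):
                    wt = (fc[:, 0] if dxi else 1 - fc[:, 0]) * \
                         (fc[:, 1] if dy else 1 - fc[:, 1])
                    rr = np.clip(c0[:, 1] + dy, 0, vgrid.H - 1)
                    cc = np.clip(c0[:, 0] + dxi, 0, vgrid.W - 1)
                    np.add.at(raw[0, :, :, 0], (rr, cc), wt * fx)
                    np.add.at(raw[0, :, :, 1], (rr, cc), wt * fy)
            force = smooth_velocity(raw, a, vgrid).v[0]
            grad = force[None] + v.v / (cfg.sigma_R ** 2 * v.T)
            gmax = float(np.linalg.norm(grad, axis=-1).max())
            if gmax <= 1e-30:
                break
            accepted = False
            for _half in range(8):
                v_new = VelocityField(v.v - (step / gmax) * grad, vgrid, a)
                phi_new = integrate_flow(v_new, "forward")
                new_total, fs, fh, rg = total_of(v_new, phi_new, mf)
                if new_total <= cur_total:
                    v, phi = v_new, phi_new
                    cur_total = new_total
                    step *= 1.1
                    accepted = True
                    break
                step *= 0.5
            if not np.isfinite(cur_total):
                raise RuntimeError(
                    f"objective became non-finite (sweep {sweep}, iter {it}); "
                    f"affine={A.to_dict()}, step={step}")
            trace.append({"fidelity_st": fs, "fidelity_histo": fh,
                          "regularization": rg, "total": cur_total,
                          "sweep": sweep, "stage": "m_step"})
            if not accepted:
                break

    phi_full = integrate_flow(v, "both")
    warped, _ = warp_raster(I, A, phi_full, out_grid=J.grid)
    mf = e_step(warped, J, mf, mask)
    return v, phi_full, mf, trace


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------


def _prep_expr(ds: PointDataset, log1p: bool) -> PointDataset:
    expr = np.log1p(ds.expr) if log1p else ds.expr
    return PointDataset(ds.coords, expr, ds.gene_names, labels=ds.labels,
                        histology=ds.histology,
                        resolution_hint=ds.resolution_hint)


def _auto_dx(source: PointDataset, target: PointDataset,
             cfg: AlignConfig) -> float:
    if cfg.dx is not None:
        return cfg.dx
    allc = np.vstack([source.coords, target.coords])
    extent = float((allc.max(axis=0) - allc.min(axis=0)).max())
    return max(extent / cfg.grid_pixels, 1e-9)


def _rasterize_dataset(ds: PointDataset, genes, dx: float, sigma: float,
                       cfg: AlignConfig, use_histology: bool) -> RasterTensor:
    grid = make_grid([ds.coords], dx, pad_fraction=cfg.pad_fraction)
    st = rasterize_expression(ds, genes, grid, sigma)
    histo = None
    if use_histology and ds.histology is not None:
        sigma_h = cfg.sigma_h if cfg.sigma_h is not None else dx
        histo = rasterize_histology(ds.histology, grid, sigma_h,
                                    mode=cfg.histology_mode)
    return stack_modalities(st, histo)


def _episode_loop(I: RasterTensor, J: RasterTensor, cfg: AlignConfig,
                  channel_weights: np.ndarray) -> dict:
    """Alternate GA episodes and local refinements with monotone acceptance."""
    best = None
    P_M = None
    incumbent_A = None
    diagnostics = {"ga_traces": [], "episode_totals": []}
    for ep in range(cfg.n_episodes):
        seed = (cfg.seed * 100003 + 7919 * ep + 1) % (2 ** 31)
        if ep == 0:
            ga_cfg = replace(cfg.ga, seed=seed)
        else:
            def center(t):
                g = t.grid
                return np.array([g.origin[0] + 0.5 * (g.W - 1) * g.dx,
                                 g.origin[1] + 0.5 * (g.H - 1) * g.dx])
            ga_cfg = replace(
                narrowed_config(cfg.ga, incumbent_A, J.grid.dx,
                                center(J), center(I)),
                seed=seed)
        A, overlap, ga_trace = ga_search(I, J, ga_cfg, P_M=P_M,
                                         channel_weights=channel_weights)
        diagnostics["ga_traces"].append(ga_trace)
        if not overlap.any():
            raise RuntimeError("no feasible affine under bounds")
        v, phi, mf, trace = local_refine(I, J, A, None, cfg, mask=overlap)
        total = trace[-1]["total"] if trace else float("inf")
        diagnostics["episode_totals"].append(total)
        state = {"A": A, "v": v, "phi": phi, "mf": mf, "overlap": overlap,
                 "trace": trace, "total": total, "episode": ep}
        if best is None or total <= best["total"] * (1 + 1e-6):
            best = state
        else:
            logger.info("episode %d rejected (total %.4g > incumbent %.4g)",
                        ep, total, best["total"])
        incumbent_A = best["A"]
        P_M = best["mf"].P_M
    diagnostics["accepted_episode"] = best["episode"]
    return {"best": best, "diagnostics": diagnostics}


def _aligned_coords(A: AffineTransform, phi: DiffeoMap,
                    pts: np.ndarray) -> np.ndarray:
    """Source points → target frame via A⁻¹∘φ⁻¹ (identity-extended φ)."""
    return A.apply_inverse(phi.apply_inverse(pts))


def _snapshot(cfg: AlignConfig) -> dict:
    d = asdict(cfg)
    d["ga"] = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in d["ga"].items() if not isinstance(v, np.ndarray)}
    return d


def align(source: PointDataset, target: PointDataset,
          cfg: Optional[AlignConfig] = None) -> AlignmentResult:
    """Full coarse-to-fine alignment of ``source`` onto ``target``.

    Selects informative genes on the source, rasterizes both slices on a
    shared-frame grid pair, runs the coupled GA/LDDMM episode loop and maps
    the source point coordinates into the target frame through the inverse
    composite map.
    """
    cfg = cfg or AlignConfig()
    src = _prep_expr(source, cfg.log1p)
    tgt = _prep_expr(target, cfg.log1p)

    ranking = rank_genes(src, k=min(cfg.knn_k, src.n - 1))
    genes = shared_informative(ranking, cfg.n_genes, tgt.gene_names)
    if not genes and cfg.require_shared_genes:
        raise ValueError(
            "no informative genes shared between source and target; the "
            "total channel alone is insufficient (set require_shared_genes "
            "=False to override)")

    dx = _auto_dx(src, tgt, cfg)
    sf_src = cfg.sigma_src_factor if cfg.sigma_src_factor is not None \
        else cfg.sigma_factor
    use_h = cfg.alpha < 1.0
    I = _rasterize_dataset(src, genes, dx, sf_src * dx, cfg, use_h)
    J = _rasterize_dataset(tgt, genes, dx, cfg.sigma_factor * dx, cfg, use_h)
    if I.c != J.c:
        raise ValueError("channel mismatch between source and target rasters"
                         " (histology present on only one side?)")
    I, J = normalize_pair(I, J)

    wch = _channel_weights(J.channel_roles, cfg)
    out = _episode_loop(I, J, cfg, wch)
    best = out["best"]

    aligned = _aligned_coords(best["A"], best["phi"], source.coords)
    return AlignmentResult(
        affine=best["A"], diffeo=best["phi"], velocity=best["v"],
        match=best["mf"], match_grid=J.grid, overlap_mask=best["overlap"],
        objective_trace=best["trace"], aligned_source_coords=aligned,
        config=_snapshot(cfg),
        diagnostics={**out["diagnostics"], "genes": genes, "dx": dx},
    )


def align_st_to_histology(source_st: PointDataset, target_histo: HistologyImage,
                          cfg: Optional[AlignConfig] = None) -> AlignmentResult:
    """Cross-modality alignment: expression raster onto a histology image.

    The source is rasterized as its single total-expression channel and the
    target as the one-channel gradient-greyscale histology raster; both are
    max-normalized and enter the single-σ_M objective variant (no α split,
    no gene channels). The episode loop is otherwise identical.
    """
    cfg = cfg or AlignConfig()
    if cfg.mode != "st-histo":
        cfg = replace(cfg, mode="st-histo")
    src = _prep_expr(source_st, cfg.log1p)

    if cfg.dx is not None:
        dx = cfg.dx
    else:
        h, w = target_histo.pixels.shape[:2]
        ext_img = target_histo.scale * max(h, w)
        ext_src = float((src.coords.max(0) - src.coords.min(0)).max())
        dx = max(max(ext_img, ext_src) / cfg.grid_pixels, 1e-9)

    src_grid = make_grid([src.coords], dx, pad_fraction=cfg.pad_fraction)
    # rank-equalized intensities: raw expression mass and histology contrast
    # have incomparable profiles, so structure, not intensity, must drive
    # the squared-error objective
    I = equalize_channels(concat_modalities(
        rasterize_expression(src, [], src_grid, cfg.sigma_factor * dx)))

    xs, ys = target_histo.pixel_world_coords()
    corners = np.array([[xs[0], ys[0]], [xs[-1], ys[-1]]])
    tgt_grid = make_grid([corners], dx, pad_fraction=cfg.pad_fraction)
    sigma_h = cfg.sigma_h if cfg.sigma_h is not None else dx
    J = equalize_channels(normalize_channels(rasterize_histology(
        target_histo, tgt_grid, sigma_h, mode="gradient_grey")))

    # single st channel against single histology channel, one σ_M weight
    wch = _channel_weights(J.channel_roles, cfg)
    out = _episode_loop(I, J, cfg, wch)
    best = out["best"]
    aligned = _aligned_coords(best["A"], best["phi"], source_st.coords)
    return AlignmentResult(
        affine=best["A"], diffeo=best["phi"], velocity=best["v"],
        match=best["mf"], match_grid=J.grid, overlap_mask=best["overlap"],
        objective_trace=best["trace"], aligned_source_coords=aligned,
        config=_snapshot(cfg),
        diagnostics={**out["diagnostics"], "dx": dx, "mode": "st-histo"},
    )


def transfer_points(result: AlignmentResult, pts: np.ndarray,
                    direction: str = "source_to_target",
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Map points between frames through the fitted composite transform.

    ``source_to_target`` applies A⁻¹∘φ⁻¹; ``target_to_source`` applies φ∘A.
    Points whose φ-evaluation falls outside the deformation grid are
    returned unchanged and flagged True in the second return value.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    dm = result.diffeo
    if direction == "source_to_target":
        inside = dm.grid.contains(pts)
        mapped = result.affine.apply_inverse(dm.apply_inverse(pts))
    elif direction == "target_to_source":
        mid = result.affine.apply(pts)
        inside = dm.grid.contains(mid)
        mapped = dm.apply(mid)
    else:
        raise ValueError("direction must be source_to_target or target_to_source")
    out = np.where(inside[:, None], mapped, pts)
    return out, ~inside
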