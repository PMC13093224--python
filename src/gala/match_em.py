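"""Probabilistic matching: two-class mixture over warped-source residuals.

Within the estimated overlap region, each target pixel either matches the
warped source (residual ε_M around I(φ(A(x)))) or belongs to an unmatched
class (background, missing or artefactual tissue) with its own mean
intensity μ_N. Both classes use isotropic Gaussian kernels, so the posterior
match probability P_M has the closed form of a two-component mixture and the
nuisance parameters (μ_N, π_M, σ_M, σ_N) have weighted-moment M-step
updates. P_M then down-weights unmatched pixels in the alignment objective,
which is what makes partial-overlap alignment work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .rasterize import RasterTensor

logger = logging.getLogger("gala")

__all__ = [
    "MatchField",
    "gaussian_kernel_score",
    "e_step",
    "m_step_nuisance",
    "init_match_field",
    "em_bound",
]

PI_CLAMP = (0.05, 0.95)   # keeps either class from emptying entirely
SIGMA_FLOOR_FRAC = 1e-3   # floor on σ as a fraction of the channel scale
DENOM_FLOOR = 1e-300


@dataclass
class MatchField:
    """Per-pixel match posterior plus the mixture's scalar parameters."""

    P_M: np.ndarray
    pi_M: float
    mu_N: np.ndarray       # length-c unmatched-class mean intensity
    sigma_M: float
    sigma_N: float

    def __post_init__(self):
        self.P_M = np.asarray(self.P_M, dtype=float)
        self.mu_N = np.atleast_1d(np.asarray(self.mu_N, dtype=float))
        if np.any(self.P_M < -1e-12) or np.any(self.P_M > 1 + 1e-12):
            raise ValueError("P_M must lie in [0,1]")
        if not (0.0 < self.pi_M < 1.0):
            raise ValueError("pi_M must lie in (0,1)")
        if not (self.sigma_M > 0 and self.sigma_N > 0):
            raise ValueError("sigmas must be positive")

    @property
    def pi_N(self) -> float:
        return 1.0 - self.pi_M


def gaussian_kernel_score(J_x: np.ndarray, mu: np.ndarray, sigma: float):
    """Isotropic Gaussian kernel exp(−‖J−μ‖²/(2σ²)) ∈ (0, 1].

    Broadcasts over leading axes when J_x/mu carry a channel axis first.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    J_x = np.asarray(J_x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d2 = ((J_x - mu) ** 2).sum(axis=0) if J_x.ndim > 1 else ((J_x - mu) ** 2).sum()
    return np.exp(-d2 / (2.0 * sigma ** 2))


def e_step(I_warped: RasterTensor, J: RasterTensor, mf: MatchField,
           mask: np.ndarray) -> MatchField:
    """Posterior update: P_M on the overlap mask, 0 elsewhere.

    P_M(x) = π_M·K(J, I_w, σ_M) / (π_M·K(J, I_w, σ_M) + π_N·K(J, μ_N, σ_N)),
    with the denominator floored to avoid 0/0 in the far tails.
    """
    if I_warped.data.shape != J.data.shape:
        raise ValueError("warped source and target shapes must agree")
    d2_M = ((I_warped.data - J.data) ** 2).sum(axis=0)
    mu = mf.mu_N.reshape(-1, 1, 1)
    d2_N = ((J.data - mu) ** 2).sum(axis=0)
    K_M = np.exp(-d2_M / (2.0 * mf.sigma_M ** 2))
    K_N = np.exp(-d2_N / (2.0 * mf.sigma_N ** 2))
    num = mf.pi_M * K_M
    den = np.maximum(num + mf.pi_N * K_N, DENOM_FLOOR)
    P = np.where(mask, num / den, 0.0)
    return replace(mf, P_M=P)


def m_step_nuisance(J: RasterTensor, P_M: np.ndarray, mask: np.ndarray,
                    I_warped: Optional[RasterTensor] = None,
                    prev: Optional[MatchField] = None,
                    ) -> tuple[np.ndarray, float, float, float]:
    """Weighted-moment updates of (μ_N, π_M, σ_M, σ_N) over the mask.

    μ_N is the (1−P_M)-weighted mean of J; π_M the mean posterior (clamped);
    σ_M/σ_N are posterior-weighted residual RMS values, floored at a small
    fraction of the channel scale. Degenerate weights retain the previous
    values (logged).
    """
    if not mask.any():
        raise ValueError("empty mask")
    c = J.data.shape[0]
    Jm = J.data[:, mask]               # c × m
    P = np.clip(P_M[mask], 0.0, 1.0)   # m
    wN = 1.0 - P
    scale = max(float(np.abs(J.data).max()), 1e-12)
    floor = SIGMA_FLOOR_FRAC * scale

    if wN.sum() > 0:
        mu_N = (Jm * wN).sum(axis=1) / wN.sum()
        r2_N = ((Jm - mu_N[:, None]) ** 2).sum(axis=0)
        sigma_N = float(np.sqrt((wN * r2_N).sum() / (c * wN.sum())))
    else:
        if prev is None:
            raise ValueError("all pixels matched and no previous state")
        logger.info("unmatched class empty; retaining previous mu_N/sigma_N")
        mu_N, sigma_N = prev.mu_N, prev.sigma_N

    pi_M = float(np.clip(P.mean(), *PI_CLAMP))

    if I_warped is not None and P.sum() > 0:
        r2_M = ((I_warped.data[:, mask] - Jm) ** 2).sum(axis=0)
        sigma_M = float(np.sqrt((P * r2_M).sum() / (c * P.sum())))
    elif prev is not None:
        sigma_M = prev.sigma_M
    else:
        sigma_M = floor
    return mu_N, pi_M, max(sigma_M, floor), max(sigma_N, floor)


def init_match_field(J: RasterTensor, I_warped: RasterTensor,
                     mask: np.ndarray, pi_M: float = 0.7) -> MatchField:
    """Initial mixture state before the first E-step.

    The two classes are seeded from the residual distribution under the
    current (affine-only) warp so the EM starts in the intended basin:
    σ_M from the well-fitting half of the pixels, σ_N from the poorly
    fitting half, and μ_N from the mean target intensity of the worst
    quartile (the evidently unmatched areas). With full overlap the two
    halves coincide and the split is harmless.
    """
    c = J.data.shape[0]
    scale = max(float(np.abs(J.data).max()), 1e-12)
    floor = SIGMA_FLOOR_FRAC * scale
    if mask.any():
        r2 = ((I_warped.data - J.data) ** 2).sum(axis=0)[mask]
        med = np.quantile(r2, 0.5)
        good = r2 <= med
        sigma_M = float(np.sqrt(max(r2[good].mean(), 0.0) / c))
        sigma_N = float(np.sqrt(max(r2[~good].mean() if (~good).any()
                                    else r2.mean(), 0.0) / c))
        worst = r2 >= np.quantile(r2, 0.75)
        Jm = J.data[:, mask]
        mu_N = Jm[:, worst].mean(axis=1) if worst.any() else Jm.mean(axis=1)
    else:
        sigma_M = sigma_N = 1.0
        mu_N = J.data.reshape(c, -1).mean(axis=1)
    P = np.where(mask, pi_M, 0.0)
    return MatchField(P, pi_M, mu_N, max(sigma_M, floor),
                      max(sigma_N, floor))


def em_bound(I_warped: RasterTensor, J: RasterTensor, mf: MatchField,
             mask: np.ndarray) -> float:
    """Variational functional the E-step and μ_N/π_M updates descend.

    Σ_x P·(‖r_M‖²/2σ_M² − log π_M) + (1−P)·(‖r_N‖²/2σ_N² − log π_N)
      + P·log P + (1−P)·log(1−P)

    (fidelity + prior + entropy). The posterior formula with *unnormalized*
    kernels is the exact minimizer of this functional over P at fixed
    parameters, and the μ_N / π_M updates are its exact minimizers at fixed
    P, so alternating them is monotone. The σ refresh is a residual-scale
    recalibration that sits outside this functional (it would need the
    Gaussian normalizers, which the kernel form deliberately drops).
    """
    r2_M = ((I_warped.data - J.data) ** 2).sum(axis=0)[mask]
    mu = mf.mu_N.reshape(-1, 1, 1)
    r2_N = ((J.data - mu) ** 2).sum(axis=0)[mask]
    P = np.clip(mf.P_M[mask], 1e-12, 1 - 1e-12)
    term_M = P * (r2_M / (2 * mf.sigma_M ** 2) - np.log(mf.pi_M))
    term_N = (1 - P) * (r2_N / (2 * mf.sigma_N ** 2) - np.log(mf.pi_N))
    ent = P * np.log(P) + (1 - P) * np.log(1 - P)
    return float((term_M + term_N + ent).sum())
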