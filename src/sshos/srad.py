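"""Speckle-reducing anisotropic diffusion (SRAD).

An iterative PDE filter for multiplicative (speckle) noise: the local
instantaneous coefficient of variation (ICOV) — a normalized
gradient/Laplacian detector — distinguishes edges from speckle, and a
diffusion coefficient close to 1 in homogeneous regions and close to 0
at edges drives a 4-neighbor divergence update.  The speckle scale q0
is re-estimated every iteration from a homogeneous reference region,
so the filter relaxes as the speckle is progressively removed.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import SRADConfig
from .io import GrayImage

log = logging.getLogger(__name__)


class DivergenceError(FloatingPointError):
    """SRAD iteration produced non-finite values (time step too large)."""


def _shifts(I: np.ndarray):
    # neighbors with symmetric (zero-flux) boundary
    n = np.vstack([I[:1, :], I[:-1, :]])
    s = np.vstack([I[1:, :], I[-1:, :]])
    w = np.hstack([I[:, :1], I[:, :-1]])
    e = np.hstack([I[:, 1:], I[:, -1:]])
    return n, s, w, e


def icov(img: GrayImage | np.ndarray, h: float = 1.0, eps: float = 1e-8) -> np.ndarray:
    """Instantaneous coefficient of variation.

    q = sqrt( max(0, (|grad I / I|^2 / 2 - (lap I / I)^2 / 16)
                     / (1 + (lap I / I) / 4)^2 ) )

    with |grad I|^2 the average of squared right- and left-sided
    differences, a 4-neighbor Laplacian, and symmetric boundaries.
    The image is shifted by ``eps`` so division is always defined.
    """
    I = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    I = I + eps
    n, s, w, e = _shifts(I)
    grad_r2 = ((s - I) ** 2 + (e - I) ** 2) / h**2  # right/forward
    grad_l2 = ((I - n) ** 2 + (I - w) ** 2) / h**2  # left/backward
    grad2 = 0.5 * (grad_r2 + grad_l2)
    lap = (n + s + w + e - 4.0 * I) / h**2
    g = grad2 / I**2
    l = lap / I
    num = 0.5 * g - (1.0 / 16.0) * l**2
    den = (1.0 + 0.25 * l) ** 2
    q2 = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
    return np.sqrt(np.maximum(q2, 0.0))


def speckle_scale(img: GrayImage | np.ndarray, region: tuple[int, int, int, int]) -> float:
    """q0 = std/mean of the intensities in a rectangular region.

    ``region`` is (row0, col0, row1, col1), half-open.
    """
    I = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    r0, c0, r1, c1 = region
    patch = I[r0:r1, c0:c1]
    if patch.size < 4:
        raise ValueError("q0 region must contain at least 4 pixels")
    m = patch.mean()
    if m == 0:
        raise ValueError("q0 region has zero mean")
    if patch.max() == patch.min():  # constant: sd is 0 up to rounding
        return 0.0
    return float(patch.std() / m)


def diffusion_coeff(q: np.ndarray, q0: float, c_cap: float = 1e6) -> np.ndarray:
    """C(q) = 1 / (1 + (q^2 - q0^2) / (q0^2 (1 + q0^2))), clamped to (0, c_cap].

    C = 1 where q = q0; with no reliable speckle estimate (q0 = 0) the
    coefficient degenerates and all-ones is returned (plain diffusion).
    """
    if q0 < 0:
        raise ValueError("q0 must be >= 0")
    if q0 == 0.0:
        log.warning("q0 = 0: no speckle estimate, using C = 1 everywhere")
        return np.ones_like(np.asarray(q, float))
    q = np.asarray(q, dtype=np.float64)
    denom = 1.0 + (q**2 - q0**2) / (q0**2 * (1.0 + q0**2))
    tiny = 1.0 / c_cap
    C = 1.0 / np.maximum(denom, tiny)
    return np.clip(C, tiny, c_cap)


def auto_q0_region(img: GrayImage | np.ndarray, block: int = 11) -> tuple[int, int, int, int]:
    """The block x block tile of minimal intensity variance (homogeneous
    reference for q0)."""
    I = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    H, W = I.shape
    nr, nc = H // block, W // block
    if nr < 1 or nc < 1:
        return (0, 0, H, W)
    tiles = I[: nr * block, : nc * block].reshape(nr, block, nc, block)
    var = tiles.transpose(0, 2, 1, 3).reshape(nr, nc, -1).var(axis=2)
    r, c = np.unravel_index(np.argmin(var), var.shape)
    return (r * block, c * block, (r + 1) * block, (c + 1) * block)


def srad_filter(
    img: GrayImage | np.ndarray, cfg: SRADConfig | None = None
) -> GrayImage:
    """Run SRAD for ``cfg.n_iter`` iterations.

    Each iteration: ICOV, q0 from the reference region, diffusion
    coefficient, then I <- I + (dt/4) * div(C grad I) with the standard
    4-neighbor discretization and zero-flux boundaries.  Output clipped
    to [0, 1].
    """
    cfg = cfg or SRADConfig()
    I = (img.values if isinstance(img, GrayImage) else np.asarray(img, float)).copy()
    region = cfg.q0_region
    if region == "auto":
        region = auto_q0_region(I)
    for _ in range(cfg.n_iter):
        q = icov(I, h=cfg.h, eps=cfg.eps)
        r0, c0, r1, c1 = region
        patch = I[r0:r1, c0:c1]
        m = patch.mean()
        q0 = float(patch.std() / m) if m > 0 else 0.0
        C = diffusion_coeff(q, q0)
        n, s, w, e = _shifts(I)
        cs = np.vstack([C[1:, :], C[-1:, :]])
        ce = np.hstack([C[:, 1:], C[:, -1:]])
        div = (
            cs * (s - I) - C * (I - n) + ce * (e - I) - C * (I - w)
        ) / cfg.h**2
        I = I + (cfg.dt / 4.0) * div
        if not np.all(np.isfinite(I)):
            raise DivergenceError("SRAD diverged; reduce the time step")
    return GrayImage(np.clip(I, 0.0, 1.0))


__all__ = [
    "DivergenceError",
    "icov",
    "speckle_scale",
    "diffusion_coeff",
    "auto_q0_region",
    "srad_filter",
]
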