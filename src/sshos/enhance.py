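"""Neutrosophic-domain contrast enhancement and unsharp sharpening.

The enhancement maps intensities through a piecewise-quadratic
S-function whose breakpoints (a, b, c) are estimated from histogram
peaks: a and c bracket the informative intensity range, and b is
chosen by exhaustive search to maximize the mean binary Shannon
entropy of the mapped image (maximum-entropy principle).  The mapped
image is then pushed away from mid-gray by the classic intensification
transform and finally unsharp-masked.

The neutrosophic decomposition (truth / indeterminacy / falsity
channels derived from the local mean and the deviation from it) is
computed as a diagnostic; the S-function path operates on the
mean-filtered image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import GrayImage

log = logging.getLogger(__name__)


class EstimationError(ValueError):
    """Histogram peak structure too weak to estimate (a, b, c)."""


class DegenerateImageError(ValueError):
    """Image has no usable intensity range (e.g. constant)."""


@dataclass(frozen=True)
class NeutrosophicImage:
    """Truth/indeterminacy/falsity channels of an image.

    T is the min-max normalized local mean, I the normalized absolute
    deviation from the local mean, and F = 1 - T.
    """

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    local_mean: np.ndarray
    delta: np.ndarray


@dataclass
class SFunctionParams:
    """Breakpoints and histogram diagnostics of the S-function.

    Levels are on the 0..255 axis.  ``b`` is filled in by
    :func:`optimal_b`; ``peak_levels``/``peak_heights`` list all local
    maxima of the smoothed histogram, of which those higher than
    ``peak_mean`` qualify as true peaks (the first and last qualifying
    peaks are ``g_min``/``g_max``).
    """

    a: float
    c: float
    g_min: int
    g_max: int
    B1: int
    B2: int
    peak_levels: np.ndarray
    peak_heights: np.ndarray
    peak_mean: float
    b: int | None = None
    fallback: bool = False


def local_mean(img: GrayImage | np.ndarray, w: int) -> np.ndarray:
    """w x w arithmetic mean with symmetric (reflective) padding."""
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    if w % 2 == 0 or w < 3:
        raise ValueError(f"window must be odd and >= 3, got {w}")
    if w > 2 * max(values.shape):
        raise ValueError("window larger than twice the image")
    return ndimage.uniform_filter(values, size=w, mode="reflect")


def neutrosophic_components(img: GrayImage | np.ndarray, w: int = 5) -> NeutrosophicImage:
    """Transform an image into the neutrosophic (T, I, F) domain.

    T normalizes the local mean over its full range, I normalizes the
    absolute deviation |q - local_mean| over its range, and F = 1 - T.
    Raises :class:`DegenerateImageError` when either range collapses.
    """
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    qhat = local_mean(values, w)
    lo, hi = qhat.min(), qhat.max()
    if hi <= lo:
        raise DegenerateImageError("local mean has no range; image is constant")
    T = (qhat - lo) / (hi - lo)
    delta = np.abs(values - qhat)
    dlo, dhi = delta.min(), delta.max()
    if dhi <= dlo:
        raise DegenerateImageError("deviation from local mean has no range")
    I = (delta - dlo) / (dhi - dlo)
    return NeutrosophicImage(T=T, I=I, F=1.0 - T, local_mean=qhat, delta=delta)


def s_function(g, a: float, b: float, c: float):
    """Piecewise-quadratic sigmoid: 0 below a, 1 above c, quadratic knees.

    Continuous at a, b, c; monotone non-decreasing for a < b < c.
    """
    if not (a < b < c):
        raise ValueError(f"require a < b < c, got ({a}, {b}, {c})")
    g = np.asarray(g, dtype=np.float64)
    out = np.empty_like(g)
    lower = g <= b
    out[lower] = (np.maximum(g[lower] - a, 0.0) ** 2) / ((b - a) * (c - a))
    upper = ~lower
    out[upper] = 1.0 - (np.minimum(g[upper] - c, 0.0) ** 2) / ((c - b) * (c - a))
    return out if out.ndim else float(out)


def _binary_entropy(t: np.ndarray) -> np.ndarray:
    # Shannon function with 0 log 0 = 0
    t = np.clip(t, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -t * np.log2(t) - (1.0 - t) * np.log2(1.0 - t)
    return np.nan_to_num(h, nan=0.0, posinf=0.0, neginf=0.0)


def map_entropy(T: np.ndarray) -> float:
    """Mean binary Shannon entropy (bits) of a [0, 1] map."""
    T = np.asarray(T, dtype=np.float64)
    if T.min() < 0 or T.max() > 1:
        raise ValueError("map values must lie in [0, 1]")
    return float(_binary_entropy(T).mean())


def estimate_abc(
    img: GrayImage | np.ndarray, f1: float = 0.01, f2: float = 0.01
) -> SFunctionParams:
    """Estimate S-function breakpoints a and c from histogram peaks.

    Procedure: 256-bin histogram of the rounded 0..255 levels; local
    maxima (bins strictly above both neighbors) are located and those
    higher than the mean peak height qualify; the first/last qualifying
    peaks fix g_min/g_max.  Spurious single-bin maxima need no separate
    suppression: they dilute the mean height and never qualify.  The tail
    limits B1/B2 each allow a fraction f1 of total pixels to be lost,
    and a/c are placed a fraction f2 of the way from the extreme local
    maxima toward g_min/g_max, clamped into [.., B1] / [.., B2].

    Raises :class:`EstimationError` with fewer than two qualifying
    peaks (e.g. a unimodal histogram).
    """
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    levels = np.rint(np.clip(values, 0.0, 1.0) * 255).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    interior = np.arange(1, 255)
    is_max = (hist[interior] > hist[interior - 1]) & (
        hist[interior] > hist[interior + 1]
    )
    peak_levels = interior[is_max]
    peak_heights = hist[peak_levels]
    if peak_levels.size == 0:
        raise EstimationError("histogram has no interior local maxima")
    peak_mean = float(peak_heights.mean())
    qualifying = peak_levels[peak_heights > peak_mean]
    if qualifying.size < 2:
        raise EstimationError(
            f"need >= 2 peaks above the mean peak height, found {qualifying.size}"
        )
    g_min, g_max = int(qualifying[0]), int(qualifying[-1])
    total = levels.size
    # tail limits: allow f1 of total pixels beyond each limit
    cum = np.cumsum(hist[g_min : g_max + 1])
    need = f1 * total
    b1_off = int(np.searchsorted(cum, need))
    B1 = min(g_min + b1_off, g_max)
    cum_rev = np.cumsum(hist[g_min : g_max + 1][::-1])
    b2_off = int(np.searchsorted(cum_rev, need))
    B2 = max(g_max - b2_off, g_min)
    g1, gn = int(peak_levels[0]), int(peak_levels[-1])
    a = (1.0 - f2) * (g1 - g_min) + g_min
    if a > B1:
        a = float(B1)
    c = f2 * (g_max - gn) + gn
    if c > B2:
        c = float(B2)
    return SFunctionParams(
        a=float(a),
        c=float(c),
        g_min=g_min,
        g_max=g_max,
        B1=int(B1),
        B2=int(B2),
        peak_levels=peak_levels,
        peak_heights=peak_heights,
        peak_mean=peak_mean,
    )


def optimal_b(g: np.ndarray, a: float, c: float) -> int:
    """Exhaustive scan of integer b maximizing the mapped-image entropy.

    ``g`` is the (mean-filtered) image on the 0..255 level axis.  Ties
    break toward the smallest b.
    """
    lo = int(np.floor(a)) + 1
    hi = int(np.ceil(c)) - 1
    if lo > hi:
        raise ValueError(f"empty b search interval [{lo}, {hi}]")
    g = np.asarray(g, dtype=np.float64)
    best_b, best_h = lo, -np.inf
    for b in range(lo, hi + 1):
        h = map_entropy(s_function(g, a, b, c))
        if h > best_h:
            best_b, best_h = b, h
    return best_b


def intensify(T: np.ndarray) -> np.ndarray:
    """Contrast intensification: 2T^2 below 0.5, 1 - 2(1-T)^2 above.

    Monotone, fixes 0, 0.5 and 1.
    """
    T = np.asarray(T, dtype=np.float64)
    if T.min() < 0 or T.max() > 1:
        raise ValueError("map values must lie in [0, 1]")
    return np.where(T <= 0.5, 2.0 * T**2, 1.0 - 2.0 * (1.0 - T) ** 2)


def unsharp_sharpen(
    img: GrayImage | np.ndarray, radius: float = 2.0, amount: float = 1.0
) -> np.ndarray:
    """out = clip(img + amount * (img - gaussian_blur(img, radius)), 0, 1)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    blurred = ndimage.gaussian_filter(values, sigma=radius, mode="reflect")
    return np.clip(values + amount * (values - blurred), 0.0, 1.0)


def enhance(img: GrayImage, cfg=None) -> tuple[GrayImage, dict]:
    """Full enhancement: mean filter, S-function with estimated (a, b, c),
    intensification, unsharp mask.

    Returns the enhanced image and a diagnostics dict (a, b, c, B1, B2,
    entropy H of the chosen map, fallback flag).  When peak estimation
    fails, (a, c) fall back to the 1st/99th intensity percentiles; a
    constant image is returned unchanged.
    """
    from .config import PipelineConfig

    cfg = cfg or PipelineConfig()
    filtered = local_mean(img, cfg.mean_filter_window)
    g = filtered * 255.0
    fallback = False
    try:
        params = estimate_abc(filtered, cfg.tail_loss_f1, cfg.tail_loss_f2)
        a, c = params.a, params.c
    except EstimationError as exc:
        a, c = np.percentile(g, (1.0, 99.0))
        fallback = True
        params = None
        log.warning("peak estimation failed (%s); percentile fallback a=%.1f c=%.1f",
                    exc, a, c)
    if np.floor(a) + 1 > np.ceil(c) - 1:
        log.warning("degenerate intensity range (a=%.1f, c=%.1f); image unchanged", a, c)
        return img, {"a": a, "b": None, "c": c, "H": None, "fallback": True,
                     "params": params}
    b = optimal_b(g, a, c)
    T = s_function(g, a, b, c)
    H = map_entropy(T)
    E = intensify(T)
    out = unsharp_sharpen(E, cfg.unsharp_radius, cfg.unsharp_amount)
    diag = {"a": a, "b": b, "c": c, "H": H, "fallback": fallback, "params": params}
    if params is not None:
        diag.update({"B1": params.B1, "B2": params.B2,
                     "g_min": params.g_min, "g_max": params.g_max})
        params.b = b
        params.fallback = fallback
    return GrayImage(out), diag


__all__ = [
    "EstimationError",
    "DegenerateImageError",
    "NeutrosophicImage",
    "SFunctionParams",
    "local_mean",
    "neutrosophic_components",
    "s_function",
    "estimate_abc",
    "map_entropy",
    "optimal_b",
    "intensify",
    "unsharp_sharpen",
    "enhance",
]
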