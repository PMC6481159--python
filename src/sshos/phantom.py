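"""Synthetic speckled phantoms with ground-truth lesion masks.

A phantom is a piecewise-constant scene (background plus elliptical
lesions) degraded by fully developed multiplicative speckle, modelled
as per-pixel Gamma noise with unit mean and shape ``L`` (the number of
looks).  For an L-look region the point SNR (mean over standard
deviation) is sqrt(L), which is what real B-mode envelope statistics
give after incoherent averaging of L looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GrayImage


@dataclass(frozen=True)
class Lesion:
    """An elliptical lesion: center (row, col), semi-axes in pixels,
    rotation in degrees (counter-clockwise), and its echo level."""

    center_row: float
    center_col: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float = 0.0
    level: float = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    background_level: float = 0.65
    lesions: tuple[Lesion, ...] = field(
        default_factory=lambda: (Lesion(128.0, 128.0, 28.0, 40.0, 20.0, 0.25),)
    )
    speckle_looks: float = 4.0
    additive_noise_sigma: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.background_level <= 1.0):
            raise ValueError("background_level must be in (0, 1]")
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")
        for les in self.lesions:
            if les.level == self.background_level:
                raise ValueError("lesion level must differ from background")
            if les.semi_axis_a <= 0 or les.semi_axis_b <= 0:
                raise ValueError("lesion semi-axes must be positive")


def _ellipse_mask(spec: PhantomSpec, les: Lesion) -> np.ndarray:
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    dr = rows - les.center_row
    dc = cols - les.center_col
    th = np.deg2rad(les.rotation_deg)
    # rotate into the ellipse frame; pixel belongs iff its center satisfies
    # the ellipse inequality
    u = dc * np.cos(th) + dr * np.sin(th)
    v = -dc * np.sin(th) + dr * np.cos(th)
    return (u / les.semi_axis_a) ** 2 + (v / les.semi_axis_b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a phantom and its ground-truth lesion mask.

    Returns ``(image, mask)`` where the image is the noise-free scene
    multiplied by unit-mean Gamma speckle (shape ``speckle_looks``),
    optionally plus Gaussian noise, clipped to [0, 1]; the mask is the
    union of the rasterized lesion ellipses.

    Raises if any lesion leaves the image or two lesions overlap
    (overlap would make the ground truth ambiguous).
    """
    scene = np.full((spec.height, spec.width), spec.background_level)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    for les in spec.lesions:
        ell = _ellipse_mask(spec, les)
        edge = np.zeros_like(ell)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        if (ell & edge).any() or not ell.any():
            raise ValueError("lesion does not fit inside the image")
        if (mask.astype(bool) & ell).any():
            raise ValueError("lesions overlap; ground truth would be ambiguous")
        scene[ell] = les.level
        mask[ell] = 1
    rng = np.random.default_rng(spec.random_seed)
    L = spec.speckle_looks
    speckle = rng.gamma(shape=L, scale=1.0 / L, size=scene.shape)
    noisy = scene * speckle
    if spec.additive_noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.additive_noise_sigma, scene.shape)
    return GrayImage(np.clip(noisy, 0.0, 1.0)), mask


def noise_free_scene(spec: PhantomSpec) -> np.ndarray:
    """The piecewise-constant scene before speckle (for tests)."""
    scene = np.full((spec.height, spec.width), spec.background_level)
    for les in spec.lesions:
        scene[_ellipse_mask(spec, les)] = les.level
    return scene


def speckle_snr(img: GrayImage | np.ndarray, region: np.ndarray) -> float:
    """Point SNR mean/std inside ``region``; +inf for a constant region."""
    values = img.values if isinstance(img, GrayImage) else np.asarray(img)
    sel = np.asarray(region).astype(bool)
    if not sel.any():
        raise ValueError("empty region")
    x = values[sel]
    if x.max() == x.min():  # constant region: sd is 0 up to rounding
        return float("inf")
    return float(x.mean() / x.std())


__all__ = ["Lesion", "PhantomSpec", "make_phantom", "noise_free_scene", "speckle_snr"]
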