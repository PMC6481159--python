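"""Segmentation evaluation: area overlap and boundary distance.

With A the automatic mask and G the ground truth, TP and FP are the
fractions of A inside and outside G (so TP + FP = 100 for non-empty
A), DC is the Dice coefficient and SI the Jaccard similarity index,
all in percent.  HD is the Hausdorff distance in pixels between the
two boundary point sets (mask pixels with a background 4-neighbor),
Euclidean, classically the max of the two directed distances; a
mean-of-nearest-distances variant is also available since reported
sub-pixel values in the literature often correspond to it.

Note: the similarity index SI is defined here as the Jaccard index,
the standard overlap measure distinct from Dice.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class MetricsReport:
    """Area metrics in percent, Hausdorff distance in pixels."""

    TP: float
    FP: float
    DC: float
    SI: float
    HD: float

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "DC": self.DC,
                "SI": self.SI, "HD": self.HD}


def area_metrics(auto: np.ndarray, gt: np.ndarray) -> tuple[float, float, float, float]:
    """(TP, FP, DC, SI) in percent.

    TP = 100 |A∩G| / |A|, FP = 100 |A\\G| / |A| (complementary by
    construction), DC = 100 * 2|A∩G| / (|A| + |G|), SI = Jaccard.
    An empty automatic mask reports TP 0 / FP 100 with a warning.
    """
    A = np.asarray(auto).astype(bool)
    G = np.asarray(gt).astype(bool)
    if A.shape != G.shape:
        raise ValueError("mask shapes differ")
    if not G.any():
        raise ValueError("ground-truth mask is empty")
    n_a = int(A.sum())
    n_g = int(G.sum())
    n_int = int((A & G).sum())
    n_union = int((A | G).sum())
    if n_a == 0:
        warnings.warn("empty automatic mask: TP/FP undefined, reporting 0/100")
        tp, fp = 0.0, 100.0
    else:
        tp = 100.0 * n_int / n_a
        fp = 100.0 * (n_a - n_int) / n_a
    dc = 100.0 * 2.0 * n_int / (n_a + n_g)
    si = 100.0 * n_int / n_union
    return tp, fp, dc, si


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of mask pixels with >= 1 background 4-neighbor."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(m & ~eroded)


def hausdorff(auto: np.ndarray, gt: np.ndarray, mode: str = "max") -> float:
    """Hausdorff distance between boundary point sets, in pixels.

    ``mode="max"`` is the classical symmetric Hausdorff distance;
    ``mode="mean"`` averages the nearest-point distances of both sets.
    """
    pa = boundary_points(auto)
    pg = boundary_points(gt)
    if pa.size == 0 or pg.size == 0:
        raise ValueError("mask has no boundary (empty mask)")
    d_ag = cKDTree(pg).query(pa)[0]
    d_ga = cKDTree(pa).query(pg)[0]
    if mode == "max":
        return float(max(d_ag.max(), d_ga.max()))
    if mode == "mean":
        return float(np.concatenate([d_ag, d_ga]).mean())
    raise ValueError("mode must be 'max' or 'mean'")


def evaluate(auto: np.ndarray, gt: np.ndarray, hd_mode: str = "max") -> MetricsReport:
    """Full report versus a ground-truth mask."""
    tp, fp, dc, si = area_metrics(auto, gt)
    hd = hausdorff(auto, gt, mode=hd_mode)
    return MetricsReport(TP=tp, FP=fp, DC=dc, SI=si, HD=hd)


__all__ = ["MetricsReport", "area_metrics", "boundary_points", "hausdorff", "evaluate"]
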