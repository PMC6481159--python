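"""The end-to-end SSHOS pipeline.

enhance -> sharpen -> SRAD despeckle -> block entropy features ->
seed selection -> seeded region growing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .enhance import DegenerateImageError, enhance
from .grow import GrowResult, region_growing
from .hose import BlockGrid, block_entropy_table, partition_blocks
from .io import GrayImage
from .seed import SeedPoint, select_seed
from .srad import srad_filter


@dataclass
class PipelineDiagnostics:
    """Intermediate products of a pipeline run."""

    enhanced: GrayImage | None = None
    despeckled: GrayImage | None = None
    grid: BlockGrid | None = None
    entropy_table: pd.DataFrame | None = None
    candidates: list[int] = field(default_factory=list)
    ssim_sums: dict[int, float] = field(default_factory=dict)
    ev_lengths: pd.Series | None = None
    enhance_info: dict = field(default_factory=dict)
    seed: SeedPoint | None = None


def run_pipeline(
    img: GrayImage,
    cfg: PipelineConfig | None = None,
    seed_override: tuple[int, int] | None = None,
) -> tuple[SeedPoint, GrowResult, PipelineDiagnostics]:
    """Run the full pipeline on one image.

    Deterministic: the same image and config always produce the same
    seed and mask.  Raises on images smaller than a 2 x 2 block grid
    or with no intensity range at all.
    """
    cfg = cfg or PipelineConfig()
    H, W = img.shape
    s = cfg.block_size
    if H < 2 * s or W < 2 * s:
        raise ValueError(
            f"image {H}x{W} too small for a 2x2 grid of {s}x{s} blocks"
        )
    if img.values.max() == img.values.min():
        raise DegenerateImageError("constant image: nothing to segment")

    diag = PipelineDiagnostics()
    enhanced, diag.enhance_info = enhance(img, cfg)
    diag.enhanced = enhanced
    despeckled = srad_filter(enhanced, cfg.srad)
    diag.despeckled = despeckled
    grid = partition_blocks(despeckled, s)
    diag.grid = grid
    table = block_entropy_table(
        grid, angles=cfg.angles, n_fft=cfg.fft_length, phase_bins=cfg.phase_bins
    )
    diag.entropy_table = table
    if seed_override is not None:
        seed = SeedPoint(row=seed_override[0], col=seed_override[1], block_index=0)
    else:
        seed, seed_diag = select_seed(table, grid)
        diag.candidates = seed_diag["candidates"]
        diag.ssim_sums = seed_diag["ssim_sums"]
        diag.ev_lengths = seed_diag["ev_lengths"]
    diag.seed = seed
    result = region_growing(
        despeckled,
        seed,
        tau=cfg.region_grow_threshold,
        connectivity=cfg.connectivity,
    )
    return seed, result, diag


__all__ = ["PipelineDiagnostics", "run_pipeline"]
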