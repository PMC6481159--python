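"""Automatic seed selection from block entropy features.

For every block an entropy vector E_v collects the features that fall
within [across-block mean, across-block max] of their column; the
block(s) with the longest E_v are the candidates.  Ties are broken by
the sum of whole-block SSIM against the 4-neighbor blocks (a
homogeneous lesion block resembles its neighbors), then by lowest
linear index.  The winning block's center pixel is the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hose import BlockGrid, block_center, feature_columns


@dataclass(frozen=True)
class SeedPoint:
    """1-based pixel coordinates of the selected seed and its block."""

    row: int
    col: int
    block_index: int


def ev_length(features: np.ndarray, means: np.ndarray, maxes: np.ndarray) -> int:
    """Number of features lying in [column mean, column max], inclusive."""
    features = np.asarray(features, float)
    if features.shape != np.shape(means) or features.shape != np.shape(maxes):
        raise ValueError("feature/threshold lengths differ")
    return int(((features >= means) & (features <= maxes)).sum())


def ev_lengths(table: pd.DataFrame) -> pd.Series:
    """E_v length per block for a block entropy table."""
    cols = feature_columns(table)
    feats = table[cols].to_numpy()
    means = feats.mean(axis=0)
    maxes = feats.max(axis=0)
    lengths = ((feats >= means) & (feats <= maxes)).sum(axis=1)
    return pd.Series(lengths, index=table.index, name="ev_length")


def candidate_blocks(table: pd.DataFrame) -> list[int]:
    """Block indices achieving the maximal E_v length, ascending."""
    if len(table) == 0:
        raise ValueError("empty entropy table")
    lengths = ev_lengths(table)
    return sorted(lengths.index[lengths == lengths.max()].tolist())


def block_ssim(A: np.ndarray, B: np.ndarray, data_range: float = 1.0) -> float:
    """Single-window SSIM over two whole blocks.

    ((2 mu_A mu_B + C1)(2 cov + C2)) / ((mu_A^2 + mu_B^2 + C1)
    (var_A + var_B + C2)) with C1 = (0.01 L)^2, C2 = (0.03 L)^2.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("blocks must have the same shape")
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    mu_a, mu_b = A.mean(), B.mean()
    var_a, var_b = A.var(), B.var()
    cov = ((A - mu_a) * (B - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + C1) * (2 * cov + C2)
        / ((mu_a**2 + mu_b**2 + C1) * (var_a + var_b + C2))
    )


def neighbor_ssim_sum(grid: BlockGrid, index: int) -> float:
    """Sum of SSIM between a block and its existing 4-neighbors.

    Neighbors missing at the grid border contribute 0.
    """
    r, c = grid.position(index)
    me = grid.block(r, c)
    total = 0.0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 1 <= rr <= grid.n_rows and 1 <= cc <= grid.n_cols:
            total += block_ssim(me, grid.block(rr, cc))
    return total


def select_seed(
    table: pd.DataFrame, grid: BlockGrid
) -> tuple[SeedPoint, dict]:
    """Pick the seed block and return its center pixel.

    Returns the seed and a diagnostics dict with the candidate list,
    their SSIM sums (when the tiebreak ran) and E_v lengths.
    """
    candidates = candidate_blocks(table)
    ssim_sums: dict[int, float] = {}
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        ssim_sums = {i: neighbor_ssim_sum(grid, i) for i in candidates}
        best = max(ssim_sums.values())
        winner = min(i for i, v in ssim_sums.items() if v == best)
    r, c = grid.position(winner)
    row, col = block_center(r, c, grid.block_size)
    seed = SeedPoint(row=row, col=col, block_index=winner)
    diag = {
        "candidates": candidates,
        "ssim_sums": ssim_sums,
        "ev_lengths": ev_lengths(table),
    }
    return seed, diag


__all__ = [
    "SeedPoint",
    "ev_length",
    "ev_lengths",
    "candidate_blocks",
    "block_ssim",
    "neighbor_ssim_sum",
    "select_seed",
]
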