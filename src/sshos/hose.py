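"""Block-wise Radon projections, bispectra and higher-order-spectra
entropies (HOSE).

The image is tiled into non-overlapping square blocks (11 x 11 by
default, 1-based row-major indexing).  Each block is projected onto a
set of angles by a discrete Radon transform; each projection's
bispectrum B(k1, k2) = R(k1) R(k2) conj(R(k1+k2)) is evaluated on the
principal (non-redundant) triangle Omega = {0 <= k2 <= k1,
k1 + k2 <= N/2}, and four Shannon entropies are extracted: the phase
entropy and the entropies of the normalized |B|, |B|^2 and |B|^3
distributions.  Homogeneous, noise-like blocks spread bispectral mass
broadly (high entropy); structured blocks concentrate it (low
entropy) — the contrast the seed selector exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import GrayImage


@dataclass(frozen=True)
class BlockGrid:
    """An image partitioned into s x s non-overlapping blocks.

    Block positions (r, c) are 1-based; the linear index of (r, c) is
    (r-1) * n_cols + c, row-major.  Right/bottom remainders of the
    image that do not fill a block are dropped.
    """

    block_size: int
    n_rows: int
    n_cols: int
    blocks: np.ndarray  # (n_rows, n_cols, s, s)

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def block(self, r: int, c: int) -> np.ndarray:
        self._check(r, c)
        return self.blocks[r - 1, c - 1]

    def block_by_index(self, index: int) -> np.ndarray:
        r, c = self.position(index)
        return self.blocks[r - 1, c - 1]

    def position(self, index: int) -> tuple[int, int]:
        """1-based (row, col) of a 1-based linear block index."""
        if not (1 <= index <= self.n_blocks):
            raise IndexError(f"block index {index} outside 1..{self.n_blocks}")
        return ((index - 1) // self.n_cols + 1, (index - 1) % self.n_cols + 1)

    def _check(self, r: int, c: int) -> None:
        if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
            raise IndexError(f"block position ({r}, {c}) outside grid "
                             f"{self.n_rows}x{self.n_cols}")


def partition_blocks(img: GrayImage | np.ndarray, s: int = 11) -> BlockGrid:
    """Tile the image into s x s blocks, dropping partial margins."""
    values = img.values if isinstance(img, GrayImage) else np.asarray(img, float)
    H, W = values.shape
    nr, nc = H // s, W // s
    if nr < 1 or nc < 1:
        raise ValueError(f"image {H}x{W} smaller than one {s}x{s} block")
    tiles = values[: nr * s, : nc * s].reshape(nr, s, nc, s).transpose(0, 2, 1, 3)
    return BlockGrid(block_size=s, n_rows=nr, n_cols=nc, blocks=tiles)


def block_index(r: int, c: int, grid: BlockGrid) -> int:
    """1-based row-major linear index of block position (r, c)."""
    grid._check(r, c)
    return (r - 1) * grid.n_cols + c


def block_center(r: int, c: int, s: int = 11) -> tuple[int, int]:
    """1-based pixel coordinates of the center of block (r, c)."""
    if s % 2 == 0:
        raise ValueError("block size must be odd to have a center pixel")
    return ((r - 1) * s + (s + 1) // 2, (c - 1) * s + (s + 1) // 2)


def _projection_length(s: int) -> int:
    n = int(np.ceil(s * np.sqrt(2.0)))
    return n if n % 2 else n + 1


@lru_cache(maxsize=64)
def _splat_matrix(s: int, theta: float) -> np.ndarray:
    """(n_offsets, s*s) matrix mapping a raveled block to its projection.

    Pixel-driven linear splatting: pixel (row, col) at centered
    coordinates (y, x) projects to offset r = x cos(theta) + y
    sin(theta); its value is split linearly between the two nearest
    integer offset bins, so total mass is conserved exactly.
    """
    n = _projection_length(s)
    K = (n - 1) // 2
    th = np.deg2rad(theta)
    half = (s - 1) / 2.0
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    x = cols - half
    y = rows - half
    r = x * np.cos(th) + y * np.sin(th)
    lo = np.floor(r).astype(np.int64)
    frac = r - lo
    W = np.zeros((n, s * s))
    idx = np.arange(s * s)
    np.add.at(W, (lo.ravel() + K, idx), 1.0 - frac.ravel())
    np.add.at(W, (lo.ravel() + 1 + K, idx), frac.ravel())
    return W


def radon_projection(block: np.ndarray, theta: float) -> np.ndarray:
    """Line-integral projection of a square block at angle theta (degrees).

    Output length ceil(s * sqrt(2)) rounded up to odd; the sum of the
    projection equals the sum of the block exactly.  theta = 0 gives
    per-column sums (padded); theta = 180 mirrors theta = 0.
    """
    block = np.asarray(block, dtype=np.float64)
    s = block.shape[0]
    if block.shape != (s, s):
        raise ValueError("block must be square")
    if not (0.0 <= theta <= 180.0):
        raise ValueError("theta must lie in [0, 180] degrees")
    return _splat_matrix(s, float(theta)) @ block.ravel()


def omega_lattice(n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (k1, k2) of the principal bispectrum triangle:
    0 <= k2 <= k1 and k1 + k2 <= n_fft / 2 (Nyquist-normalized
    f1 + f2 <= 1)."""
    half = n_fft // 2
    k1, k2 = np.meshgrid(np.arange(half + 1), np.arange(half + 1), indexing="ij")
    keep = (k2 <= k1) & (k1 + k2 <= half)
    return k1[keep], k2[keep]


def bispectrum(proj: np.ndarray, n_fft: int = 32) -> np.ndarray:
    """Bispectrum of a projection on the Omega lattice.

    The projection mean is removed (so the DC term does not swamp the
    distribution), the signal zero-padded to ``n_fft``, and
    B(k1, k2) = R(k1) R(k2) conj(R(k1 + k2)) returned as a complex
    vector ordered like :func:`omega_lattice`.
    """
    proj = np.asarray(proj, dtype=np.float64)
    if n_fft < proj.size or n_fft & (n_fft - 1):
        raise ValueError("n_fft must be a power of two >= projection length")
    x = proj - proj.mean()
    R = np.fft.fft(x, n=n_fft)
    k1, k2 = omega_lattice(n_fft)
    return R[k1] * R[k2] * np.conj(R[k1 + k2])


@dataclass(frozen=True)
class EntropyFeatures:
    """The four bispectral entropies of one block/angle (nats)."""

    P_he: float
    P1: float
    P2: float
    P3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P_he, self.P1, self.P2, self.P3])


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def bispectral_entropies(B: np.ndarray, phase_bins: int = 8) -> EntropyFeatures:
    """Phase, amplitude, squared and cubic bispectral entropies.

    P1/P2/P3 are Shannon entropies (natural log) of |B|, |B|^2, |B|^3
    normalized to unit sum over Omega; P_he is the entropy of the
    bispectral phase histogram over ``phase_bins`` uniform bins on
    (-pi, pi].  An all-zero bispectrum yields all-zero entropies.
    """
    B = np.asarray(B)
    if B.size == 0:
        raise ValueError("empty bispectrum")
    mag = np.abs(B)
    total = mag.sum()
    if total == 0.0:
        return EntropyFeatures(0.0, 0.0, 0.0, 0.0)
    entropies = []
    for power in (1, 2, 3):
        m = mag**power
        entropies.append(_shannon(m / m.sum()))
    phase = np.angle(B)
    # bins over (-pi, pi]: shift the closed end so -pi maps into bin 0
    edges = np.linspace(-np.pi, np.pi, phase_bins + 1)
    which = np.clip(np.searchsorted(edges, phase, side="left") - 1, 0, phase_bins - 1)
    counts = np.bincount(which, minlength=phase_bins).astype(np.float64)
    p_phase = counts / counts.sum()
    return EntropyFeatures(_shannon(p_phase), *entropies)


FEATURE_NAMES = ("P_he", "P1", "P2", "P3")


def block_entropy_table(
    grid: BlockGrid,
    angles=(0.0, 60.0, 120.0, 180.0),
    n_fft: int = 32,
    phase_bins: int = 8,
) -> pd.DataFrame:
    """Per-block entropy features at every angle.

    Returns a DataFrame indexed by 1-based linear block index with
    columns ``block_row``, ``block_col`` and ``<feature>@<angle>`` for
    each of P_he, P1, P2, P3 at each angle (16 features for 4 angles).
    """
    records = {}
    for name in ("block_row", "block_col"):
        records[name] = np.zeros(grid.n_blocks, dtype=np.int64)
    feature_cols = [f"{f}@{a:g}" for a in angles for f in FEATURE_NAMES]
    feats = np.zeros((grid.n_blocks, len(feature_cols)))
    for idx in range(1, grid.n_blocks + 1):
        r, c = grid.position(idx)
        records["block_row"][idx - 1] = r
        records["block_col"][idx - 1] = c
        block = grid.blocks[r - 1, c - 1]
        row = []
        for a in angles:
            proj = radon_projection(block, a)
            B = bispectrum(proj, n_fft)
            row.extend(bispectral_entropies(B, phase_bins).as_array())
        feats[idx - 1] = row
    df = pd.DataFrame(records, index=pd.RangeIndex(1, grid.n_blocks + 1, name="block"))
    df[feature_cols] = feats
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The entropy-feature columns of a block entropy table."""
    return [c for c in table.columns if "@" in c]


__all__ = [
    "BlockGrid",
    "EntropyFeatures",
    "FEATURE_NAMES",
    "partition_blocks",
    "block_index",
    "block_center",
    "radon_projection",
    "omega_lattice",
    "bispectrum",
    "bispectral_entropies",
    "block_entropy_table",
    "feature_columns",
]
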