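"""Pipeline configuration.

All intensity-valued parameters are expressed on the canonical [0, 1]
scale used internally; histogram-domain parameters (the S-function
breakpoints a, b, c) live on the 0..255 level axis.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class SRADConfig:
    """Settings for speckle-reducing anisotropic diffusion.

    ``q0_region`` is either the string ``"auto"`` (pick the 11x11 block
    of minimal intensity variance as the homogeneous reference) or an
    inclusive-exclusive rectangle ``(row0, col0, row1, col1)``.
    """

    dt: float = 0.05
    n_iter: int = 100
    h: float = 1.0
    q0_region: str | tuple[int, int, int, int] = "auto"
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 0.25):
            raise ValueError(f"dt must be in (0, 0.25], got {self.dt}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.h <= 0:
            raise ValueError("h must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings for the seed-selection pipeline."""

    mean_filter_window: int = 5
    tail_loss_f1: float = 0.01
    tail_loss_f2: float = 0.01
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    srad: SRADConfig = field(default_factory=SRADConfig)
    block_size: int = 11
    angles: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0)
    fft_length: int = 32
    phase_bins: int = 8
    region_grow_threshold: float = 0.12
    connectivity: int = 8
    random_seed: int = 0

    def __post_init__(self) -> None:
        w = self.mean_filter_window
        if w < 3 or w % 2 == 0:
            raise ValueError(f"mean_filter_window must be odd and >= 3, got {w}")
        for name in ("tail_loss_f1", "tail_loss_f2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.block_size < 3:
            raise ValueError("block_size must be >= 3")
        n = self.fft_length
        if n < math.ceil(self.block_size * math.sqrt(2)) or n & (n - 1):
            raise ValueError(
                "fft_length must be a power of two >= ceil(block_size * sqrt(2))"
            )
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.region_grow_threshold < 0:
            raise ValueError("region_grow_threshold must be >= 0")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a TOML file.

    Unknown keys raise; the ``[srad]`` table maps onto
    :class:`SRADConfig`.  ``q0_region`` may be a 4-element array.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    srad_raw = raw.pop("srad", {})
    if "q0_region" in srad_raw and not isinstance(srad_raw["q0_region"], str):
        srad_raw["q0_region"] = tuple(srad_raw["q0_region"])
    if "angles" in raw:
        raw["angles"] = tuple(float(a) for a in raw["angles"])
    known = set(PipelineConfig.__dataclass_fields__) - {"srad"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    unknown_srad = set(srad_raw) - set(SRADConfig.__dataclass_fields__)
    if unknown_srad:
        raise ValueError(f"unknown [srad] keys: {sorted(unknown_srad)}")
    return PipelineConfig(srad=SRADConfig(**srad_raw), **raw)


def config_dict(cfg: PipelineConfig) -> dict:
    """Flatten a config to plain types (for JSON diagnostics dumps)."""
    d = asdict(cfg)
    d["angles"] = list(cfg.angles)
    return d


__all__ = ["SRADConfig", "PipelineConfig", "load_config", "config_dict", "replace"]
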