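"""Imaging-run scale prediction.

A high-content confocal run images a grid of sites per well (9x9 available;
only the central 2x2 or 3x3 block acquired), a z-stack per site at a fixed
interval, and one image per channel per plane. Image and byte totals are
plain products; this module keeps the arithmetic and the site-index
conventions in one place.

The per-stage z-slice defaults (35/40/55 for three developmental stages and
45 for mixed-stage plates, at 2 µm) and the 2 MB-per-image default are the
acquisition settings of the reference run; z-coverage follows the
slices x interval convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ImagingConfig",
    "RunTotals",
    "z_coverage",
    "run_totals",
    "center_sites",
    "stage_summary",
]

DEFAULT_SLICES_BY_STAGE = {"12hpf": 35, "24hpf": 40, "36hpf": 55, "mixed": 45}


@dataclass(frozen=True)
class ImagingConfig:
    grid: int = 9  # sites form a grid x grid lattice
    center_block: int = 3  # 2 -> 4 sites, 3 -> 9 sites acquired
    n_wells: int = 48
    n_channels: int = 5
    slices_by_stage: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SLICES_BY_STAGE)
    )
    z_interval_um: float = 2.0
    exposure_ms: dict[str, float] = field(
        default_factory=lambda: {"default": 150.0, "nuclear": 50.0}
    )
    bytes_per_image: int = 2_000_000

    def __post_init__(self) -> None:
        if self.center_block not in (2, 3):
            raise ValueError("center block must be 2x2 or 3x3")
        if self.center_block > self.grid:
            raise ValueError("center block larger than grid")
        if any(s < 1 for s in self.slices_by_stage.values()):
            raise ValueError("slice counts must be >= 1")
        if self.z_interval_um <= 0:
            raise ValueError("z interval must be positive")

    @property
    def n_sites(self) -> int:
        return self.center_block**2

    @property
    def sites(self) -> list[int]:
        return center_sites(self.grid, self.center_block)


@dataclass(frozen=True)
class RunTotals:
    n_images: int
    total_bytes: int

    @property
    def total_gb(self) -> float:
        """Decimal gigabytes (1 GB = 1e9 bytes), as storage vendors report."""
        return self.total_bytes / 1e9


def z_coverage(slices: int, interval_um: float = 2.0) -> float:
    """Axial extent covered by a stack, as slices x interval."""
    if slices < 1:
        raise ValueError("need at least one slice")
    return slices * interval_um


def run_totals(
    sites: int,
    slices: int,
    wells: int,
    channels: int,
    bytes_per_image: int = 2_000_000,
) -> RunTotals:
    """Image count = sites x slices x wells x channels; bytes follow."""
    counts = (sites, slices, wells, channels)
    if any(c < 1 for c in counts):
        raise ValueError("all counts must be >= 1")
    n = sites * slices * wells * channels
    return RunTotals(n_images=n, total_bytes=n * bytes_per_image)


def center_sites(grid: int = 9, block: int = 3) -> list[int]:
    """1-based row-major site indices of the central block x block window.

    Sites number 1..grid**2 from the top-left, rows first. For an odd grid
    with an even block the window is anchored upper-left of center, so the
    2x2 set is contained in the 3x3 set.
    """
    if block > grid or block < 1:
        raise ValueError("block must be between 1 and the grid side")
    first = (grid - block) // 2  # floor -> upper-left of center when ambiguous
    rows = range(first, first + block)
    return sorted(r * grid + c + 1 for r in rows for c in rows)


def stage_summary(config: ImagingConfig | None = None) -> pd.DataFrame:
    """Per-stage table of slices, z-coverage, image count and data volume."""
    cfg = config or ImagingConfig()
    rows = []
    for stage, slices in cfg.slices_by_stage.items():
        totals = run_totals(
            cfg.n_sites, slices, cfg.n_wells, cfg.n_channels, cfg.bytes_per_image
        )
        rows.append(
            {
                "stage": stage,
                "slices": slices,
                "z_coverage_um": z_coverage(slices, cfg.z_interval_um),
                "n_images": totals.n_images,
                "total_gb": totals.total_gb,
            }
        )
    return pd.DataFrame(rows)


def write_plan(path: str | Path, config: ImagingConfig | None = None) -> dict:
    cfg = config or ImagingConfig()
    table = stage_summary(cfg)
    doc = {
        "grid": cfg.grid,
        "center_block": cfg.center_block,
        "sites": cfg.sites,
        "n_wells": cfg.n_wells,
        "n_channels": cfg.n_channels,
        "z_interval_um": cfg.z_interval_um,
        "bytes_per_image": cfg.bytes_per_image,
        "stages": table.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(doc, indent=2))
    return doc
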