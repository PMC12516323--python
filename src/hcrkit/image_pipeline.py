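"""Post-processing of a high-content acquisition.

Raw output is a flat directory of single-plane grayscale TIFFs whose
filenames encode plate, well, site, channel and z (a configurable
"dialect"). Processing sorts planes into per-(well, site, channel) z-stacks,
maximum-projects each stack, stitches the site tiles into an abutting
mosaic, composes a pseudocolored multichannel overlay, annotates each
channel with the gene it reports (via plate map -> pool -> amplifier ->
wavelength), and picks the scoring image for each well (the central site,
which typically holds the most embryos).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .imaging_plan import center_sites
from .pool_plate import ChannelMap

__all__ = [
    "FilenameDialect",
    "DEFAULT_DIALECT",
    "ImageKey",
    "Tile",
    "WellImage",
    "parse_filename",
    "format_filename",
    "scan_directory",
    "group_stacks",
    "incomplete_groups",
    "max_project",
    "stitch",
    "compose",
    "annotate",
    "select_scoring_image",
    "process_run",
    "DEFAULT_PALETTE",
]


@dataclass(frozen=True)
class FilenameDialect:
    """Regex (named groups) + format template for acquisition filenames."""

    pattern: str = (
        r"^(?P<plate>[^_]+)_(?P<well>[A-Ha-h]\d{2})"
        r"_s(?P<site>\d+)_w(?P<channel>\d+)_z(?P<z>\d+)\.tiff?$"
    )
    template: str = "{plate}_{well}_s{site}_w{channel}_z{z:02d}.tif"

    def regex(self) -> re.Pattern:
        return re.compile(self.pattern)


DEFAULT_DIALECT = FilenameDialect()


@dataclass(frozen=True, order=True)
class ImageKey:
    """Address of one acquired plane. Well is zero-padded (A01); site,
    channel and z are 1-based."""

    plate: str
    well: str
    site: int
    channel: int
    z: int


def parse_filename(name: str, dialect: FilenameDialect = DEFAULT_DIALECT) -> ImageKey | None:
    """Parse one filename; returns None for names outside the dialect."""
    m = dialect.regex().match(name)
    if not m:
        return None
    g = m.groupdict()
    return ImageKey(
        plate=g["plate"],
        well=g["well"].upper(),
        site=int(g["site"]),
        channel=int(g["channel"]),
        z=int(g["z"]),
    )


def format_filename(key: ImageKey, dialect: FilenameDialect = DEFAULT_DIALECT) -> str:
    return dialect.template.format(
        plate=key.plate, well=key.well, site=key.site, channel=key.channel, z=key.z
    )


def scan_directory(
    directory: str | Path, dialect: FilenameDialect = DEFAULT_DIALECT
) -> tuple[dict[ImageKey, Path], list[str]]:
    """Map every parseable file to its key; report skipped names."""
    directory = Path(directory)
    keys: dict[ImageKey, Path] = {}
    skipped: list[str] = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        key = parse_filename(path.name, dialect)
        if key is None:
            skipped.append(path.name)
        elif key in keys:
            raise ValueError(f"duplicate plane: {path.name}")
        else:
            keys[key] = path
    return keys, skipped


GroupKey = tuple[str, str, int, int]  # (plate, well, site, channel)


def group_stacks(keys: Iterable[ImageKey]) -> dict[GroupKey, list[ImageKey]]:
    """Partition keys into z-sorted per-(plate, well, site, channel) stacks.

    Raises on a duplicated (well, site, channel, z) address.
    """
    groups: dict[GroupKey, list[ImageKey]] = {}
    for key in keys:
        groups.setdefault((key.plate, key.well, key.site, key.channel), []).append(key)
    for gkey, members in groups.items():
        members.sort(key=lambda k: k.z)
        zs = [k.z for k in members]
        if len(set(zs)) != len(zs):
            raise ValueError(f"duplicate z in stack {gkey}")
    return dict(sorted(groups.items()))


def incomplete_groups(
    groups: Mapping[GroupKey, list[ImageKey]], expected_slices: int | None = None
) -> list[GroupKey]:
    """Stacks with missing planes: a gap in z, or fewer than expected."""
    bad = []
    for gkey, members in groups.items():
        zs = [k.z for k in members]
        contiguous = zs == list(range(zs[0], zs[0] + len(zs)))
        if not contiguous or (expected_slices is not None and len(zs) != expected_slices):
            bad.append(gkey)
    return bad


def max_project(stack: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z. Idempotent, z-order invariant."""
    planes = np.asarray(stack)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.ndim != 3:
        raise ValueError("stack must be a list of 2-D planes")
    return planes.max(axis=0)


def stitch(
    tiles: Mapping[int, np.ndarray], sites: Sequence[int], block: int
) -> tuple[np.ndarray, list[int]]:
    """Abutting mosaic of ``block x block`` site tiles.

    ``sites`` gives the row-major order of site indices within the block
    (e.g. from :func:`hcrkit.imaging_plan.center_sites`). Missing tiles are
    zero-filled and returned in the second element. No overlap/registration:
    high-content stages are coordinate-calibrated, so tiles simply abut.
    """
    if len(sites) != block * block:
        raise ValueError("need block**2 site indices")
    present = [tiles[s] for s in sites if s in tiles]
    if not present:
        raise ValueError("no tiles to stitch")
    h, w = present[0].shape
    for t in present:
        if t.shape != (h, w):
            raise ValueError("tile dimensions differ")
    mosaic = np.zeros((block * h, block * w), dtype=present[0].dtype)
    missing = []
    for i, site in enumerate(sites):
        r, c = divmod(i, block)
        if site in tiles:
            mosaic[r * h : (r + 1) * h, c * w : (c + 1) * w] = tiles[site]
        else:
            missing.append(site)
    return mosaic, missing


# Pseudocolor defaults, far-red -> green; nuclear rendered gray.
DEFAULT_PALETTE: dict[int, tuple[float, float, float]] = {
    1: (1.0, 0.0, 0.0),
    2: (1.0, 0.5, 0.0),
    3: (1.0, 1.0, 0.0),
    4: (0.0, 1.0, 0.0),
    5: (0.7, 0.7, 0.7),
}


def compose(
    channel_tiles: Mapping[int, np.ndarray],
    palette: Mapping[int, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Additive pseudocolor blend of aligned channel tiles, clipped to the
    input dtype range. The inputs are left untouched — they ARE the
    demultiplexed per-gene images."""
    palette = palette or DEFAULT_PALETTE
    tiles = list(channel_tiles.values())
    shape = tiles[0].shape
    dtype = tiles[0].dtype
    for t in tiles:
        if t.shape != shape:
            raise ValueError("channel tiles must share dimensions")
    lim = np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else 1.0
    acc = np.zeros((*shape, 3), dtype=np.float64)
    for ch, tile in channel_tiles.items():
        rgb = palette[ch]
        acc += tile[..., None].astype(np.float64) * np.asarray(rgb)
    return np.clip(acc, 0, lim).astype(dtype)


@dataclass
class Tile:
    pixels: np.ndarray
    key: ImageKey  # z collapsed to 0 after projection


@dataclass
class WellImage:
    """Stitched per-channel rasters + composite + annotation for one well."""

    plate: str
    well: str
    channels: dict[int, np.ndarray]
    composite: np.ndarray
    labels: dict[int, str]


def annotate(raster: np.ndarray, label: str, margin_px: int = 24) -> np.ndarray:
    """Burn ``label`` into a reserved margin added above the image.

    Pixel data outside the margin is untouched, so the scientific raster
    stays analyzable; returns an array of the same dtype with ``margin_px``
    extra rows.
    """
    if raster.ndim not in (2, 3):
        raise ValueError("raster must be 2-D grayscale or 3-D RGB")
    lim = (
        np.iinfo(raster.dtype).max
        if np.issubdtype(raster.dtype, np.integer)
        else 1.0
    )
    margin_shape = (margin_px,) + raster.shape[1:]
    margin = np.zeros(margin_shape, dtype=raster.dtype)
    img = Image.new("L", (raster.shape[1], margin_px), 0)
    ImageDraw.Draw(img).text((4, 4), label, fill=255)
    text = np.asarray(img, dtype=np.float64) / 255.0 * lim
    if raster.ndim == 3:
        margin[...] = text.astype(raster.dtype)[..., None]
    else:
        margin[...] = text.astype(raster.dtype)
    return np.concatenate([margin, raster], axis=0)


def foreground_area(tile: np.ndarray, threshold: float) -> int:
    return int((tile > threshold).sum())


def select_scoring_image(
    tiles: Mapping[int, np.ndarray],
    center_site: int | None = None,
    fallback_threshold: float | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the well's scoring tile: the central site if present.

    ``center_site`` defaults to the center of the default 9x9 grid (41).
    If the center tile is absent and ``fallback_threshold`` is given, the
    tile with the greatest foreground area (pixels above threshold) wins;
    ties break toward the lowest site index.
    """
    if not tiles:
        raise ValueError("no tiles for well")
    if center_site is None:
        grid9 = center_sites(9, 3)
        center_site = grid9[len(grid9) // 2]  # 41
    if center_site in tiles:
        return center_site, tiles[center_site]
    if len(tiles) == 1:
        (site, tile), = tiles.items()
        return site, tile
    if fallback_threshold is None:
        raise KeyError(f"center site {center_site} missing and no fallback enabled")
    best = min(
        tiles, key=lambda s: (-foreground_area(tiles[s], fallback_threshold), s)
    )
    return best, tiles[best]


def _label_for(
    resolver, well: str, channel: int, channels: ChannelMap
) -> str:
    gene = resolver(well, channel)
    if gene is None:
        key = channels.key_at(channel)
        return channels.entries[key].fluorophore  # nuclear stain label
    accession, symbol = gene
    return f"{symbol} — {accession}"


def process_run(
    input_dir: str | Path,
    resolver,
    channels: ChannelMap,
    out_dir: str | Path,
    dialect: FilenameDialect = DEFAULT_DIALECT,
    grid: int = 9,
    block: int | None = None,
    palette: Mapping[int, tuple[float, float, float]] | None = None,
    expected_slices: int | None = None,
    write_images: bool = True,
) -> dict:
    """End-to-end post-processing of one acquisition directory.

    ``resolver(well, channel_index)`` returns (accession, symbol) for probe
    channels and None for the nuclear channel (see
    :func:`hcrkit.pool_plate.resolve_gene`). Per well the function projects
    every (site, channel) stack, stitches site tiles per channel, composes
    the pseudocolor overlay, annotates everything, and records the scoring
    site. Outputs: per-channel and composite TIFFs plus ``report.json``.
    Deterministic: identical inputs and config give identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys, skipped = scan_directory(input_dir, dialect)
    groups = group_stacks(keys)
    incomplete = incomplete_groups(groups, expected_slices)

    # wells -> channel -> site -> projected tile
    wells: dict[tuple[str, str], dict[int, dict[int, np.ndarray]]] = {}
    for (plate, well, site, channel), members in groups.items():
        stack = np.stack([tifffile.imread(keys[k]) for k in members])
        wells.setdefault((plate, well), {}).setdefault(channel, {})[site] = (
            max_project(stack)
        )

    report: dict = {
        "skipped": skipped,
        "incomplete_stacks": [list(g) for g in incomplete],
        "wells": {},
    }
    for (plate, well), by_channel in sorted(wells.items()):
        sites_present = sorted({s for t in by_channel.values() for s in t})
        if block is None:
            b = int(round(len(sites_present) ** 0.5))
            b = max(b, 1)
        else:
            b = block
        site_order = center_sites(grid, b) if b > 1 else sites_present[:1]
        stitched: dict[int, np.ndarray] = {}
        labels: dict[int, str] = {}
        missing_any: dict[int, list[int]] = {}
        for channel, tiles in sorted(by_channel.items()):
            mosaic, missing = stitch(tiles, site_order, b)
            stitched[channel] = mosaic
            missing_any[channel] = missing
            labels[channel] = _label_for(resolver, well, channel, channels)
        composite = compose(stitched, palette)
        center = site_order[len(site_order) // 2]
        scoring_site, _ = select_scoring_image(
            next(iter(by_channel.values())), center_site=center
        )
        if write_images:
            for channel, mosaic in stitched.items():
                annotated = annotate(mosaic, labels[channel])
                tifffile.imwrite(
                    out_dir / f"{plate}_{well}_w{channel}.tif", annotated
                )
            tifffile.imwrite(
                out_dir / f"{plate}_{well}_composite.tif",
                annotate(composite, " | ".join(labels[c] for c in sorted(labels))),
            )
        report["wells"][f"{plate}/{well}"] = {
            "labels": {str(c): labels[c] for c in sorted(labels)},
            "scoring_site": scoring_site,
            "missing_tiles": {str(c): m for c, m in missing_any.items() if m},
        }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
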