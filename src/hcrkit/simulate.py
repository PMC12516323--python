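"""Synthetic inputs with known ground truth.

Two generators: random coding-sequence FASTA panels for the probe designer,
and full fake imaging runs (wells x sites x z x channels of single-plane
TIFFs) for the post-processing pipeline. Images carry disk-shaped "embryo"
blobs in the nuclear channel, channel-specific Gaussian spot signal only in
(well, channel) combinations designated expressing, Gaussian background
noise everywhere, and a triangular per-slice intensity profile across z.
A run manifest records every file, every truth value and the seed, and
regeneration with the same seed is byte-identical.

Rasters default to 128x128: run *structure* (file counts, grouping,
stitching geometry, demultiplexing) is what downstream tests exercise, so
small tiles keep even full-scale 97,200-file runs tractable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .image_pipeline import DEFAULT_DIALECT, FilenameDialect, ImageKey, format_filename
from .imaging_plan import center_sites
from .pool_plate import NUCLEAR, ChannelMap, channel_map

__all__ = [
    "SignalModel",
    "RunManifest",
    "synth_transcriptome",
    "write_fasta",
    "synth_run",
    "count_spots",
]

_BASES = np.array(list("ACGT"))


def synth_transcriptome(
    n: int,
    length_range: tuple[int, int] = (300, 3000),
    gc: float = 0.4,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Random CDS-like records: (accession, symbol, sequence).

    Lengths are uniform over ``length_range``; base composition is i.i.d.
    with the requested GC fraction split evenly between G and C.
    """
    if n < 1:
        raise ValueError("need at least one record")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range: {length_range}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"invalid GC fraction: {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
        records.append((f"SYN_{i + 1:06d}.1", f"syngene{i + 1:03d}", seq))
    return records


def write_fasta(records: Sequence[tuple[str, str, str]], path: str | Path) -> Path:
    """Plain 60-column FASTA with '>accession symbol' headers."""
    path = Path(path)
    with path.open("w") as fh:
        for accession, symbol, seq in records:
            fh.write(f">{accession} {symbol}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


@dataclass(frozen=True)
class SignalModel:
    """Pixel-level generative model for fake acquisitions (uint16 output).

    Embryos are filled disks in the nuclear channel; expressing probe
    channels get isotropic Gaussian spots planted on a jittered grid (so
    spots never merge and remain countable); everything sits on Gaussian
    background noise. Spot and embryo amplitude follow a triangular profile
    across z peaking mid-stack, mimicking an object centered in the stack.
    """

    background_mean: float = 100.0
    background_sigma: float = 10.0
    embryo_radius_px: int = 12
    embryo_amplitude: float = 2000.0
    embryos_per_tile: tuple[int, int] = (2, 5)  # inclusive range
    spot_amplitude: float = 3000.0
    spot_sigma_px: float = 1.2
    spots_per_tile: tuple[int, int] = (20, 40)  # inclusive range
    express_prob: float = 0.5


def _z_profile(n_slices: int) -> np.ndarray:
    """Triangular weights peaking at the stack center; max weight is 1."""
    if n_slices == 1:
        return np.ones(1)
    center = (n_slices - 1) / 2
    return 1.0 - np.abs(np.arange(n_slices) - center) / (center + 1)


def _disk_mask(shape: tuple[int, int], cy: int, cx: int, radius: int) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _spot_positions(
    rng: np.random.Generator, shape: tuple[int, int], n: int, margin: int
) -> list[tuple[int, int]]:
    """n positions on a jittered coarse grid: guaranteed pairwise separation.

    Jitter is confined to a 3-px box at each cell's center, so any two spots
    are at least ``cell - 2`` px apart and thresholded spots never merge.
    """
    h, w = shape
    cell = 10  # >> spot sigma, so thresholded spots stay disjoint
    rows = (h - 2 * margin) // cell
    cols = (w - 2 * margin) // cell
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    idx = rng.choice(len(cells), size=min(n, len(cells)), replace=False)
    box0 = (cell - 3) // 2
    out = []
    for i in idx:
        r, c = cells[i]
        jy, jx = rng.integers(box0, box0 + 3, size=2)
        out.append((margin + r * cell + int(jy), margin + c * cell + int(jx)))
    return out


def _add_gaussian_spot(
    plane: np.ndarray, cy: int, cx: int, amplitude: float, sigma: float
) -> None:
    r = int(np.ceil(3 * sigma))
    y0, y1 = max(cy - r, 0), min(cy + r + 1, plane.shape[0])
    x0, x1 = max(cx - r, 0), min(cx + r + 1, plane.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


@dataclass
class RunManifest:
    """Ground truth for a synthetic run: every file, every planted signal."""

    seed: int
    wells: list[str]
    sites: list[int]
    n_slices: int
    n_channels: int
    tile_shape: tuple[int, int]
    nuclear_channel: int
    truth: dict  # well -> channel(str) -> {accession, symbol, expressing}
    spot_counts: dict  # "well/site/channel" -> planted spot count
    embryo_counts: dict  # "well/site" -> embryo count
    signal_model: dict
    files: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        doc["tile_shape"] = tuple(doc["tile_shape"])
        for field_name in ("embryos_per_tile", "spots_per_tile"):
            doc["signal_model"][field_name] = tuple(doc["signal_model"][field_name])
        return cls(**doc)


def synth_run(
    out_dir: str | Path,
    n_wells: int = 4,
    grid: int = 9,
    block: int = 2,
    n_slices: int = 5,
    n_channels: int = 5,
    seed: int = 0,
    tile_shape: tuple[int, int] = (128, 128),
    signal_model: SignalModel | None = None,
    plate_id: str = "plate1",
    well_genes: Mapping[str, Mapping[int, tuple[str, str]]] | None = None,
    channels: ChannelMap | None = None,
    dialect: FilenameDialect = DEFAULT_DIALECT,
    overwrite: bool = False,
) -> RunManifest:
    """Write a full fake acquisition and its ground-truth manifest.

    File count is ``block**2 * n_slices * n_wells * n_channels``. Wells fill
    row-major from A01; only the central ``block x block`` sites of the
    ``grid x grid`` lattice are "acquired", as on the real instrument.
    ``well_genes`` maps well -> channel index -> (accession, symbol); when
    omitted, synthetic gene names are minted. The last channel (highest
    index = lowest excitation under the default map) is the nuclear stain.
    Expression truth per probe (well, channel) is Bernoulli with the model's
    ``express_prob``; non-expressing combinations get zero planted spots.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    model = signal_model or SignalModel()
    cmap = channels or channel_map()
    rng = np.random.default_rng(seed)

    from .pool_plate import well_names

    wells = [f"{w[0]}{int(w[1:]):02d}" for w in well_names()[:n_wells]]
    sites = center_sites(grid, block)
    nuclear_idx = n_channels  # descending-excitation convention: 405 nm last

    truth: dict = {}
    for wi, well in enumerate(wells):
        truth[well] = {}
        for ch in range(1, n_channels + 1):
            if ch == nuclear_idx:
                truth[well][str(ch)] = {
                    "accession": None,
                    "symbol": cmap.entries[NUCLEAR].fluorophore
                    if NUCLEAR in cmap.entries
                    else "nuclear",
                    "expressing": True,
                }
                continue
            if well_genes is not None:
                accession, symbol = well_genes[well][ch]
            else:
                gi = wi * (n_channels - 1) + ch
                accession, symbol = f"SYN_{gi:06d}.1", f"syngene{gi:03d}"
            truth[well][str(ch)] = {
                "accession": accession,
                "symbol": symbol,
                "expressing": bool(rng.random() < model.express_prob),
            }

    profile = _z_profile(n_slices)
    spot_counts: dict[str, int] = {}
    embryo_counts: dict[str, int] = {}
    files: list[str] = []
    h, w = tile_shape

    for well in wells:
        for site in sites:
            n_embryos = int(
                rng.integers(model.embryos_per_tile[0], model.embryos_per_tile[1] + 1)
            )
            embryo_counts[f"{well}/{site}"] = n_embryos
            centers = [
                (
                    int(rng.integers(model.embryo_radius_px, h - model.embryo_radius_px)),
                    int(rng.integers(model.embryo_radius_px, w - model.embryo_radius_px)),
                )
                for _ in range(n_embryos)
            ]
            for ch in range(1, n_channels + 1):
                expressing = truth[well][str(ch)]["expressing"]
                if ch == nuclear_idx:
                    signal = np.zeros(tile_shape)
                    for cy, cx in centers:
                        signal[_disk_mask(tile_shape, cy, cx, model.embryo_radius_px)] = (
                            model.embryo_amplitude
                        )
                    n_spots = 0
                elif expressing:
                    wanted = int(
                        rng.integers(model.spots_per_tile[0], model.spots_per_tile[1] + 1)
                    )
                    positions = _spot_positions(rng, tile_shape, wanted, margin=6)
                    n_spots = len(positions)  # may be fewer on tiny rasters
                    signal = np.zeros(tile_shape)
                    for cy, cx in positions:
                        _add_gaussian_spot(
                            signal, cy, cx, model.spot_amplitude, model.spot_sigma_px
                        )
                else:
                    signal = None
                    n_spots = 0
                if ch != nuclear_idx:
                    spot_counts[f"{well}/{site}/{ch}"] = n_spots
                noise = rng.normal(
                    model.background_mean,
                    model.background_sigma,
                    size=(n_slices, h, w),
                )
                stack = noise
                if signal is not None:
                    stack = stack + profile[:, None, None] * signal[None]
                stack = np.clip(stack, 0, 65535).astype(np.uint16)
                for zi in range(n_slices):
                    key = ImageKey(plate_id, well, site, ch, zi + 1)
                    name = format_filename(key, dialect)
                    tifffile.imwrite(out_dir / name, stack[zi])
                    files.append(name)

    manifest = RunManifest(
        seed=seed,
        wells=wells,
        sites=sites,
        n_slices=n_slices,
        n_channels=n_channels,
        tile_shape=tile_shape,
        nuclear_channel=nuclear_idx,
        truth=truth,
        spot_counts=spot_counts,
        embryo_counts=embryo_counts,
        signal_model=asdict(model),
        files=files,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def count_spots(tile: np.ndarray, threshold: float) -> int:
    """Count connected components above ``threshold``.

    A fixture-validation helper for checking the projection/stitch chain
    against planted ground truth — not a biological readout.
    """
    from skimage import measure

    return int(measure.label(tile > threshold).max())
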