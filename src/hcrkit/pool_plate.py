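"""Probe pooling, 96-well plate maps, order sheets and channel maps.

Four probe sets with distinct amplifiers are combined into one oligo pool
and dispensed into one well, so each well assays four genes, one per
fluorescence channel. This module chunks designed probe sets into pools,
lays pools onto plates, emits the synthesis order sheet, and holds the
amplifier -> fluorophore/excitation/filter map that later demultiplexes
each (well, wavelength) back to a single gene.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .probe_design import ProbeSet

__all__ = [
    "ProbePool",
    "PlateMap",
    "Channel",
    "ChannelMap",
    "NUCLEAR",
    "build_pools",
    "assign_wells",
    "order_sheet",
    "make_oligo_name",
    "parse_oligo_name",
    "channel_map",
    "resolve_gene",
    "normalize_well",
    "well_names",
    "write_platemap",
    "read_platemap",
]

ROWS = string.ascii_uppercase[:8]  # A-H
N_COLS = 12
PLATE_SIZE = len(ROWS) * N_COLS  # 96


def normalize_well(well: str) -> str:
    """Canonical un-padded form: 'A01' -> 'A1'."""
    m = re.fullmatch(r"([A-Ha-h])0*([1-9]\d*)", well)
    if not m:
        raise ValueError(f"malformed well name: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > N_COLS:
        raise ValueError(f"column out of range: {well!r}")
    return f"{row}{col}"


def well_names(order: str = "row_major") -> list[str]:
    """The 96 well names in fill order."""
    if order == "row_major":
        return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]
    if order == "column_major":
        return [f"{r}{c}" for c in range(1, N_COLS + 1) for r in ROWS]
    raise ValueError(f"unknown fill order: {order!r}")


@dataclass
class ProbePool:
    """Up to four probe sets with pairwise-distinct amplifiers, one well."""

    pool_id: str
    members: tuple[ProbeSet, ...]
    well: str | None = None
    plate_id: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 4:
            raise ValueError(f"{self.pool_id}: pool must hold 1-4 probe sets")
        amps = [m.amplifier_id for m in self.members]
        if len(set(amps)) != len(amps):
            raise ValueError(f"{self.pool_id}: duplicate amplifier in pool: {amps}")


@dataclass
class PlateMap:
    """One 96-well plate: well -> pool id (wells stored un-padded, e.g. A1)."""

    plate_id: str
    layout: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(well_names())
        for well in self.layout:
            if well not in valid:
                raise ValueError(f"well outside 8x12 geometry: {well!r}")


def build_pools(probe_sets: Sequence[ProbeSet], pool_size: int = 4) -> list[ProbePool]:
    """Chunk probe sets into pools of ``pool_size`` in input order.

    Only sets with status "ok" may be pooled. The designer's round-robin
    B1->B4 amplifier assignment means consecutive chunks automatically carry
    distinct amplifiers; a chunk violating that raises. The last pool may be
    partial.
    """
    for ps in probe_sets:
        if ps.status != "ok":
            raise ValueError(
                f"{ps.target.accession}: status {ps.status!r}, cannot pool"
            )
    pools = []
    for i in range(0, len(probe_sets), pool_size):
        chunk = tuple(probe_sets[i : i + pool_size])
        pools.append(ProbePool(f"P{i // pool_size + 1:03d}", chunk))
    return pools


def assign_wells(
    pools: Sequence[ProbePool],
    start_well: str = "A1",
    order: str = "row_major",
    plate_prefix: str = "plate",
) -> list[PlateMap]:
    """Deterministic plate fill; overflow past 96 wells starts a new plate."""
    names = well_names(order)
    start = names.index(normalize_well(start_well))
    plates: list[PlateMap] = []
    for i, pool in enumerate(pools):
        slot = start + i
        plate_idx, well_idx = divmod(slot, PLATE_SIZE)
        plate_id = f"{plate_prefix}{plate_idx + 1}"
        if plate_idx >= len(plates):
            plates.append(PlateMap(plate_id))
        pool.well = names[well_idx]
        pool.plate_id = plate_id
        plates[plate_idx].layout[pool.well] = pool.pool_id
    return plates


_NAME_SEP = "__"


def make_oligo_name(
    pool_id: str, accession: str, amplifier_id: str, pair_index: int, strand: str
) -> str:
    """Reversible oligo name: fields joined by '__', strand in {up, down}."""
    if strand not in ("up", "down"):
        raise ValueError(f"strand must be 'up' or 'down', got {strand!r}")
    fields = (pool_id, accession, amplifier_id, f"p{pair_index:02d}", strand)
    for f in fields[:3]:
        if _NAME_SEP in f:
            raise ValueError(f"field may not contain {_NAME_SEP!r}: {f!r}")
    return _NAME_SEP.join(fields)


def parse_oligo_name(name: str) -> dict:
    pool_id, accession, amplifier_id, pair, strand = name.split(_NAME_SEP)
    return {
        "pool_id": pool_id,
        "accession": accession,
        "amplifier": amplifier_id,
        "pair_index": int(pair.lstrip("p")),
        "strand": strand,
    }


def order_sheet(pools: Iterable[ProbePool]) -> pd.DataFrame:
    """One row per synthesized oligo, in pool/set/pair order.

    Row count is twice the total pair count. Raises on oligo-name collision.
    """
    rows = []
    for pool in pools:
        for ps in pool.members:
            for pair in ps.pairs:
                for strand, seq in (("up", pair.oligo_up), ("down", pair.oligo_down)):
                    rows.append(
                        {
                            "pool_id": pool.pool_id,
                            "accession": ps.target.accession,
                            "symbol": ps.target.symbol,
                            "amplifier": ps.amplifier_id,
                            "pair_index": pair.pair_index,
                            "oligo_name": make_oligo_name(
                                pool.pool_id,
                                ps.target.accession,
                                ps.amplifier_id,
                                pair.pair_index,
                                strand,
                            ),
                            "sequence": seq,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "pool_id",
            "accession",
            "symbol",
            "amplifier",
            "pair_index",
            "oligo_name",
            "sequence",
        ],
    )
    if df["oligo_name"].duplicated().any():
        dup = df.loc[df["oligo_name"].duplicated(), "oligo_name"].iloc[0]
        raise ValueError(f"oligo name collision: {dup}")
    return df


@dataclass(frozen=True)
class Channel:
    fluorophore: str
    excitation_nm: int
    emission_filter: str


NUCLEAR = "nuclear"

# Default acquisition map: laser line with emission filter per fluorophore.
DEFAULT_CHANNELS: dict[str, Channel] = {
    "B1": Channel("Cyanine7", 740, "794/32"),
    "B2": Channel("Alexa Fluor 647", 640, "680/42"),
    "B3": Channel("Alexa Fluor 594", 555, "624/40"),
    "B4": Channel("ATTO 532", 520, "562/40"),
    NUCLEAR: Channel("Hoechst 33342", 405, "452/45"),
}


@dataclass(frozen=True)
class ChannelMap:
    """amplifier/nuclear -> channel, plus the acquisition index convention.

    Channel indices (w1..wN in filenames) follow descending excitation, so
    the nuclear 405-nm channel is last.
    """

    entries: Mapping[str, Channel]

    def __post_init__(self) -> None:
        ex = [c.excitation_nm for c in self.entries.values()]
        if len(set(ex)) != len(ex):
            raise ValueError("excitation wavelengths must be unique")

    @property
    def index_order(self) -> list[str]:
        return sorted(
            self.entries, key=lambda k: -self.entries[k].excitation_nm
        )

    def index_of(self, key: str) -> int:
        """1-based acquisition channel index of an amplifier or 'nuclear'."""
        return self.index_order.index(key) + 1

    def key_at(self, index: int) -> str:
        return self.index_order[index - 1]

    def by_excitation(self, excitation_nm: int) -> str:
        for key, ch in self.entries.items():
            if ch.excitation_nm == excitation_nm:
                return key
        raise KeyError(f"no channel at {excitation_nm} nm")

    def __len__(self) -> int:
        return len(self.entries)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            key: {
                "fluorophore": ch.fluorophore,
                "excitation_nm": ch.excitation_nm,
                "emission_filter": ch.emission_filter,
            }
            for key, ch in self.entries.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelMap":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            {
                key: Channel(v["fluorophore"], v["excitation_nm"], v["emission_filter"])
                for key, v in doc.items()
            }
        )


def channel_map(config: Mapping[str, Channel] | None = None) -> ChannelMap:
    """Build the run's channel map; default reproduces the five-channel
    Cy7/AF647/AF594/ATTO532/Hoechst configuration.

    ``config`` entries must cover every amplifier used plus the nuclear
    stain; a missing amplifier raises ``KeyError`` downstream at resolution.
    """
    return ChannelMap(dict(config or DEFAULT_CHANNELS))


def resolve_gene(
    plates: Sequence[PlateMap],
    pools: Sequence[ProbePool],
    channels: ChannelMap,
    well: str,
    channel_index: int,
    plate_id: str | None = None,
) -> tuple[str, str] | None:
    """(well, channel) -> (accession, symbol); None for the nuclear channel.

    Raises ``KeyError`` for an unoccupied well or an amplifier with no pool
    member in that well.
    """
    well = normalize_well(well)
    key = channels.key_at(channel_index)
    if key == NUCLEAR:
        return None
    pool_id = None
    for plate in plates:
        if plate_id is not None and plate.plate_id != plate_id:
            continue
        if well in plate.layout:
            pool_id = plate.layout[well]
            break
    if pool_id is None:
        raise KeyError(f"well {well} is not occupied")
    pool = next(p for p in pools if p.pool_id == pool_id)
    for ps in pool.members:
        if ps.amplifier_id == key:
            return ps.target.accession, ps.target.symbol
    raise KeyError(f"no {key} probe set in pool {pool_id} (well {well})")


def write_platemap(plates: Sequence[PlateMap], pools: Sequence[ProbePool],
                   csv_path: str | Path, json_path: str | Path | None = None) -> pd.DataFrame:
    """Plate map as CSV (one row per well x pool member) and optional JSON."""
    rows = []
    by_id = {p.pool_id: p for p in pools}
    for plate in plates:
        for well, pool_id in plate.layout.items():
            for ps in by_id[pool_id].members:
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "well": well,
                        "pool_id": pool_id,
                        "amplifier": ps.amplifier_id,
                        "accession": ps.target.accession,
                        "symbol": ps.target.symbol,
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        doc = [
            {"plate_id": p.plate_id, "layout": p.layout} for p in plates
        ]
        Path(json_path).write_text(json.dumps(doc, indent=2))
    return df


def resolver_from_table(df: pd.DataFrame, channels: ChannelMap):
    """Build a (well, channel_index) -> (accession, symbol) resolver from a
    plate-map table (as written by :func:`write_platemap`)."""
    lookup = {
        (normalize_well(r.well), r.amplifier): (r.accession, r.symbol)
        for r in df.itertuples()
    }

    def resolve(well: str, channel_index: int):
        key = channels.key_at(channel_index)
        if key == NUCLEAR:
            return None
        w = normalize_well(well)
        if (w, key) not in lookup:
            raise KeyError(f"no {key} probe set mapped to well {w}")
        return lookup[(w, key)]

    return resolve


def read_platemap(csv_path: str | Path) -> pd.DataFrame:
    """Read a plate-map CSV written by :func:`write_platemap`."""
    df = pd.read_csv(csv_path)
    required = {"plate_id", "well", "pool_id", "amplifier", "accession", "symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return df
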