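"""Split-initiator HCR v3 probe design.

A probe set for one target mRNA is a tiling of 3-15 probe *pairs* along the
sense strand. Each pair covers a 52-nt window: a 25-nt upstream binding site,
a 2-nt gap, and a 25-nt downstream binding site. Each synthesized oligo is
45 nt: an 18-nt initiator half, a 2-nt spacer, and the 25-nt binding region
(reverse complement of its window half), so amplification triggers only when
both oligos of a pair bind adjacently on the transcript.

Candidate windows are selected greedily 5'->3', keeping only windows whose
two assembled 45-mers pass the sequence filters (homopolymer run <= 3 by
default, optional GC band). Window and oligo geometry are configurable; the
defaults sum to the conventional 45-nt probe length.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TargetGene",
    "Amplifier",
    "ProbeWindow",
    "ProbePair",
    "ProbeSet",
    "DesignParams",
    "PLACEHOLDER_AMPLIFIERS",
    "load_targets",
    "revcomp",
    "max_homopolymer",
    "gc_fraction",
    "enumerate_windows",
    "assemble_pair",
    "design_probe_set",
    "design_panel",
    "write_design_report",
]

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (an involution)."""
    if not _VALID_SEQ.match(seq):
        raise ValueError(f"sequence contains characters outside ACGT: {seq!r}")
    return str(Seq(seq).reverse_complement())


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TargetGene:
    """One target mRNA/CDS: accession, common symbol, sense-strand sequence."""

    accession: str
    symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(f"{self.accession}: sequence not over ACGT")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplifier:
    """One orthogonal HCR amplifier (B1-B4).

    ``initiator_up``/``initiator_down`` are the two 18-nt halves of the
    amplifier's initiator, split across the two oligos of every pair. The
    true B1-B4 initiator sequences are vendor-defined and are supplied via
    configuration; :data:`PLACEHOLDER_AMPLIFIERS` ships synthetic stand-ins
    of the correct length for dry runs and testing.
    """

    id: str
    initiator_up: str
    initiator_down: str
    spacer_up: str = "AA"
    spacer_down: str = "TA"
    fluorophore: str | None = None
    excitation_nm: int | None = None
    emission_filter: str | None = None

    def __post_init__(self) -> None:
        if len(self.initiator_up) != 18 or len(self.initiator_down) != 18:
            raise ValueError(f"{self.id}: initiator halves must be 18 nt")
        if len(self.spacer_up) != 2 or len(self.spacer_down) != 2:
            raise ValueError(f"{self.id}: spacers must be 2 nt")


# Synthetic placeholder initiators (NOT the vendor B1-B4 sequences, which are
# not public): 18-nt, distinct, homopolymer runs <= 2 so they never trip the
# designer's own filters at the junctions.
PLACEHOLDER_AMPLIFIERS: dict[str, Amplifier] = {
    "B1": Amplifier("B1", "GAGGAGGGCAGCAAACGG", "GAAGAGTCTTCCTTTACG"),
    "B2": Amplifier("B2", "CCTCGTAAATCCTCATCA", "ATCATCCAGTAAACCGCC"),
    "B3": Amplifier("B3", "GTCCCTGCCTCTATATCT", "CCACTCAACTTTAACCCG"),
    "B4": Amplifier("B4", "CCTCAACCTACCTCCAAC", "TCTCACCATATTCGCTTC"),
}


@dataclass(frozen=True)
class ProbeWindow:
    """A 52-nt tiling window on the target sense strand (0-based start)."""

    start: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class ProbePair:
    window: ProbeWindow
    oligo_up: str
    oligo_down: str
    amplifier_id: str
    pair_index: int


@dataclass(frozen=True)
class ProbeSet:
    """All probe pairs for one target, sharing one amplifier.

    ``status`` is "ok" when 3-15 pairs survived the filters, otherwise
    "too_few_pairs" and the set is excluded from pooling/ordering.
    """

    target: TargetGene
    amplifier_id: str
    pairs: tuple[ProbePair, ...]
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DesignParams:
    """Geometry and filter settings for the designer.

    The window is ``site_len + gap_len + site_len`` nt (52 by default); each
    oligo is ``18 + 2 + site_len`` nt (45 by default).
    """

    site_len: int = 25
    gap_len: int = 2
    min_gap: int = 2
    min_pairs: int = 3
    max_pairs: int = 15
    max_homopolymer: int = 3
    gc_range: tuple[float, float] | None = None  # disabled by default

    @property
    def window_len(self) -> int:
        return 2 * self.site_len + self.gap_len


DEFAULT_PARAMS = DesignParams()


def _parse_header(description: str) -> tuple[str, str]:
    """Accession is the first token; symbol the second (or the accession)."""
    parts = description.split()
    accession = parts[0]
    symbol = parts[1] if len(parts) > 1 else accession
    return accession, symbol


def load_targets(
    source: str | Path | TextIO,
) -> tuple[list[TargetGene], list[dict]]:
    """Read targets from multi-record FASTA.

    U is mapped to T and case folded to upper. Records with characters
    outside ACGTU are rejected and reported, not fatal; an empty file or a
    duplicate accession raises ``ValueError``.

    Returns ``(targets, rejected)`` where each rejected entry is a dict with
    ``accession`` and ``reason``.
    """
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    targets: list[TargetGene] = []
    rejected: list[dict] = []
    seen: set[str] = set()
    for rec in records:
        accession, symbol = _parse_header(rec.description)
        if accession in seen:
            raise ValueError(f"duplicate accession: {accession}")
        seen.add(accession)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            rejected.append({"accession": accession, "reason": "empty sequence"})
            continue
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            rejected.append(
                {"accession": accession, "reason": f"invalid characters: {''.join(bad)}"}
            )
            continue
        targets.append(TargetGene(accession, symbol, seq))
    return targets, rejected


def assemble_pair(
    window: ProbeWindow,
    amplifier: Amplifier,
    pair_index: int = 0,
    params: DesignParams = DEFAULT_PARAMS,
) -> ProbePair:
    """Build the two 45-mers for one window.

    The upstream oligo carries the first initiator half followed by the
    reverse complement of the window's 3' binding site; the downstream oligo
    carries the reverse complement of the window's 5' site followed by the
    second initiator half. Spacers sit between initiator and binding region.
    """
    s = params.site_len
    site5 = window.sequence[:s]
    site3 = window.sequence[s + params.gap_len :]
    if len(site3) != s:
        raise ValueError("window length inconsistent with geometry")
    oligo_up = amplifier.initiator_up + amplifier.spacer_up + revcomp(site3)
    oligo_down = revcomp(site5) + amplifier.spacer_down + amplifier.initiator_down
    return ProbePair(window, oligo_up, oligo_down, amplifier.id, pair_index)


def _window_passes(
    window: ProbeWindow, amplifier: Amplifier, params: DesignParams
) -> bool:
    if "N" in window.sequence:
        return False
    pair = assemble_pair(window, amplifier, params=params)
    for oligo in (pair.oligo_up, pair.oligo_down):
        if max_homopolymer(oligo) > params.max_homopolymer:
            return False
        if params.gc_range is not None:
            lo, hi = params.gc_range
            if not lo <= gc_fraction(oligo) <= hi:
                return False
    return True


def enumerate_windows(
    target: TargetGene,
    amplifier: Amplifier,
    params: DesignParams = DEFAULT_PARAMS,
) -> list[ProbeWindow]:
    """Greedy 5'->3' selection of non-overlapping filter-passing windows.

    A window is accepted if both assembled oligos pass the filters; the scan
    then jumps ``window_len + min_gap`` downstream, otherwise advances 1 nt.
    """
    wlen = params.window_len
    seq = target.sequence
    windows: list[ProbeWindow] = []
    pos = 0
    while pos + wlen <= len(seq):
        cand = ProbeWindow(pos, seq[pos : pos + wlen])
        if _window_passes(cand, amplifier, params):
            windows.append(cand)
            pos += wlen + params.min_gap
        else:
            pos += 1
    return windows


def design_probe_set(
    target: TargetGene,
    amplifier: Amplifier,
    params: DesignParams = DEFAULT_PARAMS,
) -> ProbeSet:
    """Design one probe set: windows, pairs, size enforcement.

    At most ``max_pairs`` (15) pairs are kept, 5'-most first; a target
    yielding fewer than ``min_pairs`` (3) candidates gets status
    ``too_few_pairs`` and is excluded from ordering downstream.
    """
    windows = enumerate_windows(target, amplifier, params)[: params.max_pairs]
    pairs = tuple(
        assemble_pair(w, amplifier, i, params) for i, w in enumerate(windows)
    )
    status = "ok" if len(pairs) >= params.min_pairs else "too_few_pairs"
    return ProbeSet(target, amplifier.id, pairs, status)


def design_panel(
    targets: Sequence[TargetGene],
    amplifiers: dict[str, Amplifier] | None = None,
    params: DesignParams = DEFAULT_PARAMS,
) -> list[ProbeSet]:
    """Design probe sets for a panel, cycling amplifiers B1->B4 in input order.

    The round-robin assignment makes consecutive 4-target groups directly
    poolable (distinct amplifiers within each pool of four).
    """
    amplifiers = amplifiers or PLACEHOLDER_AMPLIFIERS
    order = sorted(amplifiers)
    return [
        design_probe_set(t, amplifiers[order[i % len(order)]], params)
        for i, t in enumerate(targets)
    ]


def write_design_report(sets: Iterable[ProbeSet], path: str | Path) -> dict:
    """JSON design report: per-target status, pair count, window coordinates
    (0-based half-open)."""
    report = {
        "targets": [
            {
                "accession": ps.target.accession,
                "symbol": ps.target.symbol,
                "amplifier": ps.amplifier_id,
                "status": ps.status,
                "n_pairs": len(ps.pairs),
                "windows": [[p.window.start, p.window.end] for p in ps.pairs],
            }
            for ps in sets
        ]
    }
    Path(path).write_text(json.dumps(report, indent=2))
    return report
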