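"""Concentration/volume bookkeeping for the miniaturized assay.

Every liquid-handling stage of the protocol — probe-pool resuspension, the
two-step serial dilution into consumable probe plates, the hairpin master
mix and its amplification-stage dilutions, and the wash sequences — is
modelled as a chain of dilution steps. All arithmetic is exact (rational);
concentrations are truncated (not rounded) only at reporting, matching how
protocol write-ups conventionally print them (20*5/15 nM -> "6.66").

Default parameters reproduce the reference protocol: 100 pmol per oligo
resuspended in 100 µl (1 µM), 10+90 µl primary dilution (100 nM), 20+80 µl
intermediate (20 nM), 5 µl consumable aliquots (20 plates per intermediate
well), hybridization with 10 µl sample (6.66 nM final in 15 µl); eight
hairpin species pooled from 100 µl each at 3 µM (375 nM), diluted 25+70 µl
(98 nM) and delivered 12 µl into 10 µl sample (53 nM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .pool_plate import PlateMap

__all__ = [
    "DilutionStep",
    "ReactionPlan",
    "HairpinMixPlan",
    "ProbeChainParams",
    "HairpinParams",
    "WashStage",
    "WashParams",
    "HandlingParams",
    "dilute",
    "truncate",
    "probe_chain",
    "hairpin_chain",
    "wash_plan",
    "emit_worklist",
]

Number = int | float | Fraction


def dilute(c_in: Number, v_transfer: Number, v_diluent: Number) -> Fraction:
    """Concentration after mixing ``v_transfer`` of stock at ``c_in`` with
    ``v_diluent`` of buffer. Exact rational result."""
    c_in, v_t, v_d = Fraction(c_in), Fraction(v_transfer), Fraction(v_diluent)
    if v_t <= 0 or v_d < 0:
        raise ValueError("transfer volume must be positive, diluent nonnegative")
    if c_in < 0:
        raise ValueError("concentration must be nonnegative")
    return c_in * v_t / (v_t + v_d)


def truncate(value: Number, ndigits: int = 0) -> float:
    """Truncate toward zero at ``ndigits`` decimals (98.68 -> 98; 6.666 -> 6.66)."""
    scaled = Fraction(value) * 10**ndigits
    trunc = int(scaled)  # int() truncates toward zero
    return trunc / 10**ndigits if ndigits else float(trunc)


@dataclass(frozen=True)
class DilutionStep:
    """One mixing event: c_out = c_in * v_transfer / (v_transfer + v_diluent)."""

    label: str
    c_in_nM: Fraction
    v_transfer_ul: Fraction
    v_diluent_ul: Fraction

    @property
    def c_out_nM(self) -> Fraction:
        return dilute(self.c_in_nM, self.v_transfer_ul, self.v_diluent_ul)

    @property
    def v_total_ul(self) -> Fraction:
        return self.v_transfer_ul + self.v_diluent_ul


@dataclass
class ReactionPlan:
    """Chained dilution steps plus reported (truncated) concentrations."""

    steps: list[DilutionStep]
    aliquot_plates: int
    aliquot_volume_ul: Fraction
    reported: dict[str, float] = field(default_factory=dict)

    def validate_chain(self) -> None:
        """Connected steps must hand their output concentration to the next."""
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.c_in_nM != prev.c_out_nM:
                raise ValueError(
                    f"chain broken between {prev.label!r} and {nxt.label!r}: "
                    f"{prev.c_out_nM} != {nxt.c_in_nM}"
                )

    @property
    def final_concentration_nM(self) -> Fraction:
        return self.steps[-1].c_out_nM

    @property
    def final_volume_ul(self) -> Fraction:
        return self.steps[-1].v_total_ul

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "label": s.label,
                    "c_in_nM": float(s.c_in_nM),
                    "v_transfer_ul": float(s.v_transfer_ul),
                    "v_diluent_ul": float(s.v_diluent_ul),
                    "c_out_nM": float(s.c_out_nM),
                }
                for s in self.steps
            ],
            "aliquot_plates": self.aliquot_plates,
            "aliquot_volume_ul": float(self.aliquot_volume_ul),
            "reported": self.reported,
        }


@dataclass(frozen=True)
class ProbeChainParams:
    """Probe-side defaults (pmol, µl)."""

    pmol_per_oligo: Fraction = Fraction(100)
    resuspend_ul: Fraction = Fraction(100)
    primary_transfer_ul: Fraction = Fraction(10)
    primary_diluent_ul: Fraction = Fraction(90)
    intermediate_transfer_ul: Fraction = Fraction(20)
    intermediate_diluent_ul: Fraction = Fraction(80)
    aliquot_ul: Fraction = Fraction(5)
    sample_ul: Fraction = Fraction(10)


def probe_chain(params: ProbeChainParams | None = None) -> ReactionPlan:
    """Resuspension -> primary -> intermediate -> consumable aliquots ->
    hybridization. Defaults give 1 µM -> 100 -> 20 -> 6.66 nM (truncated) in
    15 µl, with 20 consumable plates per intermediate well."""
    p = params or ProbeChainParams()
    # 100 pmol in 100 µl = 1 pmol/µl = 1 µM = 1000 nM
    stock_nM = p.pmol_per_oligo / p.resuspend_ul * 1000
    steps = [
        DilutionStep("resuspend", stock_nM, p.resuspend_ul, Fraction(0)),
        DilutionStep("primary", stock_nM, p.primary_transfer_ul, p.primary_diluent_ul),
    ]
    steps.append(
        DilutionStep(
            "intermediate",
            steps[-1].c_out_nM,
            p.intermediate_transfer_ul,
            p.intermediate_diluent_ul,
        )
    )
    intermediate_volume = steps[-1].v_total_ul
    n_plates = intermediate_volume / p.aliquot_ul
    if n_plates.denominator != 1:
        raise ValueError("intermediate volume not divisible into aliquots")
    steps.append(
        DilutionStep("hybridization", steps[-1].c_out_nM, p.aliquot_ul, p.sample_ul)
    )
    plan = ReactionPlan(
        steps=steps,
        aliquot_plates=int(n_plates),
        aliquot_volume_ul=p.aliquot_ul,
        reported={
            "stock_uM": truncate(stock_nM / 1000, 2),
            "primary_nM": truncate(steps[1].c_out_nM, 2),
            "intermediate_nM": truncate(steps[2].c_out_nM, 2),
            "hybridization_nM": truncate(steps[3].c_out_nM, 2),
        },
    )
    plan.validate_chain()
    return plan


@dataclass(frozen=True)
class HairpinParams:
    """Hairpin master mix defaults: H1 and H2 for each of four amplifiers."""

    n_species: int = 8
    v_each_ul: Fraction = Fraction(100)
    c_stock_nM: Fraction = Fraction(3000)  # 3 µM
    mix_transfer_ul: Fraction = Fraction(25)
    mix_diluent_ul: Fraction = Fraction(70)
    delivery_ul: Fraction = Fraction(12)
    sample_ul: Fraction = Fraction(10)


@dataclass
class HairpinMixPlan:
    """Per-species concentration at master mix, amplification dilution and
    in-well stages; snap-cooling is an annotation, not a dilution."""

    params: HairpinParams
    master_mix_nM: Fraction
    amplification_nM: Fraction
    in_well_nM: Fraction
    reported: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_species": self.params.n_species,
            "master_mix_nM": float(self.master_mix_nM),
            "amplification_nM": float(self.amplification_nM),
            "in_well_nM": float(self.in_well_nM),
            "reported": self.reported,
        }


def hairpin_chain(params: HairpinParams | None = None) -> HairpinMixPlan:
    """Pool n species -> dilute in amplification buffer -> deliver to sample.

    Defaults: 8 x 100 µl at 3 µM pooled (each species 375 nM), 25 µl mix +
    70 µl buffer (98 nM reported), 12 µl into 10 µl sample (53 nM reported).
    Stage-2/3 values are truncated to integer nM for reporting.
    """
    p = params or HairpinParams()
    if p.n_species < 1:
        raise ValueError("need at least one hairpin species")
    # Pooling: each species' 100 µl is diluted into the combined volume.
    master = dilute(p.c_stock_nM, p.v_each_ul, (p.n_species - 1) * p.v_each_ul)
    amplification = dilute(master, p.mix_transfer_ul, p.mix_diluent_ul)
    in_well = dilute(amplification, p.delivery_ul, p.sample_ul)
    return HairpinMixPlan(
        params=p,
        master_mix_nM=master,
        amplification_nM=amplification,
        in_well_nM=in_well,
        reported={
            "master_mix_nM": truncate(master),
            "amplification_nM": truncate(amplification),
            "in_well_nM": truncate(in_well),
        },
    )


@dataclass(frozen=True)
class WashStage:
    name: str
    count: int = 3
    volume_ul: float = 135.0
    temperature_c: float = 21.0
    settle_min: float = 30.0


@dataclass(frozen=True)
class WashParams:
    pre_amplification: tuple[WashStage, ...] = (
        WashStage("probe_wash_buffer", 3, 135.0, 37.0, 30.0),
        WashStage("5xSSCT", 3, 135.0, 21.0, 30.0),
    )
    post_amplification: tuple[WashStage, ...] = (
        WashStage("5xSSCT_post", 3, 135.0, 21.0, 30.0),
    )
    residual_ul: float = 15.0  # well volume left after the final pre-amp wash
    hoechst_ug_per_ml: float = 10.0
    hoechst_min: float = 30.0


def wash_plan(params: WashParams | None = None) -> dict:
    """Expand wash stages into an ordered step list with cumulative time.

    Each wash is add-volume / settle / remove; the tracked residual volume
    after the final pre-amplification wash is what the amplification stage
    builds on (15 µl by default).
    """
    p = params or WashParams()
    steps: list[dict] = []
    t = 0.0

    def expand(stages: Sequence[WashStage], phase: str) -> None:
        nonlocal t
        for stage in stages:
            if stage.settle_min < 0:
                raise ValueError("negative settle time")
            for i in range(stage.count):
                t += stage.settle_min
                steps.append(
                    {
                        "phase": phase,
                        "buffer": stage.name,
                        "wash_index": i + 1,
                        "volume_ul": stage.volume_ul,
                        "temperature_c": stage.temperature_c,
                        "settle_min": stage.settle_min,
                        "cumulative_min": t,
                    }
                )

    expand(p.pre_amplification, "pre_amplification")
    pre_total = t
    expand(p.post_amplification, "post_amplification")
    if p.hoechst_min > 0:
        t += p.hoechst_min
        steps.append(
            {
                "phase": "stain",
                "buffer": "5xSSCT+Hoechst",
                "wash_index": 1,
                "volume_ul": 135.0,
                "concentration_ug_per_ml": p.hoechst_ug_per_ml,
                "temperature_c": 21.0,
                "settle_min": p.hoechst_min,
                "cumulative_min": t,
            }
        )
    return {
        "steps": steps,
        "pre_amplification_settle_h": pre_total / 60.0,
        "residual_ul": p.residual_ul,
        "total_min": t,
    }


@dataclass(frozen=True)
class HandlingParams:
    """Liquid-handling metadata attached to every worklist step."""

    aspirate_ul_per_s: float = 10.0
    dispense_ul_per_s: float = 200.0
    tip_height_mm: float = 3.0


def emit_worklist(
    plan: ReactionPlan,
    plates: Sequence[PlateMap],
    hairpins: HairpinMixPlan | None = None,
    handling: HandlingParams | None = None,
) -> list[dict]:
    """Declarative per-well liquid-handling steps for the hybridization and
    amplification stages. Machine-readable (JSON-serializable), not
    robot-executable; handling speeds/heights ride along as metadata.
    """
    h = handling or HandlingParams()
    meta = {
        "aspirate_ul_per_s": h.aspirate_ul_per_s,
        "dispense_ul_per_s": h.dispense_ul_per_s,
        "tip_height_mm": h.tip_height_mm,
    }
    hyb = plan.steps[-1]
    records: list[dict] = []
    for plate in plates:
        for well in sorted(plate.layout, key=lambda w: (w[0], int(w[1:]))):
            records.append(
                {
                    "step": "preplate_probe_aliquot",
                    "source": "intermediate_probe_plate",
                    "destination_plate": plate.plate_id,
                    "destination_well": well,
                    "volume_ul": float(hyb.v_transfer_ul),
                    **meta,
                }
            )
            records.append(
                {
                    "step": "hybridization_sample_transfer",
                    "source": "bulk_reagent_plate/embryos",
                    "destination_plate": plate.plate_id,
                    "destination_well": well,
                    "volume_ul": float(hyb.v_diluent_ul),
                    **meta,
                }
            )
            if hairpins is not None:
                records.append(
                    {
                        "step": "amplification_hairpin_delivery",
                        "source": "consumable_amplifier_plate",
                        "destination_plate": plate.plate_id,
                        "destination_well": well,
                        "volume_ul": float(hairpins.params.delivery_ul),
                        **meta,
                    }
                )
    return records


def write_plan_json(
    path: str | Path,
    probe: ReactionPlan,
    hairpins: HairpinMixPlan,
    washes: dict | None = None,
    worklist: list[dict] | None = None,
) -> dict:
    doc = {
        "probe_chain": probe.to_dict(),
        "hairpin_chain": hairpins.to_dict(),
    }
    if washes is not None:
        doc["washes"] = washes
    if worklist is not None:
        doc["worklist"] = worklist
    Path(path).write_text(json.dumps(doc, indent=2))
    return doc
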