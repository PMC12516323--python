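# hcrkit

Toolkit for running miniaturized, automated, multiplexed **HCR RNA-FISH
screens** end to end on the dry-lab side: design split-initiator probe pools
for hundreds of mRNA targets, plan every dilution and liquid-handling step of
a plate-based assay, predict the scale of the confocal imaging run, and
post-process the resulting mountain of single-plane TIFFs into annotated,
demultiplexed per-gene images.

It is written for labs that screen spatial expression patterns at scale —
e.g. 192 targets across a 96-well plate, four genes multiplexed per well via
the orthogonal B1–B4 hairpin amplifiers — and for anyone who needs the same
bookkeeping on synthetic data first: a built-in simulator generates random
transcriptomes and complete fake imaging runs with known ground truth.

## What it computes

**Probe design.** Each target is tiled 5'→3' with up to 15 non-overlapping
52-nt windows (25-nt site + 2-nt gap + 25-nt site). Every window yields a
probe *pair* of two 45-nt oligos:

```
oligo_up   = initiator_up(18) + spacer(2) + revcomp(window[27:52])
oligo_down = revcomp(window[0:25]) + spacer(2) + initiator_down(18)
```

Both assembled oligos must keep homopolymer runs ≤ 3 nt; targets yielding
fewer than 3 pairs are flagged and excluded. Four probe sets with distinct
amplifiers form one pool = one well, so each of the four probe channels in a
well reports one gene.

**Reaction planning.** All concentrations are tracked as exact rationals and
truncated only for display. The default plan reproduces the reference
protocol: 100 pmol/oligo in 100 µl (1 µM) → 10+90 µl (100 nM) → 20+80 µl
(20 nM) → twenty 5-µl consumable aliquots → +10 µl sample = **6.66 nM per
probe in 15 µl**; hairpins: 8 species × 100 µl at 3 µM pooled (**375 nM**
each) → 25+70 µl (**98 nM**) → 12 µl into 10 µl sample (**53 nM**).

**Imaging planning.** Image count = sites × z-slices × wells × channels; the
default 3×3 center block of a 9×9 site grid, 48 wells, 5 channels gives
75,600 / 86,400 / 118,800 / 97,200 images for 35 / 40 / 55 / 45 z-slices.

**Image processing.** Filename parsing (configurable dialect), per-stack
maximum-intensity projection, abutting 2×2/3×3 stitching, additive
pseudocolor composition (the unmodified channel images *are* the
demultiplexed per-gene outputs), margin text annotation with
`symbol — accession` resolved through plate map → pool → amplifier →
wavelength, and center-site scoring-image selection.

## Worked example

```sh
hcrkit simulate transcriptome -n 192 --seed 7 -o targets.fa
hcrkit pool -i targets.fa -o panel/
hcrkit plan --defaults -o plan.json
```

The `plan` command prints the reported concentrations of the default plan:

```json
{
  "stock_uM": 1.0,
  "primary_nM": 100.0,
  "intermediate_nM": 20.0,
  "hybridization_nM": 6.66,
  "master_mix_nM": 375.0,
  "amplification_nM": 98.0,
  "in_well_nM": 53.0
}
```

i.e. each probe ends at 6.66 nM during hybridization and each hairpin at
53 nM during amplification. `panel/` now holds the synthesis order sheet
(one row per 45-mer), the plate map (48 pools, wells A1–D12) and the channel
map. A full simulated screen can then be generated and processed:

```sh
hcrkit simulate run --wells 4 --sites 4 --slices 5 --seed 3 --out run/
hcrkit process --input run/ --platemap panel/platemap.csv --out processed/
```

which writes per-channel and composite TIFFs plus `report.json` with each
well's gene labels and scoring site.

## Layout

| module | role |
| --- | --- |
| `hcrkit.probe_design` | windows, filters, split-initiator pair assembly |
| `hcrkit.pool_plate` | pooling, plate maps, order sheets, channel maps |
| `hcrkit.reaction_planner` | dilution chains, wash plans, worklists |
| `hcrkit.imaging_plan` | run-scale arithmetic, center-site selection |
| `hcrkit.image_pipeline` | sort/project/stitch/demultiplex/annotate |
| `hcrkit.simulate` | synthetic transcriptomes and ground-truth runs |
| `hcrkit.cli` | `hcrkit design/pool/plan/imaging-plan/simulate/process` |

See `docs/methods.md` for modelling assumptions and design choices.
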