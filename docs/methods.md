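# Methods

## Probe design model

A split-initiator probe pair detects a target only when both oligos bind
adjacently: each oligo carries half of an amplifier initiator, so hairpin
polymerization — and hence signal — requires the juxtaposition of both
halves on the transcript. The designer models this with a fixed geometry:

- **window**: 52 nt on the sense strand = 25-nt upstream site + 2-nt gap +
  25-nt downstream site;
- **oligo**: 45 nt = 18-nt initiator half + 2-nt spacer + 25-nt binding
  region (the reverse complement of its window half).

The 45-nt total and the homopolymer cap (runs ≤ 3 nt, applied to the full
assembled oligo, since that is what gets synthesized) are the fixed
constraints; binding-site length, gap, spacer bases (`AA`/`TA`) and which
oligo carries which initiator half are conventions of this package and all
configurable. Candidate selection is greedy 5'→3' with a 2-nt minimum
inter-window gap: deterministic, and close to maximal pair counts on short
CDS inputs. Set size is capped at 15 pairs; fewer than 3 surviving windows
marks the target `too_few_pairs` and excludes it from ordering. A GC-band
filter exists but is off by default. Degenerate bases (N) reject a window
rather than being expanded.

The B1–B4 initiator sequences are vendor-defined and not public; the shipped
`PLACEHOLDER_AMPLIFIERS` are synthetic 18-mers of correct length (labelled
as such) intended for dry runs and tests. Real screens supply their own
amplifier definitions.

Out of scope by design: thermodynamic modelling (Tm, secondary structure),
off-target screening, isoform-aware placement.

## Pooling and plate conventions

Pool membership follows input FASTA order in chunks of four; amplifiers are
assigned round-robin B1→B4 at design time so every chunk carries distinct
amplifiers. Wells fill row-major from A1 (48 pools end at D12); overflow
past 96 wells starts a new plate. Oligo names use a reversible grammar,
`pool__accession__amplifier__pNN__strand`, so order sheets can be parsed
back without side tables.

The default channel map pairs B1→Cyanine7 (740 nm ex, 794/32 em),
B2→Alexa Fluor 647 (640, 680/42), B3→Alexa Fluor 594 (555, 624/40),
B4→ATTO 532 (520, 562/40), plus Hoechst 33342 (405, 452/45) for nuclei.
Filename channel indices w1…w5 follow descending excitation, so w5 is the
nuclear channel. Demultiplexing is the composition
well → pool → amplifier → wavelength, which is total and unique for every
occupied well's probe channels.

## Reaction planning

All volumes and concentrations are `fractions.Fraction`; solute mass is
conserved exactly across splits, and chain connectivity (each step's input
concentration equals the previous step's output) is validated. Reported
values are **truncated**, not rounded — 20·5/15 = 6.666… prints as 6.66,
375·25/95 = 98.68… as 98, and ·12/22 = 53.8 as 53 — matching the
convention of the protocol the defaults encode. The hairpin master mix
assumes 8 species (H1 and H2 for each of four amplifiers); snap-cooling is
an annotation, not a dilution. The post-amplification SSCT wash count
defaults to 3 and is configurable, as are the shaker settings (500 rpm for
5 min by default; an alternative convention of 450 rpm for 30 min exists and
can be configured). Worklists are declarative JSON records carrying the
liquid-handling metadata (aspirate 10 µl/s, dispense 200 µl/s, 3-mm tip
height); generating vendor-executable robot protocols is out of scope.

## Imaging-run arithmetic

`n_images = sites × slices × wells × channels`. Z-coverage uses the
slices × interval convention (35 slices at 2 µm → 70 µm), consistent with
the run arithmetic the defaults reproduce. Site indices are 1-based,
row-major from the top-left of the 9×9 grid; the central 3×3 block is
{31,32,33,40,41,42,49,50,51} with 41 the exact center. The "center" 2×2 of
an odd grid is ambiguous; the fixed convention is upper-left-of-center
({31,32,40,41}), which nests inside the 3×3 block. Data volume uses
2×10⁶ bytes per image (decimal GB), the effective per-plane size of the
reference acquisitions; it is configurable.

## Image pipeline

Stitching is plain abutment in grid row-major order — high-content stages
are coordinate-calibrated, so no overlap/registration is attempted; a
missing tile is zero-filled and flagged. Maximum projection is the per-pixel
max across z (idempotent, z-order invariant). Composition is additive RGB
with clipping at the dtype limit; the unmodified per-channel inputs are the
demultiplexed outputs. Annotation renders text into a reserved margin
*above* the raster so the scientific pixels remain untouched. The scoring
image per well is the central site (41 by default), with an optional
largest-foreground-area fallback when the center tile is missing. The whole
pipeline is deterministic: identical inputs and configuration give
byte-identical outputs. Positive/negative expression calling is explicitly
not implemented — "discernible from background" is a visual judgement, and
any automated score would be an extension, not a reproduction.

## Synthetic data

`synth_transcriptome` draws i.i.d. bases at a requested GC fraction with
lengths uniform in range; defaults (192 records, 300–3000 nt, GC 0.40)
produce panels on which the designer yields full 48-pool plates.

`synth_run` emulates run *structure*: the full file lattice (wells × center
sites × z × channels), parseable filenames, and a manifest recording every
file and every planted truth. The pixel model is deliberately simple —
filled-disk "embryos" in the nuclear channel, isotropic Gaussian spots
(amplitude 3000, σ 1.2 px on a background of mean 100, σ 10, uint16) in
expressing probe channels only, a triangular intensity profile across z
peaking mid-stack, and Gaussian background noise. Spots are planted on a
coarse grid (10-px cells, 3-px center jitter) so they are at least 8 px
apart and remain individually countable after projection; a threshold +
connected-components counter recovers planted counts within 10% when spot
amplitude ≥ 5× background σ. Expression truth per (well, probe channel) is
Bernoulli(0.5), emulating a screen in which roughly half the probes give
clear signal. Tiles default to 128×128 px: geometry and bookkeeping, not
image content, are what downstream code exercises, so small rasters keep
even full-lattice runs (97,200 planes) tractable on one CPU.

What passing on synthetic runs does **not** show: robustness to real
morphology (blastula/gastrula/pluteus shapes), optical PSFs, Poisson photon
noise, stage drift, autofocus failures, or uneven illumination — none are
modelled.

## Numerical and degenerate-input choices

- Exact rational arithmetic for all concentration chains; floats only at
  reporting boundaries. Truncation (toward zero) at reporting, never
  rounding.
- Greedy window scan advances 1 nt on a filter failure and
  `window + min_gap` on acceptance; ties cannot arise.
- Scoring-image fallback breaks foreground-area ties toward the lowest site
  index.
- Empty inputs: zero probe sets → zero pools; an empty plate map → an empty
  worklist; an empty image directory → an empty grouping; a single-plane
  stack projects to itself.
- Duplicate accessions, duplicate planes (same well/site/channel/z) and
  duplicate excitation wavelengths are hard errors; unparseable filenames
  and records with non-ACGTU characters are skipped and reported.

## Problem sizes used in the shipped checks

Designer properties run on 100 seeded random targets (300–3000 nt);
pooling/plate arithmetic on a 192-target panel; the end-to-end screen check
on the full 48 × 9 × 45 × 5 lattice at 128×128 px; the acceptance script's
screen uses the same 48-well, 9-site structure at 9 z-slices and 64×64 px,
since annotation agreement is bookkeeping and independent of raster scale.
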