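# amphihap

Detecting hybrids from shotgun sequencing in the water smartweed complex
(*Persicaria amphibia* s.l.) — and in any system like it where two close
relatives and their hybrids co-occur.

## The problem

Hybridisation between a short, aquatic taxon ("stipulacea"-type) and a
tall, terrestrial one ("coccinea"-type) produces plants with the tall
parent's looks but the aquatic parent's maternally inherited chloroplast
genome. Three independent evidence channels expose this *cyto-nuclear
discordance*:

1. **ITS2 haplotype composition.** The nuclear ribosomal DNA cistron is
   tandemly repeated; in hybrids and polyploids concerted evolution is
   incomplete, so one individual carries several ITS2 sequence variants at
   skewed frequencies. Every shotgun read that fully spans a fixed 133 bp
   ITS2 window is one observation of one repeat copy; exact-sequence
   counting over ~1000 spanning reads estimates the within-individual
   mixture (e.g. a dominant haplotype near 88%).
2. **Plastome IGS length markers.** Two plastome types diverged by ~0.3%
   differ by occasional indels concentrated in intergenic spacers (IGS).
   Ranking homologous spacers by size difference and amplifying the best
   two gives a gel-resolvable assay for the plastid type (calls A / B /
   both / none).
3. **Morphology.** A four-field key: inflorescence shape, flared ocreae,
   leaf shape, plant height.

A sample whose three channels agree is a parental; any disagreement among
determinate channels marks a hybrid, and the plastid channel names the
maternal parent. The package also computes the standard alignment
statistics used alongside such studies: constant / parsimony-informative
site counts and pairwise-deletion p-distances

For the ITS2 tally, "fully spans" is operationalised as anchored-pattern
containment: the read (or its reverse complement) must contain the 8 bp
flanking anchors on both sides of the window, separated by exactly the
window length, with at most one mismatch per anchor. Rare variants below
a noise floor (count < max(2, 0.5% of spanning reads)) are pooled into an
"other" bin.

Because the original raw data are not bundled, a first-class synthetic
generator (`amphihap.simulate`) reproduces the study conditions — skewed
haplotype mixtures, 2×150 bp reads with substitution errors, plastome
pairs with planted IGS indels, cohorts with planted hybrids — and records
truth tables, so every stage is testable end to end.

## Worked example

`python examples/01_its2_tally.py` simulates one library (three planted
haplotypes at 88/10/2%, ~1000 window-spanning reads, error-free) and
tallies it:

```
reads simulated:      226406
window-spanning reads: 954
  Hap1: recovered  90.9%   truth  90.9%
  Hap2: recovered   7.5%   truth   7.5%
  Hap3: recovered   1.6%   truth   1.6%
```

The recovered percentages are the shares of spanning reads carrying each
exact 133 bp sequence; with error-free reads they equal the generator's
own bookkeeping read for read (the realised draw 90.9/7.5/1.6 is the
multinomial sample around the planted 88/10/2 mixture). The other
examples cover marker discovery and genotyping (`02_igs_markers.py`),
alignment statistics (`03_alignment_stats.py`) and full-cohort hybrid
classification (`04_hybrid_cohort.py`). A thin CLI (`amphihap simulate |
tally | markers | pcr | alnstats | classify`) wraps the same functions
for shell use.

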