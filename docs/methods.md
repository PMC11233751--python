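# Methods

## ITS2 haplotype tallying

The nuclear ribosomal repeat (≈5.9 kb unit by default) carries a 133 bp
ITS2 window. In a polyploid or hybrid individual the tandem copies are not
homogenised, so the window exists in several sequence variants within one
genome. Deep shotgun data samples repeat copies roughly uniformly, so the
empirical distribution of exact window sequences over spanning reads
estimates the within-individual haplotype mixture.

**Spanning criterion.** A read counts only if it contains the complete
window *and* its immediate context: the `anchor_len` (default 8) reference
bases on each side, separated by exactly the window length, with at most
`max_anchor_mismatch` (default 1) mismatches per anchor. The read and its
reverse complement are both searched and a reverse-strand hit is
canonicalised to reference orientation. Anchors make "fully encompasses
the window" testable and strand-safe; `locate_window` refuses anchors
that are not unique in the reference. With 150 bp reads and an 8 bp
anchor the anchored span is 149 bp, so essentially only reads centred on
the window qualify — this is the operative definition of the sequencing
depth "n spanning reads", not a limitation.

**Counting and noise floor.** Counting is exact-sequence: no quality
weighting, no denoising model, mate pairs treated as independent reads,
segments containing N discarded. Variants with count below
`max(min_count, min_freq × total_spanning)` (defaults 2 and 0.5%) are
pooled into an `other` bin; the floor is sized so that a ~1000-read
library at ~1% per-base error does not call spurious haplotypes.
Surviving variants are matched to a named catalog exactly
(`max_mismatch=0` by default; a tolerance is available, and a variant
within tolerance of two catalog entries is an error, not a guess);
unmatched survivors become `Novel1..K` in descending count order.
Indel-bearing window copies are excluded by default and can be retained
as length variants with `keep_length_variants`.

**Reported frequencies.** A profile carries two scales: counts over all
spanning reads (including `other`), and the renormalised composition over
named haplotypes only — the pie-chart convention. Because sequencing
errors hit all haplotypes at the same per-base rate, renormalisation
keeps the named shares unbiased; but at error rate e only about
(1−e)^133 of windows are error-free, so the *effective* depth behind the
renormalised shares is roughly that fraction of the spanning count. At
e = 0.01 and 1000 spanning reads the effective depth is ≈260 reads,
giving a standard error near 2 percentage points for an 88% haplotype —
recovered compositions at that error rate should be read with that
uncertainty in mind (the acceptance suite documents exactly this).

## Read simulation

Fragments take a uniform insert length of 250–450 bp (the library-prep
insert is not a quantity the analysis depends on, since tallying uses
single reads) and a uniform start on the template; mate 1 is the first
150 bp, mate 2 the reverse complement of the last 150 bp. Each fragment
samples one haplotype from the mixture — one molecule, one repeat copy —
and both mates come from that molecule. Errors are substitutions only,
applied per base; real indel errors would break the exact-length window
contract and are deliberately out of scope (such reads are simply not
counted in real data either). Base qualities are constant Q30 because the
tally does not use them. The number of fragments is chosen by exact
enumeration of placement probabilities so that the expected number of
window-spanning reads meets the target; the truth table records the
realised per-haplotype counts of reads covering the anchored span, which
is the same criterion the tally applies — so on error-free data the tally
must reproduce the truth exactly, and does.

What the generator does *not* emulate: position- and cycle-dependent
Illumina error profiles, quality variation, PCR duplicates, coverage
bias, chimeric reads, and rDNA copy-number variation between loci.
Passing tests therefore demonstrate correctness of the counting machinery
and statistical behaviour under idealised noise, not robustness to every
real-library artefact.

## Plastome pair and IGS markers

Genome A (default 159,320 bp; 20 kb in the test suite) carries a synthetic
annotation of ten named genes, including the rpl20/rps12 and rpl33/rps18
neighbours, separated by intergenic spacers; gene and spacer lengths are
drawn once per seed. Genome B is A plus Bernoulli substitutions at
`plastome_snp_rate` (default 0.003, the divergence scale of the two
plastome types) plus planted insertions in named spacers, so each
region's length delta equals its planted indel exactly and
len(B) − len(A) is their sum.

`derive_igs` names the spacer between consecutive genes "geneL-geneR",
skips overlapping-gene gaps with a warning, and closes the circle with a
final lastGene-firstGene interval; on a fully partitioned genome gene
plus spacer lengths sum to the genome length (a conservation check in the
tests). `rank_markers` pairs spacers by name across genomes and sorts by
|ΔL| descending with lexicographic tie-break, making it input-order
invariant.

In-silico PCR uses the standard feasibility proxy: up to `max_mismatch`
(default 2) mismatches per primer, but the 3′-terminal five bases must
match exactly; products up to `max_product` (default 5 kb) from all
convergent primer orientations are reported sorted by length. Primer
design scans outward from the region boundaries for the nearest 20-mer
identical in both genomes — the computational analogue of designing an
assay that amplifies both plastome types. Genotyping compares observed
fragment lengths to the two expected sizes with a ±5 bp tolerance; if the
expected sizes differ by less than 10 bp (the resolution of a 1.2%
agarose gel) the marker is flagged unresolvable. Observing both sizes
yields "both" — the signature of a mixed population sample. Duplicate
binding sites (e.g. inside inverted repeats) are reported, not collapsed.

## Alignment statistics

Gaps and N are missing data. A column is constant when exactly one
determinate state occurs among its non-missing entries, parsimony
informative when at least two states each occur in at least two
sequences, otherwise variable-uninformative; all-missing columns are
counted separately, and the four classes partition the alignment exactly.
Distances are p-distances with pairwise deletion (only columns determinate
in both taxa are compared), the convention under which whole-plastome
percent divergences are normally quoted; a pair with no comparable column
gets NaN with a warning. Tree-inference software differs in how it counts
ambiguity codes, so counts from this module can differ from a tree
program's header by a few parts in ten thousand on gappy alignments.

## Hybrid classification

The morphology key uses four fields only: long cylindrical inflorescence
on a >30 cm plant → coccinea-type; short ovoid inflorescence on a <30 cm
plant → stipulacea-type; conflicting combinations → ambiguous (flared
ocreae reinforce the aquatic taxon but never decide alone).

ITS2 composition classes are called by diagnostic rules first — exactly
{Type1, US1} present → stipulacea; ≥4 haplotypes including both → northern
coccinea; ≥4 lacking both → southern coccinea — then by nearest reference
profile under Bray–Curtis dissimilarity (ambiguous on a tie or when the
nearest reference is farther than 0.5). The rules mirror the observed
compositions; Bray–Curtis is the conventional metric for relative
abundance vectors and replaces eyeballing pie-chart similarity.

Verdicts: collapse ITS2 classes onto taxa (coccinea_* → coccinea), drop
ambiguous channels, and require unanimity among the rest. Any
disagreement among determinate channels → hybrid — including an
ITS2-only conflict, because a nuclear signal of the other taxon cannot
arise in a pure parental — with the maternal parent read off the plastid
channel (maternal plastid inheritance; configurable off for paternally
inheriting groups) and the minority channels listed as discordant.
Unanimous-but-incomplete evidence yields a low-confidence parental;
discordance resting on an ambiguous plastid stays ambiguous, since no
maternal parent can be named. The rule's full finite input space is
checked against an independent restatement in the tests.

Known limitation: the verdict is binary parental/hybrid. Backcross
generations, admixture proportions and a "this parental-looking plant is
not the parent of *these* hybrids" geography argument are annotation-level
judgements outside the rule.

## Problem sizes and numerical choices

The test suite and acceptance script run the read simulator on a 600 bp
nrDNA carrier (window and flanks unchanged) and 20 kb plastomes: with a
149 bp anchored span, a ~1000-spanning-read library then needs ~2×10⁵
simulated reads instead of ~3×10⁶, while every planted parameter remains
identifiable. Cohort runs use 150–300 spanning reads per sample with
minor haplotype shares ≥4%, so the smallest expected named count is ≥6
and presence/absence rules are stable. Defaults everywhere else are the
study-scale values (5,868 bp reference, 159,320 bp plastome, 1000
spanning reads, mixture 0.88/0.10/0.02).

All randomness flows from a single integer seed through fixed stream
indices (`numpy` SeedSequence), so identical spec + seed reproduce
byte-identical FASTQ. Ambiguity codes other than N collapse to N on
input; tallying treats non-ACGT as unusable. Ties are broken
deterministically throughout (novel naming by descending count then
sequence; marker ranking by delta then name).
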