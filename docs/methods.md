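# Methods

## Scope and model

`toxinloss` decides, per gene × specimen, whether a member of a highly
similar toxin gene family is present and expressed, and if not, why —
whole-gene deletion (homozygous or heterozygous), chimeric gene fusion, or
a frame-disrupting indel. Three independent evidence layers are analysed
and fused, and the loss phenotype is tested for association with a
two-level geographic cohort. All coordinates are 0-based half-open
internally; GFF3 is converted at the I/O boundary; everything is on the
forward strand (no step of the analysis depends on strand).

## Synthetic data generator (`family_forge`)

The generator defines the study conditions the analysis is validated
against. It emulates a metalloproteinase-like complex, not read-level
sequencing: evidence is produced at the coordinate/count level (peptide
count tables, per-position depth tracks, BED12 spliced alignments,
haplotype contigs), which is the granularity the analysis consumes.

**Family.** All paralogs descend from one 13-exon template (exon layout:
signal, 2× pro, 6× metalloproteinase, 2× disintegrin, 2× cysteine-rich;
120 nt per exon, codon-aligned). Structural classes keep a prefix: P1 = 9
exons (metalloproteinase-only), P2 = 11 (+disintegrin), P3 = 13
(+cysteine-rich). Each gene is mutated at the codon level at a per-gene
rate drawn so pairwise *core* protein identities (the class-shared exons
1–9) land inside the configured band (default 0.88 ± 0.06); realized
identities are checked and the family resampled if any pair falls outside.
Identity across whole proteins of different classes is dominated by domain
content and is deliberately not what the band describes. The single P1
gene is the analysis target; a designated P3 gene adjacent to it is the
control locus and is never mutated by genotypes. "Hard regions" — the
near-identical segments where unambiguous mapping fails — are created by
copying metalloproteinase exons 5–6 of one P3 paralog into the target
verbatim, exactly reproducing the shared-exon mapping pathology. Desk
scale: 8 genes on a ~35 kb contig (introns 200 nt, intergenic 600 nt); a
30-gene preset approaches the real complex's scale.

**Genotypes.** The `atrox_like` preset places a fixed mutation inventory on
seed-shuffled specimens: west cohort — two homozygous deletions, one
homozygous fusion, one heterozygous deletion; east cohort — one homozygous
deletion, one heterozygous frameshift, two intact. This mirrors the
empirical situation the pipeline must resolve (loss concentrated in, but
not exclusive to, one cohort; carriers that still express). A `random`
mode draws loss alleles per haplotype at configurable per-cohort
frequencies. The fusion allele joins the P2 partner's exons 1–b to the
target's exons b+1..n (default breakpoint b = 6); the frameshift allele
inserts 1 nt at the midpoint of metalloproteinase exon 7.

**Evidence.** Peptide counts are Poisson with expectation
`peptide_yield × (TPM/1000) × allele_factor / 2` per tryptic-peptide
occurrence (defaults: yield 20 at 1000 TPM — saturating detection for an
intact gene; fusion transcript factor 0.05 — low residual expression of
the chimera). Contamination adds a fixed fraction (default 0.1%) of every
other specimen's expectation; the rate is a free parameter chosen once, as
no empirical value is established for instrument carry-over in this
setting. Transcript depth per reference-transcript position is Poisson
with the same dosage scaling (200× at 1000 TPM diploid); hard-region
positions are multiplied by 0.02, giving the diagnostic pattern of low but
nonzero depth in high expressors and exact zeros in low expressors.
Full-length alleles emit a sliding 3-exon window of assembled fragments
(linking every junction) plus three 5′/3′-jittered full-span isoform
reads; fusion alleles emit one chimeric fragment/read; deleted alleles
emit nothing (transcript-level index hopping defaults to off, so a
homozygous deletion has exactly zero unique coverage). Capture depth is
Poisson around `capture_depth × copies/2`, modulated by a per-125-nt-tile
Gamma efficiency (CV 0.2) so noise is spatially correlated at the bait
spacing. Contigs are the literal haplotype sequences per gene locus
(identical haplotypes collapse, as an assembler would).

Determinism: every operation draws from `numpy.random.default_rng` seeded
with (caller seed, per-operation stream constant), so identical config +
seed reproduce byte-identical output files.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: read-level errors and mapping ambiguity
beyond the hard-region model, assembly fragmentation/misassembly, partial
capture dropout, isoform diversity (alternative splicing is represented
only as block-structure differences in constructed tests), and search-
engine identification error in peptides.

## Peptide evidence

Tryptic digestion cleaves C-terminal to K/R except before P; peptides
shorter than 6 aa are dropped from matching (no missed cleavages, no I/L
equivalence, no modifications — identified peptide strings are taken at
face value; modification handling belongs to the search engine). A peptide
is exclusive-unique (EUP) iff it occurs as a substring of exactly one
family protein. Domain coverage is computed over *assignable*
metalloproteinase-domain positions — those overlapped by at least one
theoretical EUP of the gene — so conserved segments never enter the
denominator. States: NOT_DETECTED (no EUPs), PARTIAL_LOW (coverage < 0.50
and mean count < 2), EXPRESSED (coverage > 0.90 and mean count ≥ 5), else
INTERMEDIATE. The 0.50/0.90 cut-offs bracket the empirically observed
bimodal regimes; the never-observed middle regime is reported explicitly
rather than coerced. Count thresholds are config-exposed operational
choices.

## Transcript evidence

Zero regions are maximal zero-depth runs ≥ 10 bp (config; no principled
minimum exists, the value suppresses single-position sampling zeros).
High expressors for a transcript are the top half of specimens by total
mapped counts (min 1); a position is masked iff *every* high expressor's
depth there is ≤ 1× that specimen's median transcript depth. The
short-read vote is NO_FULL_LENGTH iff some zero region is not wholly
inside the mask, INCONCLUSIVE if all zero regions are masked, and
SUPPORTS_FULL with none. Tiling requires every coding exon overlapped and
every adjacent junction spanned by a fragment (consecutive blocks, or one
block covering both exons). Long reads merge when 5′ starts differ by
< 100 bp, 3′ ends by < 30 bp, and every interior block-structure
difference run is < 10 bp; clusters are connected components of this
relation (order-independent; transitive chains merge), and the consensus
is the longest member, unpolished. Final call: FULL_LENGTH iff an isoform
spans every coding exon, or tiling is complete and the short-read vote
does not positively contradict it; without long-read data the isoform
vote is ignored.

## Locus evidence

Copy state from the capture-depth ratio of target to control gene: ≤ 0.05
homozygous deletion, 0.30–0.70 heterozygous, ≥ 0.80 intact; values in the
gaps are AMBIGUOUS_RATIO, reported, never forced. The bands are
operational stand-ins for a qualitative judgement; the het band in
particular has no empirical calibration. A zero control mean is NO_DATA
(capture failure), never deletion.

Contig annotation: each reference exon is located on a contig by edlib
infix alignment (nucleotide level; candidates kept below 35% divergence),
then scored by amino-acid identity from an affine-gap BLOSUM62 alignment
of the translated segment (identical residues / exon length). Overlapping
candidates are resolved by score then length; a winner whose best rival
from another gene scores within 0.02 is reported *ambiguous* — exact
inter-paralog copies (hard exons) and individual exons with ≤ 1
substitution between paralogs land here, which is a property of the
family, not a defect of the method. Frame status comes from the alignment
path: indel runs confined to the outermost 3 alignment columns are
boundary artifacts (a substituted terminal base absorbed as a gap) and are
excluded; a net interior indel not divisible by 3 is a frameshift, a stop
codon in the (frame-corrected) translation a premature stop. Because the
translation downstream of an indel is garbage by construction,
frame-damaged candidates are attributed by their nucleotide match rather
than their amino-acid identity.

Fusion requires a run of ≥ 2 unambiguous calls to one non-target gene, all
identities ≥ 0.90, adjacent (skipping ambiguous calls) to a target call or
contig boundary, on a contig that also carries ≥ 1 target call — the last
condition prevents any intact paralog contig from trivially "fusing" with
a target it never touches. Disruption reports the first frame-damaged
metalloproteinase-domain exon; multiple frame-intact exons with identities
in [0.60, 0.98) instead flag a DIVERGENT_ALLELE (0.98 because same-gene
matches sit at ≥ 0.98; 0.60 mirrors the weakest attributable exon match).
Per gene × specimen, mechanism states are assigned only when *no* contig
carries a complete in-frame exon chain for the gene; heterozygous carriers
therefore keep their copy-ratio state with the mutant-contig report
retained as supporting evidence.

## Integration and association

Final status rules, in order: EXPRESSED iff protein EXPRESSED and
transcript FULL_LENGTH (and locus not HOM_DELETION — that combination is
CONFLICT); HOM_DELETION → LOST_DELETED; HET_DELETION without expressed
protein → LOST_DELETED; FUSION → LOST_FUSION; FRAMESHIFT without protein →
LOST_DISRUPTED; absent protein + no full-length transcript + intact or
missing locus → SILENCED_UNEXPLAINED; anything else CONFLICT. Carriers
(het deletion, het frameshift with expression) are EXPRESSED with a note —
they are not loss phenotypes in the association table.

The association uses the continuity-corrected (Yates) χ² with df = 1 on
the cohort × phenotype table; the correction is the default because it is
the statistic consistent with the published survey value (uncorrected on
the 7/8-vs-4/19 table gives ≈ 10.30, corrected ≈ 7.73), and the
uncorrected variant is available behind a flag. The printed statistic is
reported to two decimals (text and figure roundings of the same quantity
differ in their last digit: 7.73 vs 7.72). p-values are descriptive; no
automated decision uses them, and no multiple-testing control is applied
to the single pre-specified test. TPM summaries (count/length scaled to
1e6 per specimen, log2(TPM+1)) are descriptive only; differential
expression is out of scope.

## Problem sizes and numerical choices

The test suite and acceptance script use the desk-scale preset (8 genes ×
8 specimens, ~35 kb reference) — chosen so that a full simulate + analyse
replicate takes about one second — with 20 replicate seeds for the truth-
recovery properties (10 in the acceptance script). The 30-gene preset
exercises scale without being part of routine runs. Poisson sampling
everywhere; no pseudo-counts. Ties in clustering are resolved by connected
components; ties in exon attribution by the 0.02 ambiguity margin; empty
or degenerate inputs (no high expressors, zero control coverage, empty
specimen tables, zero-margin tables) raise typed errors or explicit flags
rather than silently degrading.

## Known limitations

Exon attribution operates at whole-exon granularity; breakpoints are
reported between exons, not at base resolution. Individual exons identical
between paralogs are intrinsically unattributable and appear as ambiguous
calls (they may shorten reported donor/target exon runs around a fusion
breakpoint). The mappability mask needs at least one genuinely
high-expressing specimen; in a cohort where every specimen has lost the
gene, absence calls from short reads alone are inconclusive by design.
The generator's noise model (Poisson counts, Gamma bait efficiency,
fixed-fraction contamination) is deliberately simple; conclusions about
robustness to structured real-world artifacts require real data.
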