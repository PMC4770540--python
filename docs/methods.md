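# Methods

`autozygmap` implements the classical mapping strategy for a rare recessive
defect observed in a handful of related individuals from a livestock
breeding population: autozygosity mapping from medium-density SNP-array
genotypes, followed by recessive-compatibility filtering of sequence
variants in the mapped interval and protein-level annotation of the
surviving candidate. This note records the models, parameter choices and
numerical conventions, and what the synthetic data can and cannot show.

## Study design and model

The design assumes an autosomal recessive trait segregating in a half-sib
family: a few affected males (cases), a larger cohort of unaffected
paternal half-sibs, and a pedigree loop through one common ancestor on both
the paternal and the maternal path of every case. Under this model each
case is autozygous — identical by descent on both haplotypes — across a
chromosomal segment around the causal allele, while unaffected half-sibs
carry at most one copy of the ancestral haplotype and are therefore not
homozygous across the same segment.

Mapping proceeds in two set operations on runs of homozygosity (ROH):

1. intersect the ROH of all cases (a candidate region must be homozygous
   in every affected animal), and
2. exclude any candidate region that is fully covered by an ROH of an
   unaffected relative (a healthy animal homozygous across the region
   contradicts the recessive model there).

Partial control overlap neither excludes nor trims a region: the exclusion
argument is region-level, and trimming by control ROH ends would import
noise from unrelated homozygosity.

## ROH definition

ROH are defined directly rather than through a scanning-window heuristic: a
run is a maximal stretch of consecutive markers, bounded on both ends by
homozygous calls, containing at most `max_het` heterozygous and
`max_missing` missing calls; it is reported when it holds at least
`min_snps` homozygous calls and spans at least `min_length_bp`.

Defaults: `min_snps = 20`, `min_length_bp = 500 kb`, `max_het = 0`,
`max_missing = 2`. The 20-SNP / 500-kb thresholds are the standard criteria
for sparse ~50k arrays with roughly one marker per 56 kb, where shorter or
thinner runs are too often chance homozygosity. No heterozygote is allowed
("contiguous homozygous"); two missing calls are tolerated because this
pipeline deliberately does not impute sporadically missing genotypes —
LD-based imputation is out of scope, and the small allowance recovers the
runs an imputing workflow would see. Segment boundaries are the outermost
homozygous SNPs, a conservative convention (no extension toward flanking
heterozygotes).

Two semantic choices close gaps the run definition leaves open:

- With a nonzero missing/het allowance, maximal candidate windows can
  overlap. Overlaps are resolved positionally — the leftmost maximal window
  wins — *before* the SNP-count and length thresholds are applied, so
  raising a threshold can only remove runs, never surface different ones
  (monotonicity), and reported segments never overlap.
- The scanner is cross-checked against an exhaustive enumeration over all
  marker sub-intervals on randomized instances.

## Genotype quality control

Markers off autosomes 1–29 (X, Y, mitochondrial, unplaced) are removed
first. The call-rate filter removes markers, then individuals, below a 90 %
call rate; since each removal changes the other dimension's call rates, the
two passes repeat until a fixed point, making the filter idempotent. The
Hardy-Weinberg filter removes markers with exact-test p <= 1e-4.

The HWE test is the exact conditional test (enumeration of heterozygote
counts given allele counts, two-sided by summing configurations no more
likely than the observed one), computed in log-gamma space. A chi-square
approximation would be unreliable at the cohort sizes this design uses
(about 21 genotyped animals); the exact test is well defined at any size.
Monomorphic markers return p = 1.

## Variant filtering

Within a mapped region, a site is *recessive-compatible* when every case is
homozygous for the alternate allele and every called control is homozygous
reference. Missing control calls are neutral, but at least 90 % of controls
must be called (`min_control_called_frac`) — low-coverage sequence data
always has missing genotypes, and a site supported by very few control
calls is uninformative. Sites with any missing case genotype are dropped.

The panel-segregation filter encodes the breed-specificity argument: a
deleterious recessive that arose after breed formation should not
segregate in unrelated breeds. Panel animals of breeds closely related to
the cases' breed (default: the three Nordic Red breeds Ayrshire, Swedish
Red, Danish Red) are ignored; any alternate-allele observation (het or
hom-alt) in the remaining panel removes the site. Multi-allelic VCF records
are decomposed into biallelic records before filtering; in a decomposed
record, genotypes carrying a *different* alternate allele are treated as
missing.

A site is *coding* when any affected reference base (for insertions, also
the base immediately 3' of the anchor) intersects a CDS interval of a gene
model; untranslated exon sequence and introns are non-coding.

## Consequence annotation

A variant is normalised to its minimal edit (shared flanking bases
trimmed), projected into spliced CDS coordinates (strand-aware), applied to
the CDS, and both reference and mutant CDS are translated with the standard
genetic code (no selenocysteine handling). Pure insertions/deletions are
additionally shifted to their 3'-most equivalent position on the coding
strand for notation, so deleting either G of a GG run yields one canonical
record; both the `GG>G` and anchored 1-bp-deletion spellings of the same
edit produce identical results.

Frameshift notation `p.<ref><pos>fs<k>` counts the first altered residue as
residue 1 of the shifted frame and the stop as residue k, so the
premature-stop position is `pos + k - 1` and the mutant protein length is
`pos + k - 2`; truncation statistics are `lost = ref_len - mutant_len` and
`percent = round(100 * lost / ref_len)`. A variant destroying the start
codon is reported as start-lost with no frameshift arithmetic. Edits
spanning a splice boundary are rejected rather than guessed at. The
annotator is cross-checked against literally editing the genomic sequence,
re-splicing and re-translating, on randomized small gene models on both
strands.

## Coordinates and rounding

All internal coordinates are 1-based fully-closed; interval length is
`end - start + 1`. Conversion to BED (0-based half-open) happens only in
the BED writers. Reported frequencies (1 decimal), interval lengths in Mb
(2 decimals) and truncation percentages (integer) use half-up rounding,
matching how such values are conventionally printed.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* the analysis relies on, at desk
scale, fully determined by one seed:

- **Pedigree**: a fixed template — one founder sires both the common sire
  and the maternal grand-dam, so each case reaches the founder through both
  parents; half-sibs share the sire with unrelated dams. Defaults: 3 cases,
  18 half-sibs.
- **Gene drop**: one marked founder allele transmitted by fair Mendelian
  draws; the study configuration (all cases homozygous, half-sibs carrying
  at most one copy) is enforced by rejection sampling, which is cheap at the
  default case count.
- **Array genotypes**: ~1 marker per 56 kb (gaps uniform in ±50 % of the
  spacing) on 29 autosomes of 5 Mb; markers are independent HWE draws at
  uniform minor-allele frequencies in [0.05, 0.5], except that carriers of
  the founder segment have 1 or 2 allele draws replaced by the fixed founder
  haplotype allele across the planted 2 Mb interval. Missing rate 1 %;
  genotyping-error (het miscall) rate 0 by default so planted runs are
  deterministic.
- **Variant table**: one causal 1 bp deletion at CDS position 1350 of the
  gene fixture — hom-alt in cases, hom-ref in controls (300 animals, ten
  breeds) and in non-Nordic panel animals (1009), het at 20 % in Nordic-Red
  panel animals (56) — plus 400 background variants segregating
  independently under HWE in all cohorts. Sparse (2 %) missing calls in
  control/panel genotypes.
- **Gene fixture**: a 19-exon gene whose CDS (translation starting in exon
  2) encodes 876 residues, engineered from a small set of codon templates so
  the reference frame is stop-free and deleting the third base of codon 450
  (which sits in a GG dinucleotide, in the eleventh exon) puts the first
  shifted-frame stop exactly at protein position 476. The construction is
  verified by direct translation before the model is returned, and an
  infeasible geometry raises.

Not emulated: linkage disequilibrium outside the planted segment,
recombination-map realism, read-level sequencing error, genotyping batch
structure, and real allele-frequency spectra. Passing tests therefore
demonstrate that the algorithms recover a planted signal with the correct
geometry and survive their brute-force cross-checks — they do not
demonstrate robustness to LD-induced chance ROH or to systematic genotyping
artifacts in real array data.

Because region boundaries are outermost homozygous markers, the mapped
region's bp coordinates sit strictly inside the planted interval (by up to
one marker spacing per side); recovery is asserted at marker resolution.

## Problem sizes

The default synthetic study (29 × 5 Mb, ~2,560 markers, 21 array
individuals, 1,368 sequenced animals, 401 variant sites) simulates, writes
all file formats, and runs the full pipeline in a few seconds on one CPU;
the complete test suite, including the brute-force oracle comparisons (50
randomized replicates per oracle), runs in under a minute.

## Known limitations

- The panel-size discrepancy in the emulated study (a 1147-animal panel
  minus 56 excluded animals described as 1009 kept) is left to
  configuration; defaults use 56 + 1009.
- `shifted_stop_codon == n_codons` is not constructible with the fixture's
  codon templates (the shifted stop would have to overlap the terminal stop
  codon's first base) and raises.
- The gene-drop rejection sampler scales poorly beyond ~4 forced-homozygous
  cases; the default design uses 3.
- Haplotype identity within shared segments is not checked: mapping is
  genotype-homozygosity-based, as in unphased array practice.
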