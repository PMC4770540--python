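# autozygmap

Autozygosity mapping of recessive defects from SNP-array and sequence
data: runs-of-homozygosity (ROH) detection, case/control interval mapping,
recessive-compatibility variant filtering against multi-breed control
panels, and frameshift consequence annotation in HGVS-style notation.

The package is aimed at geneticists mapping a rare monogenic recessive
trait — for example a sterilizing sperm defect surfacing in a few related
breeding bulls — with only a handful of affected individuals, unaffected
half-sibs, medium-density array genotypes and access to whole-genome
sequence panels from other populations.

## The method

Affected individuals descending from a common carrier ancestor through
both parents are **autozygous** (homozygous by descent) across a segment
around the causal allele. With array genotypes **G** and marker map, the
pipeline:

1. **QC** — keeps autosomal markers with per-SNP and per-individual call
   rate ≥ 90 % and exact Hardy-Weinberg test *P* > 10⁻⁴ (exact conditional
   test, enumeration of heterozygote counts given allele counts).
2. **ROH** — reports maximal runs of ≥ 20 contiguous homozygous SNPs
   spanning ≥ 500 kb (no heterozygote, ≤ 2 missing calls allowed), per
   individual and chromosome.
3. **Mapping** — intersects case ROH (a region must be homozygous in
   *every* case) and removes regions fully covered by an ROH of any
   unaffected half-sib; interval lengths are (end − start + 1)/10⁶ Mb.
4. **Variant filtering** — inside the mapped region keeps sites
   homozygous-alt in all cases and homozygous-ref in all called controls,
   then drops sites whose alternate allele segregates in a wider
   multi-breed panel (breeds related to the cases' breed excluded).
5. **Annotation** — projects the surviving variant into spliced CDS
   coordinates, translates reference and mutant CDS, and reports the
   frameshift as `p.<ref><pos>fs<k>` (stop at protein position
   `pos + k − 1`), plus truncation statistics
   `lost = ref_len − mutant_len`, `percent = round(100·lost/ref_len)`.
6. **Stats** — allele frequency `q = (2·hom_alt + het)/(2·n)` from survey
   genotype counts and the recessive incidence expectation `q²·n` under
   Hardy-Weinberg equilibrium.

A first-class synthetic-data module generates the whole study design —
half-sib pedigree with an inbreeding loop, gene drop of the founder
allele, array genotypes with a planted autozygous segment, a variant table
with a planted coding 1 bp deletion, and an 876-codon, 19-exon gene
fixture realising the frameshift geometry — so every stage is testable
without any external data. See `docs/methods.md` for models, parameter
defaults and numerical conventions.

## Worked example

Simulate a study (29 × 5 Mb autosomes, 3 cases, 18 half-sibs, 300
sequenced controls, 1065-animal panel, one planted 2 Mb autozygous segment
and causal deletion) and run the full pipeline:

```sh
autozygmap simulate --seed 1 --out-dir data
autozygmap run --data-dir data --out-dir data/results
```

```
mapped region(s): 13:1508914-3484379 (1.98 Mb)
1 candidate variant(s); summary at data/results/summary.json
```

The mapped region is the planted 2 Mb segment at marker resolution (region
boundaries are the outermost shared homozygous SNPs), and the single
surviving coding candidate is the planted deletion. Annotating it directly:

```sh
autozygmap annotate --gene-model data/genes.gff3 --fasta data/reference.fa \
    --variant 13:2504580:GG:G
```

```json
{
  "cds_notation": "c.1351delG",
  "first_altered": 451,
  "frameshift": true,
  "kind": "frameshift",
  "mutant_len": 475,
  "percent_lost": 46,
  "protein_notation": "p.A451fs26",
  "ref_len": 876,
  "residues_lost": 401,
  "termination_index": 476
}
```

Deleting one G of the GG dinucleotide at coding position 1350 (third base
of codon 450; reported 3'-shifted as c.1351delG) shifts the reading frame
from residue 451 onward and terminates translation at protein position
476: the 876-residue protein loses 401 residues (46 %).

Carrier-survey statistics from genotype counts (74 hom-ref, 23 het, 0
hom-alt):

```sh
autozygmap stats --counts 74,23,0 --affected-cohort-size 100
```

reports an alternate-allele frequency of 11.9 % and, at that frequency,
about 1.4 expected affected homozygotes per 100 animals under random
mating — i.e. roughly one affected animal in a yearly intake of 100.

Every subcommand (`simulate`, `qc`, `roh`, `map`, `filter`, `annotate`,
`stats`, `run`) is a thin wrapper over the library API
(`autozygmap.scan_roh`, `intersect_case_roh`, `recessive_compatible`,
`apply_variant_translate`, ...), which can be used directly from Python.

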