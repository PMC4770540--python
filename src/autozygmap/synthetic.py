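"""Synthetic study generator.

Emulates the data structure of an autozygosity-mapping study of a rare
recessive defect in a livestock half-sib design: a small set of affected
individuals inbred through one common ancestor on both the paternal and the
maternal path, a cohort of unaffected paternal half-sibs, medium-density
array genotypes (~1 SNP per 56 kb) with a planted shared autozygous
segment in the affected animals, a sequence-variant table over the mapped
interval carrying one planted coding 1 bp deletion, and a multi-exon gene
fixture whose geometry realises the planted frameshift (deletion at the
third base of a chosen codon, premature stop at a chosen downstream codon).

Everything is a deterministic function of the configuration seed. Markers
are independent draws under Hardy-Weinberg equilibrium apart from the
planted segment; there is no background linkage disequilibrium and no
recombination-map realism.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consequence import GeneModel
from .core import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval, Variant
from .qc import GenotypeMatrix, MarkerMap
from .variants import VariantTable

_STOPS = {"TAA", "TAG", "TGA"}
_FIXTURE_RNG_SALT = 7919  # fixed: gene fixtures carry no seed parameter

# rng stream labels so each generator stage has an independent substream
_STREAM_DROP, _STREAM_ARRAY, _STREAM_VARIANTS = 2, 3, 4

# control panel: ten breeds, 300 sequenced animals
DEFAULT_CONTROL_BREEDS: dict[str, int] = {
    "Gelbvieh": 12,
    "NordicFinncattle": 6,
    "Fleckvieh": 153,
    "OriginalSimmental": 15,
    "HolsteinFriesian": 31,
    "BrownSwiss": 50,
    "MurnauWerdenfelser": 2,
    "Ayrshire": 2,
    "RedHolstein": 21,
    "OriginalBraunvieh": 8,
}

# wider multi-breed panel: 56 animals of the three Nordic Red breeds
# (eligible to carry the planted allele) plus 1009 animals of other breeds
DEFAULT_PANEL_BREEDS: dict[str, int] = {
    "Ayrshire": 20,
    "SwedishRed": 20,
    "DanishRed": 16,
    "Fleckvieh": 250,
    "HolsteinFriesian": 250,
    "BrownSwiss": 200,
    "Angus": 159,
    "Charolais": 150,
}

DEFAULT_CARRIER_BREEDS: tuple[str, ...] = ("Ayrshire", "SwedishRed", "DanishRed")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Chromosome sizes are desk-scale (29 autosomes of 5 Mb with one planted
    2 Mb autozygous segment) while cohort sizes, marker spacing and the
    variant geometry match the emulated design: 3 cases, 18 half-sibs, 300
    sequenced controls from ten breeds, a 1065-animal multi-breed panel,
    ~1 marker per 56 kb, and a causal 1 bp deletion at coding position 1350
    of an 876-codon gene (premature stop 26 shifted-frame codons later).
    """

    n_chromosomes: int = 29
    chrom_length_bp: int = 5_000_000
    marker_spacing_bp: int = 56_000
    n_cases: int = 3
    n_unaffected_sibs: int = 18
    control_breeds: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_BREEDS)
    )
    panel_breeds: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_BREEDS)
    )
    carrier_breeds: tuple[str, ...] = DEFAULT_CARRIER_BREEDS
    planted_interval: GenomicInterval = GenomicInterval("13", 1_500_001, 3_500_000)
    causal_cds_pos: int = 1350
    gene_n_codons: int = 876
    fs_stop_offset: int = 26  # shifted-frame codons until the premature stop
    n_background_variants: int = 400
    genotype_missing_rate: float = 0.01
    genotype_error_rate: float = 0.0
    seq_missing_rate: float = 0.02
    carrier_het_rate: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 1

    def __post_init__(self) -> None:
        rates = {
            "genotype_missing_rate": self.genotype_missing_rate,
            "genotype_error_rate": self.genotype_error_rate,
            "seq_missing_rate": self.seq_missing_rate,
            "carrier_het_rate": self.carrier_het_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_cases < 1 or self.n_unaffected_sibs < 0:
            raise ValueError("need n_cases >= 1 and n_unaffected_sibs >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        chroms = {str(i) for i in range(1, self.n_chromosomes + 1)}
        iv = self.planted_interval
        if iv.chrom not in chroms or iv.end > self.chrom_length_bp:
            raise ValueError(
                f"planted interval {iv} does not fit a simulated chromosome"
            )
        if self.causal_cds_pos % 3 != 0:
            raise ValueError("causal_cds_pos must hit the third base of a codon")
        fs_codon = self.causal_cds_pos // 3
        if not 1 <= fs_codon < fs_codon + self.fs_stop_offset <= self.gene_n_codons + 1:
            raise ValueError("infeasible causal codon / stop-offset combination")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")

    @property
    def n_controls(self) -> int:
        return sum(self.control_breeds.values())

    @property
    def n_panel(self) -> int:
        return sum(self.panel_breeds.values())


@dataclass(frozen=True)
class Individual:
    id: str
    sire: Optional[str]
    dam: Optional[str]
    sex: str  # "M" | "F"
    cohort: str  # "case" | "halfsib" | "ancestor"


@dataclass
class Pedigree:
    """Individuals in topological order (parents precede offspring)."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id}")
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"parent {parent} of {ind.id} missing or listed after offspring"
                    )
            if (ind.sire is None) != (ind.dam is None):
                raise ValueError(f"{ind.id} has exactly one known parent")
            seen.add(ind.id)
        if not self.founders:
            raise ValueError("pedigree has no founders")
        self._by_id = {ind.id: ind for ind in self.individuals}

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self.individuals if i.sire is None]

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def cohort(self, label: str) -> list[str]:
        return [i.id for i in self.individuals if i.cohort == label]

    def ancestors(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = self._by_id[stack.pop()]
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def reaches_through_both_parents(self, ind_id: str, ancestor_id: str) -> bool:
        """True when `ancestor_id` is reachable via the sire AND via the dam path."""
        ind = self._by_id[ind_id]
        if ind.sire is None:
            return False

        def via(parent: str) -> bool:
            return parent == ancestor_id or ancestor_id in self.ancestors(parent)

        return via(ind.sire) and via(ind.dam)


FOUNDER_ID = "FOUNDER"


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Fixed half-sib template pedigree with one inbreeding loop per case.

    One designated founder sires both the common sire of all cases/half-sibs
    and the maternal grand-dam of every case, so each case reaches the
    founder through its paternal and its maternal path. Half-sibs share the
    sire but their dams are unrelated founders, so they are not inbred
    through the founder.
    """
    inds: list[Individual] = [
        Individual(FOUNDER_ID, None, None, "M", "ancestor"),
        Individual("FDAM1", None, None, "F", "ancestor"),
        Individual("FDAM2", None, None, "F", "ancestor"),
        Individual("SIRE", FOUNDER_ID, "FDAM1", "M", "ancestor"),
        Individual("MATGM", FOUNDER_ID, "FDAM2", "F", "ancestor"),
    ]
    for i in range(1, config.n_cases + 1):
        inds.append(Individual(f"DAMSIRE{i}", None, None, "M", "ancestor"))
        inds.append(Individual(f"DAM{i}", f"DAMSIRE{i}", "MATGM", "F", "ancestor"))
        inds.append(Individual(f"CASE{i}", "SIRE", f"DAM{i}", "M", "case"))
    for j in range(1, config.n_unaffected_sibs + 1):
        inds.append(Individual(f"HSDAM{j}", None, None, "F", "ancestor"))
        inds.append(Individual(f"HS{j}", "SIRE", f"HSDAM{j}", "M", "halfsib"))
    return Pedigree(inds)


def gene_drop(
    pedigree: Pedigree,
    founder_id: str = FOUNDER_ID,
    seed: int | np.random.Generator = 0,
    force: bool = True,
    max_tries: int = 500_000,
) -> dict[str, int]:
    """Drop one marked founder allele through the pedigree by Mendelian transmission.

    The designated founder starts with exactly one copy; every other founder
    has none. Each transmission is an independent fair draw per parental
    copy. With `force=True` the drop is repeated (rejection sampling) until
    every case carries two copies and every half-sib at most one — the
    configuration an autozygosity-mapping study conditions on.
    """
    if founder_id not in {i.id for i in pedigree.individuals}:
        raise KeyError(f"founder {founder_id} not in pedigree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cases = pedigree.cohort("case")
    sibs = pedigree.cohort("halfsib")

    for _ in range(max_tries if force else 1):
        copies: dict[str, int] = {}
        for ind in pedigree.individuals:
            if ind.sire is None:
                copies[ind.id] = 1 if ind.id == founder_id else 0
            else:
                transmitted = 0
                for parent in (ind.sire, ind.dam):
                    c = copies[parent]
                    if c == 2:
                        transmitted += 1
                    elif c == 1:
                        transmitted += int(rng.integers(0, 2))
                copies[ind.id] = transmitted
        if not force:
            return copies
        if all(copies[c] == 2 for c in cases) and all(copies[s] <= 1 for s in sibs):
            return copies
    raise RuntimeError(
        f"no carrier configuration satisfying the case/half-sib constraints "
        f"in {max_tries} gene drops"
    )


def _marker_positions(rng: np.random.Generator, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Marker grid per chromosome: gaps uniform in [spacing/2, 3*spacing/2]."""
    spacing = config.marker_spacing_bp
    out: dict[str, np.ndarray] = {}
    for c in range(1, config.n_chromosomes + 1):
        n_max = int(config.chrom_length_bp // (spacing // 2)) + 2
        gaps = rng.integers(spacing // 2, 3 * spacing // 2 + 1, size=n_max)
        pos = np.cumsum(gaps)
        out[str(c)] = pos[pos <= config.chrom_length_bp]
    return out


def simulate_array_genotypes(
    pedigree: Pedigree,
    carrier_states: Mapping[str, int],
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Array genotypes for cases and half-sibs with the planted autozygous segment.

    Outside the planted interval genotypes are independent HWE draws at
    uniform minor-allele frequencies. Inside the interval each individual
    replaces as many of its two allele draws as it carries founder copies by
    the fixed founder-haplotype allele, so two-copy carriers are homozygous
    across the segment. Genotyping errors (heterozygous miscalls) and
    missingness are applied afterwards at the configured rates.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ARRAY])
    individuals = pedigree.cohort("case") + pedigree.cohort("halfsib")
    copies = np.array([carrier_states[i] for i in individuals])
    positions = _marker_positions(rng, config)

    map_rows = []
    geno_cols = []
    iv = config.planted_interval
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        pos = positions[chrom]
        n_mark = len(pos)
        maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_mark)
        hap = (rng.random(n_mark) < maf).astype(np.int8)  # founder haplotype allele
        in_planted = (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)

        # two allele draws per individual and marker
        a1 = (rng.random((len(individuals), n_mark)) < maf).astype(np.int8)
        a2 = (rng.random((len(individuals), n_mark)) < maf).astype(np.int8)
        # founder copies overwrite allele draws inside the planted segment
        one_copy = (copies >= 1)[:, None] & in_planted[None, :]
        two_copies = (copies == 2)[:, None] & in_planted[None, :]
        a1 = np.where(one_copy, hap[None, :], a1)
        a2 = np.where(two_copies, hap[None, :], a2)
        g = (a1 + a2).astype(np.int8)

        if config.genotype_error_rate > 0:
            err = rng.random(g.shape) < config.genotype_error_rate
            g = np.where(err, np.int8(HET), g)
        if config.genotype_missing_rate > 0:
            miss = rng.random(g.shape) < config.genotype_missing_rate
            g = np.where(miss, np.int8(MISSING), g)

        geno_cols.append(g)
        for k, p in enumerate(pos):
            map_rows.append(
                {"marker_id": f"SNP{chrom}_{k + 1}", "chrom": chrom, "pos": int(p),
                 "allele_ref": "A", "allele_alt": "B"}
            )

    marker_map = MarkerMap(pd.DataFrame(map_rows))
    matrix = GenotypeMatrix(
        individual_ids=individuals,
        marker_ids=marker_map.marker_ids,
        calls=np.concatenate(geno_cols, axis=1),
    )
    return matrix, marker_map


# ---------------------------------------------------------------------------
# gene fixture
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def build_gene_fixture(
    n_codons: int = 876,
    fs_codon: int = 450,
    shifted_stop_codon: int = 476,
    *,
    n_exons: int = 19,
    chrom: str = "13",
    locus_start: int = 100_001,
    gene_id: str = "GENE1",
) -> tuple[GeneModel, str]:
    """Construct a multi-exon gene whose CDS realises a planted frameshift.

    The CDS encodes `n_codons` residues plus a stop, contains no internal
    stop in the reference frame, starts in exon 2 (exon 1 is untranslated),
    and is engineered so that deleting one base at CDS position
    ``3 * fs_codon`` (the third base of `fs_codon`, which sits in a GG
    dinucleotide) shifts the frame and puts the first mutant stop codon at
    protein position `shifted_stop_codon`. The construction is verified by
    direct translation before returning; an infeasible codon choice raises.

    Returns the gene model and its cached locus reference sequence.
    """
    if not 1 <= fs_codon < shifted_stop_codon <= n_codons:
        raise ValueError("require 1 <= fs_codon < shifted_stop_codon <= n_codons")
    if shifted_stop_codon == n_codons:
        raise ValueError(
            "shifted_stop_codon == n_codons is infeasible: the shifted stop would "
            "need the terminal stop codon to start with A"
        )
    if n_exons < 2:
        raise ValueError("need at least 2 exons (translation starts in exon 2)")

    # codon templates: filler GCA reads CAG in the shifted frame (never a stop)
    codons = ["GCA"] * (n_codons + 1)
    codons[0] = "ATG"
    codons[-1] = "TAA"
    if fs_codon > 1:
        codons[fs_codon - 1] = "GCG"  # third base G, followed by G: a GG dinucleotide
    s = shifted_stop_codon
    stop_template = "GTA"  # bases 2-3 give the TA of the shifted TAA stop
    if fs_codon + 1 == s and fs_codon > 1:
        # codon fs must end G *and* codon s must be x,T,A; GTA starts with G, so
        # the GG context survives only when fs_codon's successor starts with G.
        pass
    codons[s - 1] = stop_template
    codons[s] = "ACA" if s < n_codons else codons[s]  # successor must start with A
    cds = "".join(codons)

    # independent verification by direct translation (not via the annotator)
    from Bio.Seq import Seq

    ref_prot = str(Seq(cds).translate())
    if "*" in ref_prot[:-1] or not ref_prot.endswith("*") or len(ref_prot) != n_codons + 1:
        raise ValueError("fixture construction failed: invalid reference frame")
    del_pos = 3 * fs_codon
    mutant = cds[: del_pos - 1] + cds[del_pos:]
    mut_prot = str(Seq(mutant[: len(mutant) - len(mutant) % 3]).translate())
    first_stop = mut_prot.find("*") + 1
    if first_stop != shifted_stop_codon:
        raise ValueError(
            f"fixture construction failed: shifted-frame stop at {first_stop}, "
            f"requested {shifted_stop_codon}"
        )

    # exon layout: exon 1 untranslated; CDS split over the remaining exons
    rng = np.random.default_rng(
        [_FIXTURE_RNG_SALT, n_codons, fs_codon, shifted_stop_codon, n_exons]
    )
    n_coding_exons = min(n_exons - 1, len(cds))
    base, rem = divmod(len(cds), n_coding_exons)
    chunk_sizes = [base + 1 if i < rem else base for i in range(n_coding_exons)]

    flank, exon1_len, utr5b_len, utr3_len, intron_len = 50, 150, 30, 120, 300
    seq_parts: list[str] = []
    exons: list[GenomicInterval] = []
    cursor = locus_start

    def emit(piece: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        seq_parts.append(piece)
        cursor += len(piece)
        return start, cursor - 1

    emit(_random_bases(rng, flank))
    e1 = emit(_random_bases(rng, exon1_len))
    exons.append(GenomicInterval(chrom, *e1))
    cds_offset = 0
    cds_start = cds_end = None
    for i, size in enumerate(chunk_sizes):
        emit(_random_bases(rng, intron_len))
        if i == 0:
            utr_start, _ = emit(_random_bases(rng, utr5b_len))
            c_start, c_end = emit(cds[cds_offset : cds_offset + size])
            exons.append(GenomicInterval(chrom, utr_start, c_end))
            cds_start = c_start
        elif i == n_coding_exons - 1:
            c_start, c_end = emit(cds[cds_offset : cds_offset + size])
            _, utr_end = emit(_random_bases(rng, utr3_len))
            exons.append(GenomicInterval(chrom, c_start, utr_end))
            cds_end = c_end
        else:
            c_start, c_end = emit(cds[cds_offset : cds_offset + size])
            exons.append(GenomicInterval(chrom, c_start, c_end))
        cds_offset += size
    if n_coding_exons == 1:  # single coding exon carries both UTR ends
        cds_end = exons[-1].end
        _, utr_end = emit(_random_bases(rng, utr3_len))
        exons[-1] = GenomicInterval(chrom, exons[-1].start, utr_end)
    emit(_random_bases(rng, flank))

    locus_seq = "".join(seq_parts)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        locus_start=locus_start,
        locus_seq=locus_seq,
    )
    return model, locus_seq


def mirror_gene_model(model: GeneModel) -> GeneModel:
    """The same gene placed on the opposite strand of the reverse-complemented locus.

    Coordinates are reflected within the cached locus span, so the spliced
    CDS (and hence every consequence) is unchanged.
    """
    from Bio.Seq import Seq

    lo = model.locus_start
    hi = model.locus_start + len(model.locus_seq) - 1

    def m(p: int) -> int:
        return lo + hi - p

    exons = [
        GenomicInterval(model.chrom, m(e.end), m(e.start)) for e in reversed(model.exons)
    ]
    return GeneModel(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand="-" if model.strand == "+" else "+",
        exons=exons,
        cds_start=m(model.cds_end),
        cds_end=m(model.cds_start),
        locus_start=lo,
        locus_seq=str(Seq(model.locus_seq).reverse_complement()),
    )


def mirror_variant(model: GeneModel, variant: Variant) -> Variant:
    """Project a variant onto the mirrored gene model (see `mirror_gene_model`)."""
    from Bio.Seq import Seq

    lo = model.locus_start
    hi = model.locus_start + len(model.locus_seq) - 1
    if not variant.ref:
        raise ValueError("mirroring anchorless insertions is not supported")
    new_pos = lo + hi - (variant.pos + len(variant.ref) - 1)
    return Variant(
        chrom=variant.chrom,
        pos=new_pos,
        ref=str(Seq(variant.ref).reverse_complement()),
        alt=str(Seq(variant.alt).reverse_complement()) if variant.alt else "",
    )


def random_gene_model(
    rng: np.random.Generator,
    n_codons: int | None = None,
    n_exons: int | None = None,
    strand: str | None = None,
    chrom: str = "1",
    locus_start: int = 1_001,
) -> GeneModel:
    """A small random multi-exon gene model for randomized cross-checks."""
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    if n_codons is None:
        n_codons = int(rng.integers(25, 80))
    if n_exons is None:
        n_exons = int(rng.integers(1, 5))
    cds = "ATG" + "".join(rng.choice(non_stop, size=n_codons - 1)) + "TAA"

    base, rem = divmod(len(cds), n_exons)
    chunks = [base + 1 if i < rem else base for i in range(n_exons)]
    cursor = locus_start
    seq_parts: list[str] = []
    exons: list[GenomicInterval] = []
    flank = int(rng.integers(5, 30))
    seq_parts.append(_random_bases(rng, flank))
    cursor += flank
    offset = 0
    for i, size in enumerate(chunks):
        if i > 0:
            intron = int(rng.integers(20, 100))
            seq_parts.append(_random_bases(rng, intron))
            cursor += intron
        exons.append(GenomicInterval(chrom, cursor, cursor + size - 1))
        seq_parts.append(cds[offset : offset + size])
        cursor += size
        offset += size
    seq_parts.append(_random_bases(rng, int(rng.integers(5, 30))))
    plus = GeneModel(
        gene_id="RAND1",
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
        locus_start=locus_start,
        locus_seq="".join(seq_parts),
    )
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return plus if strand == "+" else mirror_gene_model(plus)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

def place_gene_in_interval(config: SimulationConfig) -> tuple[GeneModel, str]:
    """Build the default gene fixture centred in the planted interval."""
    iv = config.planted_interval
    fs_codon = config.causal_cds_pos // 3
    locus_start = iv.start + iv.length_bp // 2
    return build_gene_fixture(
        n_codons=config.gene_n_codons,
        fs_codon=fs_codon,
        shifted_stop_codon=fs_codon + config.fs_stop_offset,
        chrom=iv.chrom,
        locus_start=locus_start,
    )


def causal_deletion(model: GeneModel, causal_cds_pos: int) -> Variant:
    """The planted 1 bp deletion: one G of the GG dinucleotide at the causal site."""
    g = model.cds_to_genomic(causal_cds_pos)
    ref = model.sequence(g, g + 1)
    if ref != "GG":  # guaranteed by the fixture construction on the plus strand
        raise ValueError(f"expected GG context at CDS {causal_cds_pos}, found {ref}")
    return Variant(chrom=model.chrom, pos=g, ref=ref, alt=ref[0])


def simulate_variant_table(
    config: SimulationConfig,
    carrier_states: Mapping[str, int],
    pedigree: Pedigree | None = None,
    gene_model: GeneModel | None = None,
) -> tuple[VariantTable, Variant]:
    """Sequence-variant table over the planted interval.

    One planted coding 1 bp deletion is homozygous-alt in every case,
    homozygous-ref in every control and in panel animals outside the
    carrier (Nordic Red) breeds, and heterozygous at `carrier_het_rate` in
    carrier-breed panel animals. Background variants segregate independently
    under HWE at random allele frequencies in all cohorts. Sparse missing
    calls are applied to control and panel genotypes only.
    """
    rng = np.random.default_rng([config.seed, _STREAM_VARIANTS])
    if pedigree is None:
        pedigree = simulate_pedigree(config)
    if gene_model is None:
        gene_model, _ = place_gene_in_interval(config)
    causal = causal_deletion(gene_model, config.causal_cds_pos)

    cases = pedigree.cohort("case")
    for case in cases:
        if carrier_states.get(case, 0) != 2:
            raise ValueError(f"case {case} does not carry two founder copies")
    roster_rows = [{"individual": c, "cohort": "case", "breed": "SwedishRed"} for c in cases]
    for breed, count in config.control_breeds.items():
        for k in range(count):
            roster_rows.append(
                {"individual": f"CTRL_{breed}_{k + 1}", "cohort": "control", "breed": breed}
            )
    for breed, count in config.panel_breeds.items():
        for k in range(count):
            roster_rows.append(
                {"individual": f"PANEL_{breed}_{k + 1}", "cohort": "panel", "breed": breed}
            )
    roster = pd.DataFrame(roster_rows)
    n_ind = len(roster)
    cohorts = roster["cohort"].to_numpy()
    breeds = roster["breed"].to_numpy()

    iv = config.planted_interval
    locus_hi = gene_model.locus_start + len(gene_model.locus_seq) - 1
    taken = {causal.pos, causal.pos + 1}
    bg_pos: list[int] = []
    while len(bg_pos) < config.n_background_variants:
        draw = rng.integers(iv.start, iv.end + 1, size=config.n_background_variants)
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                bg_pos.append(p)
            if len(bg_pos) == config.n_background_variants:
                break
    bg_pos.sort()

    bases = "ACGT"
    site_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []

    def background_genotypes(freq: float) -> np.ndarray:
        draws = rng.random((2, n_ind))
        return ((draws[0] < freq).astype(np.int8) + (draws[1] < freq).astype(np.int8))

    for p in bg_pos:
        if gene_model.locus_start <= p <= locus_hi:
            ref = gene_model.sequence(p, p)
        else:
            ref = bases[int(rng.integers(0, 4))]
        if rng.random() < 0.9:  # SNP
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            vclass = "SNP"
        else:  # 1 bp insertion after the ref base
            alt = ref + bases[int(rng.integers(0, 4))]
            vclass = "indel"
        freq = float(rng.uniform(0.01, 0.4))
        site_rows.append({"chrom": iv.chrom, "pos": p, "ref": ref, "alt": alt, "vclass": vclass})
        geno_rows.append(background_genotypes(freq))

    causal_geno = np.full(n_ind, HOM_REF, dtype=np.int8)
    causal_geno[cohorts == "case"] = HOM_ALT
    carrier_panel = (cohorts == "panel") & np.isin(breeds, list(config.carrier_breeds))
    het_draw = rng.random(n_ind) < config.carrier_het_rate
    causal_geno[carrier_panel & het_draw] = HET
    site_rows.append(
        {"chrom": causal.chrom, "pos": causal.pos, "ref": causal.ref,
         "alt": causal.alt, "vclass": "indel"}
    )
    geno_rows.append(causal_geno)

    sites = pd.DataFrame(site_rows)
    genotypes = np.vstack(geno_rows)
    order = np.argsort(sites["pos"].to_numpy(), kind="stable")
    sites = sites.iloc[order].reset_index(drop=True)
    genotypes = genotypes[order]

    if config.seq_missing_rate > 0:
        maskable = (cohorts == "control") | (cohorts == "panel")
        miss = (rng.random(genotypes.shape) < config.seq_missing_rate) & maskable[None, :]
        genotypes = np.where(miss, np.int8(MISSING), genotypes)

    table = VariantTable(sites=sites, genotypes=genotypes, roster=roster)
    return table, causal


def build_panel_fixture(
    seed: int = 0,
    n_total: int = 77,
    n_coding: int = 1,
    n_segregating: int = 35,
    n_controls: int = 10,
    excluded_breeds: Sequence[str] = DEFAULT_CARRIER_BREEDS,
) -> tuple[VariantTable, GeneModel]:
    """A recessive-compatible variant set for exercising the panel filter.

    Builds `n_total` sites that already pass recessive filtering (hom-alt in
    the case, hom-ref in all controls): `n_coding` of them inside the default
    gene fixture's CDS and the rest non-coding. `n_segregating` of the
    non-coding sites carry the alternate allele in at least one panel animal
    of a non-excluded breed (so the panel filter removes them); excluded-breed
    panel animals carry alt alleles at a random subset of the remaining sites
    without consequence. Returns the table and the gene model used for
    coding classification.
    """
    if n_coding != 1:
        raise ValueError("fixture currently plants exactly one coding site")
    if n_segregating > n_total - n_coding:
        raise ValueError("cannot have more segregating sites than non-coding sites")
    rng = np.random.default_rng(seed)
    model, _ = build_gene_fixture()
    causal = causal_deletion(model, 1350)

    roster_rows = [{"individual": "CASE1", "cohort": "case", "breed": "SwedishRed"}]
    roster_rows += [
        {"individual": f"CTRL{k + 1}", "cohort": "control", "breed": "Fleckvieh"}
        for k in range(n_controls)
    ]
    panel_breeds = list(excluded_breeds) + ["Fleckvieh", "HolsteinFriesian", "Angus"]
    for breed in panel_breeds:
        for k in range(5):
            roster_rows.append(
                {"individual": f"PANEL_{breed}_{k + 1}", "cohort": "panel", "breed": breed}
            )
    roster = pd.DataFrame(roster_rows)
    cohorts = roster["cohort"].to_numpy()
    breeds = roster["breed"].to_numpy()
    nonexcluded_panel = np.flatnonzero(
        (cohorts == "panel") & ~np.isin(breeds, list(excluded_breeds))
    )
    excluded_panel = np.flatnonzero(
        (cohorts == "panel") & np.isin(breeds, list(excluded_breeds))
    )
    n_ind = len(roster)

    # non-coding positions: upstream of the gene locus on the same chromosome
    n_noncoding = n_total - n_coding
    positions = rng.choice(
        np.arange(1_000, model.locus_start - 10), size=n_noncoding, replace=False
    )
    positions.sort()
    segregating = set(rng.choice(n_noncoding, size=n_segregating, replace=False).tolist())

    bases = "ACGT"
    site_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    for idx, p in enumerate(positions):
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        g = np.full(n_ind, HOM_REF, dtype=np.int8)
        g[cohorts == "case"] = HOM_ALT
        if idx in segregating:
            carrier = int(rng.choice(nonexcluded_panel))
            g[carrier] = HET if rng.random() < 0.5 else HOM_ALT
        elif len(excluded_panel) and rng.random() < 0.3:
            g[int(rng.choice(excluded_panel))] = HET
        site_rows.append(
            {"chrom": model.chrom, "pos": int(p), "ref": ref, "alt": alt, "vclass": "SNP"}
        )
        geno_rows.append(g)

    g = np.full(n_ind, HOM_REF, dtype=np.int8)
    g[cohorts == "case"] = HOM_ALT
    if len(excluded_panel):
        g[int(rng.choice(excluded_panel))] = HET  # the allele may segregate there
    site_rows.append(
        {"chrom": causal.chrom, "pos": causal.pos, "ref": causal.ref,
         "alt": causal.alt, "vclass": "indel"}
    )
    geno_rows.append(g)

    sites = pd.DataFrame(site_rows)
    genotypes = np.vstack(geno_rows)
    order = np.argsort(sites["pos"].to_numpy(), kind="stable")
    table = VariantTable(
        sites=sites.iloc[order].reset_index(drop=True),
        genotypes=genotypes[order],
        roster=roster,
    )
    return table, model


@dataclass
class SyntheticStudy:
    """Bundle of one simulated study, every piece derived from the config seed."""

    config: SimulationConfig
    pedigree: Pedigree
    carrier_states: dict[str, int]
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    variant_table: VariantTable
    gene_model: GeneModel
    causal_variant: Variant


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study: pedigree, genotypes, variants, gene."""
    if config is None:
        config = SimulationConfig()
    pedigree = simulate_pedigree(config)
    carriers = gene_drop(
        pedigree, FOUNDER_ID, np.random.default_rng([config.seed, _STREAM_DROP])
    )
    genotypes, marker_map = simulate_array_genotypes(pedigree, carriers, config)
    gene_model, _ = place_gene_in_interval(config)
    table, causal = simulate_variant_table(config, carriers, pedigree, gene_model)
    return SyntheticStudy(
        config=config,
        pedigree=pedigree,
        carrier_states=carriers,
        genotypes=genotypes,
        marker_map=marker_map,
        variant_table=table,
        gene_model=gene_model,
        causal_variant=causal,
    )
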