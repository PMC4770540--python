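"""Coding-consequence annotation for small variants on exon/CDS gene models.

Applies a variant to the spliced coding sequence of a gene model, translates
reference and mutant with the standard genetic code, and reports frameshift
and truncation consequences in HGVS-style c./p. notation. The frameshift
notation ``p.<ref><pos>fs<k>`` counts the first altered residue as residue 1
of the shifted frame and the new stop as residue k, so the premature-stop
protein position equals ``pos + k - 1`` and the mutant protein length equals
``pos + k - 2``.

Variants are normalised to their minimal edit (shared flanking bases
trimmed) and pure insertions/deletions are shifted to their 3'-most
equivalent position on the coding strand before notation is derived, so
e.g. deleting either G of a GG run yields one canonical record.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .core import GenomicInterval, Variant, round_half_up

_STOPS = {"TAA", "TAG", "TGA"}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CdsProjection:
    """Result of projecting a genomic position onto a gene's CDS."""

    kind: str  # "cds" | "intronic" | "utr5" | "utr3" | "intergenic"
    cds_pos: Optional[int] = None

    @property
    def is_coding(self) -> bool:
        return self.kind == "cds"

    def __str__(self) -> str:
        return f"cds:{self.cds_pos}" if self.is_coding else f"non-coding: {self.kind}"


@dataclass
class GeneModel:
    """Exon structure, strand and CDS bounds with the cached locus sequence.

    `exons` are 1-based inclusive genomic intervals in ascending genomic
    order, non-overlapping; `cds_start`/`cds_end` are the genomic bounds of
    the CDS (min/max regardless of strand). `locus_seq` caches the reference
    sequence from `locus_start` onward and must cover every exon. The spliced
    CDS (including its stop codon) must be a multiple of three, translate
    without internal stop codons and end at a stop codon.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    locus_start: int
    locus_seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model requires at least one exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError("exons must be ascending and non-overlapping")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError("exon chromosome labels disagree with the gene")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start exceeds cds_end")
        for bound in (self.cds_start, self.cds_end):
            if not any(e.start <= bound <= e.end for e in self.exons):
                raise ValueError("CDS bounds must lie inside exons")
        if self.locus_start > self.exons[0].start or (
            self.locus_start + len(self.locus_seq) - 1 < self.exons[-1].end
        ):
            raise ValueError("locus sequence does not cover the exon span")
        self.locus_seq = self.locus_seq.upper()
        cds = self.cds_sequence()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        protein = str(Seq(cds).translate())
        if not protein.endswith("*"):
            raise ValueError("CDS does not end at a stop codon")
        if "*" in protein[:-1]:
            raise ValueError("reference CDS contains an internal stop codon")

    # -- sequence access -------------------------------------------------
    def sequence(self, start: int, end: int) -> str:
        """Reference bases for the 1-based inclusive genomic span [start, end]."""
        lo = self.locus_start
        hi = self.locus_start + len(self.locus_seq) - 1
        if start < lo or end > hi:
            raise ValueError(f"span {start}-{end} outside cached locus {lo}-{hi}")
        return self.locus_seq[start - lo : end - lo + 1]

    def cds_intervals(self) -> list[GenomicInterval]:
        """Exon pieces inside the CDS bounds, ascending genomic order."""
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s <= t:
                out.append(GenomicInterval(self.chrom, s, t))
        return out

    @property
    def cds_length(self) -> int:
        return sum(iv.length_bp for iv in self.cds_intervals())

    def cds_sequence(self) -> str:
        """Spliced CDS on the coding strand, including the stop codon."""
        pieces = [self.sequence(iv.start, iv.end) for iv in self.cds_intervals()]
        forward = "".join(pieces)
        return forward if self.strand == "+" else _revcomp(forward)

    def translate_reference(self) -> str:
        """Reference protein (stop codon stripped)."""
        return str(Seq(self.cds_sequence()).translate())[:-1]

    # -- coordinate projection -------------------------------------------
    def genomic_to_cds(self, pos: int, chrom: str | None = None) -> CdsProjection:
        """Project a genomic position onto spliced CDS coordinates.

        Positions in introns or UTR exon parts are classified rather than
        mapped. Raises for a position on a different chromosome.
        """
        if chrom is not None and str(chrom) != self.chrom:
            raise ValueError(f"position on {chrom}, gene on {self.chrom}")
        ivs = self.cds_intervals()
        offset = 0
        order = ivs if self.strand == "+" else list(reversed(ivs))
        for iv in order:
            if iv.start <= pos <= iv.end:
                within = (pos - iv.start) if self.strand == "+" else (iv.end - pos)
                return CdsProjection("cds", offset + within + 1)
            offset += iv.length_bp
        if any(e.start <= pos <= e.end for e in self.exons):
            if self.strand == "+":
                kind = "utr5" if pos < self.cds_start else "utr3"
            else:
                kind = "utr5" if pos > self.cds_end else "utr3"
            return CdsProjection(kind)
        if self.exons[0].start <= pos <= self.exons[-1].end:
            return CdsProjection("intronic")
        return CdsProjection("intergenic")

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse projection: 1-based CDS coordinate to genomic position."""
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise ValueError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        ivs = self.cds_intervals()
        order = ivs if self.strand == "+" else list(reversed(ivs))
        remaining = cds_pos - 1
        for iv in order:
            if remaining < iv.length_bp:
                return iv.start + remaining if self.strand == "+" else iv.end - remaining
            remaining -= iv.length_bp
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect of a small variant applied to a gene model."""

    kind: str  # frameshift | in-frame | substitution | synonymous | start-lost
    ref_len: int
    mutant_len: Optional[int]
    frameshift: bool
    first_altered: Optional[int]
    termination_index: Optional[int]
    residues_lost: Optional[int]
    percent_lost: Optional[int]
    cds_notation: str
    protein_notation: str


def cds_codon_of(cds_pos: int, cds_length: int | None = None) -> tuple[int, int]:
    """Codon index and base-within-codon (both 1-based) of a CDS coordinate.

    ``cds_codon_of(1350) == (450, 3)``: coding position 1350 is the third
    base of codon 450.
    """
    if cds_pos < 1:
        raise ValueError("CDS positions are 1-based")
    if cds_length is not None and cds_pos > cds_length:
        raise ValueError(f"CDS position {cds_pos} beyond CDS length {cds_length}")
    return math.ceil(cds_pos / 3), (cds_pos - 1) % 3 + 1


def genomic_to_cds(model: GeneModel, pos: int, chrom: str | None = None) -> CdsProjection:
    return model.genomic_to_cds(pos, chrom)


def truncation_stats(ref_len: int, mutant_len: int) -> tuple[int, int]:
    """Residues lost and integer percent lost for a truncated protein."""
    if not 0 <= mutant_len <= ref_len:
        raise ValueError("require 0 <= mutant_len <= ref_len (elongation handled elsewhere)")
    lost = ref_len - mutant_len
    return lost, int(round_half_up(100 * lost / ref_len, 0))


def _minimal_edit(model: GeneModel, variant: Variant) -> tuple[int, str, str]:
    """Trim shared flanking bases; returns (genomic pos of first edited base, ref, alt)."""
    ref, alt, pos = variant.ref.upper(), variant.alt.upper(), variant.pos
    observed = model.sequence(pos, pos + len(ref) - 1) if ref else ""
    if observed != ref:
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:{pos}: "
            f"expected {observed!r}, variant says {ref!r}"
        )
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def _project_edit(model: GeneModel, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Map a genomic minimal edit into CDS space: (cds pos, cds ref, cds alt).

    For insertions the returned cds pos is the CDS coordinate *before which*
    the alt bases are inserted. Raises if the edit is not fully inside the
    CDS or spans a splice boundary.
    """
    if ref:
        projections = [model.genomic_to_cds(p) for p in range(pos, pos + len(ref))]
        if not all(pr.is_coding for pr in projections):
            kinds = {pr.kind for pr in projections if not pr.is_coding}
            raise ValueError(f"edit touches non-coding sequence ({', '.join(sorted(kinds))})")
        coords = [pr.cds_pos for pr in projections]
        lo = min(coords)
        if sorted(coords) != list(range(lo, lo + len(ref))):
            raise ValueError("edit spans a splice boundary")
        if model.strand == "+":
            return lo, ref, alt
        return lo, _revcomp(ref), _revcomp(alt)
    # pure insertion between pos-1 and pos
    left = model.genomic_to_cds(pos - 1)
    right = model.genomic_to_cds(pos)
    if not (left.is_coding and right.is_coding):
        raise ValueError("insertion point not inside the CDS")
    if abs(left.cds_pos - right.cds_pos) != 1:
        raise ValueError("insertion point spans a splice boundary")
    if model.strand == "+":
        return right.cds_pos, "", alt
    return left.cds_pos, "", _revcomp(alt)


def _shift_3prime(cds: str, s: int, ref_seg: str, alt_seg: str) -> tuple[int, str, str]:
    """3'-most equivalent placement of a pure del/ins within the CDS (notation only)."""
    r, a = len(ref_seg), len(alt_seg)
    if r > 0 and a == 0:  # deletion of cds[s-1 : s-1+r]
        while s + r - 1 < len(cds) and cds[s - 1] == cds[s - 1 + r]:
            s += 1
        return s, cds[s - 1 : s - 1 + r], ""
    if r == 0 and a > 0:  # insertion before cds position s
        ins = alt_seg
        while s - 1 < len(cds) and cds[s - 1] == ins[0]:
            ins = ins[1:] + ins[0]
            s += 1
        return s, "", ins
    return s, ref_seg, alt_seg


def _cds_notation(s: int, ref_seg: str, alt_seg: str) -> str:
    r, a = len(ref_seg), len(alt_seg)
    if r == 1 and a == 1:
        return f"c.{s}{ref_seg}>{alt_seg}"
    if a == 0:
        return f"c.{s}del{ref_seg}" if r == 1 else f"c.{s}_{s + r - 1}del{ref_seg}"
    if r == 0:
        return f"c.{s - 1}_{s}ins{alt_seg}"
    return f"c.{s}_{s + r - 1}delins{alt_seg}"


def apply_variant_translate(model: GeneModel, variant: Variant) -> ProteinConsequence:
    """Apply a small variant to the CDS, translate, and derive the consequence.

    The variant (VCF-style, anchors allowed) is trimmed to its minimal edit,
    which must lie fully within the CDS of `model`. Reference and mutant CDS
    are translated with the standard genetic code; the first altered residue,
    the premature-stop position and truncation statistics are derived from
    the two proteins.
    """
    if str(variant.chrom) != model.chrom:
        raise ValueError(f"variant on {variant.chrom}, gene on {model.chrom}")
    pos, ref_seg, alt_seg = _minimal_edit(model, variant)
    ref_cds = model.cds_sequence()
    ref_prot = str(Seq(ref_cds).translate())[:-1]
    ref_len = len(ref_prot)

    if not ref_seg and not alt_seg:
        return ProteinConsequence(
            kind="synonymous", ref_len=ref_len, mutant_len=ref_len, frameshift=False,
            first_altered=None, termination_index=None, residues_lost=0,
            percent_lost=0, cds_notation="c.=", protein_notation="p.=",
        )

    s, cref, calt = _project_edit(model, pos, ref_seg, alt_seg)
    mutant_cds = ref_cds[: s - 1] + calt + ref_cds[s - 1 + len(cref):]
    s_norm, cref_norm, calt_norm = _shift_3prime(ref_cds, s, cref, calt)
    cds_notation = _cds_notation(s_norm, cref_norm, calt_norm)

    if ref_cds[:3] == "ATG" and mutant_cds[:3] != "ATG":
        return ProteinConsequence(
            kind="start-lost", ref_len=ref_len, mutant_len=None, frameshift=False,
            first_altered=1, termination_index=None, residues_lost=None,
            percent_lost=None, cds_notation=cds_notation, protein_notation="p.M1?",
        )

    frameshift = (len(cref) - len(calt)) % 3 != 0
    mut_trim = mutant_cds[: len(mutant_cds) - len(mutant_cds) % 3]
    mut_full = str(Seq(mut_trim).translate())
    stop_idx = mut_full.find("*")
    stop_found = stop_idx >= 0
    mutant_len = stop_idx if stop_found else len(mut_full)
    mut_prot = mut_full[:mutant_len]

    first_altered: Optional[int] = None
    for i in range(min(ref_len, mutant_len)):
        if ref_prot[i] != mut_prot[i]:
            first_altered = i + 1
            break
    if first_altered is None and (mutant_len != ref_len or not stop_found):
        first_altered = min(ref_len, mutant_len) + 1

    termination_index = mutant_len + 1 if stop_found else None
    residues_lost = ref_len - mutant_len
    percent_lost = int(round_half_up(100 * residues_lost / ref_len, 0))

    if first_altered is None:
        kind = "synonymous"
        protein_notation = "p."
        if mut_prot != ref_prot:  # same length, some residue changed? unreachable here
            kind = "substitution"
    elif frameshift:
        kind = "frameshift"
        ref_aa = ref_prot[first_altered - 1] if first_altered <= ref_len else "*"
        if stop_found:
            k = termination_index - first_altered + 1
            protein_notation = f"p.{ref_aa}{first_altered}fs{k}"
        else:
            protein_notation = f"p.{ref_aa}{first_altered}fs"
    else:
        ref_aa = ref_prot[first_altered - 1] if first_altered <= ref_len else "*"
        if len(cref) == len(calt) == 1:
            if stop_found and mutant_len < ref_len and termination_index == first_altered:
                kind = "substitution"
                protein_notation = f"p.{ref_aa}{first_altered}*"
            else:
                kind = "substitution"
                mut_aa = mut_prot[first_altered - 1] if first_altered <= mutant_len else "*"
                protein_notation = f"p.{ref_aa}{first_altered}{mut_aa}"
        else:
            kind = "in-frame"
            protein_notation = f"p.{ref_aa}{first_altered}_inframe"

    return ProteinConsequence(
        kind=kind, ref_len=ref_len, mutant_len=mutant_len, frameshift=frameshift,
        first_altered=first_altered, termination_index=termination_index,
        residues_lost=residues_lost, percent_lost=percent_lost,
        cds_notation=cds_notation, protein_notation=protein_notation,
    )
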