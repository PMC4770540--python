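"""Readers and writers: PED/MAP genotypes, VCF, FASTA, GFF3, TSV reports.

Internal coordinates are 1-based inclusive everywhere; conversion to BED's
0-based half-open convention happens only in the BED writers.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import GeneModel
from .core import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval, chrom_sort_key
from .qc import GenotypeMatrix, MarkerMap
from .roh import ROHSegment
from .synthetic import Individual, Pedigree
from .variants import VariantTable

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    ped_path: str | Path,
    map_path: str | Path,
    pedigree: Pedigree | None = None,
) -> None:
    """Write whitespace-delimited PED/MAP files.

    The MAP file carries six columns (chrom, marker id, cM placeholder, bp,
    ref allele, alt allele); the declared alleles let a reader collapse PED
    allele pairs back into the 4-state genotype codes. Unplaced markers are
    written with chromosome 0.
    """
    sub = marker_map.subset(genotypes.marker_ids)
    with open(map_path, "w") as fh:
        for row in sub.df.itertuples(index=False):
            chrom = "0" if row.chrom == "unknown" else row.chrom
            a1 = getattr(row, "allele_ref", "A")
            a2 = getattr(row, "allele_alt", "B")
            fh.write(f"{chrom}\t{row.marker_id}\t0\t{row.pos}\t{a1}\t{a2}\n")

    a1s = sub.df.get("allele_ref", pd.Series(["A"] * len(sub))).to_numpy()
    a2s = sub.df.get("allele_alt", pd.Series(["B"] * len(sub))).to_numpy()
    sex_code = {"M": "1", "F": "2"}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(genotypes.individual_ids):
            sire = dam = "0"
            sex = "0"
            if pedigree is not None and ind in {x.id for x in pedigree.individuals}:
                rec = pedigree[ind]
                sire = rec.sire or "0"
                dam = rec.dam or "0"
                sex = sex_code.get(rec.sex, "0")
            fields = ["FAM1", ind, sire, dam, sex, "0"]
            row = genotypes.calls[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == HOM_REF:
                    fields += [a1s[j], a1s[j]]
                elif g == HET:
                    fields += [a1s[j], a2s[j]]
                else:
                    fields += [a2s[j], a2s[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PED/MAP text into a genotype matrix and marker map.

    Allele pairs are collapsed against the MAP file's declared alleles
    (columns 5-6; 'A'/'B' assumed for 4-column MAP files); ``0 0`` means
    missing. Ragged rows or undeclared alleles raise with the line number.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise ValueError(f"{map_path}:{lineno}: expected 4 or 6 MAP columns")
            chrom = "unknown" if parts[0] == "0" else parts[0]
            a1, a2 = (parts[4], parts[5]) if len(parts) == 6 else ("A", "B")
            map_rows.append(
                {"marker_id": parts[1], "chrom": chrom, "pos": int(parts[3]),
                 "allele_ref": a1, "allele_alt": a2}
            )
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    n_mark = len(marker_map)
    a1s = marker_map.df["allele_ref"].to_numpy()
    a2s = marker_map.df["allele_alt"].to_numpy()

    individual_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_mark} fields, got {len(parts)}"
                )
            individual_ids.append(parts[1])
            calls = np.empty(n_mark, dtype=np.int8)
            for j in range(n_mark):
                x, y = parts[6 + 2 * j], parts[7 + 2 * j]
                if x == "0" or y == "0":
                    calls[j] = MISSING
                    continue
                n_alt = 0
                for allele in (x, y):
                    if allele == a2s[j]:
                        n_alt += 1
                    elif allele != a1s[j]:
                        raise ValueError(
                            f"{ped_path}:{lineno}: allele {allele!r} at marker "
                            f"{marker_map.marker_ids[j]} not among declared "
                            f"{a1s[j]}/{a2s[j]}"
                        )
                calls[j] = (HOM_REF, HET, HOM_ALT)[n_alt]
            rows.append(calls)
    return (
        GenotypeMatrix(
            individual_ids=individual_ids,
            marker_ids=marker_map.marker_ids,
            calls=np.vstack(rows) if rows else np.empty((0, n_mark), dtype=np.int8),
        ),
        marker_map,
    )


# ---------------------------------------------------------------------------
# roster / pedigree TSV
# ---------------------------------------------------------------------------

def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, sep="\t", index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    roster = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "cohort", "breed"}
    if not required <= set(roster.columns):
        raise ValueError(f"roster {path} must have columns {sorted(required)}")
    return roster


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    rows = [
        {"id": i.id, "sire": i.sire or "0", "dam": i.dam or "0",
         "sex": i.sex, "cohort": i.cohort}
        for i in pedigree.individuals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    inds = [
        Individual(
            id=r.id,
            sire=None if r.sire == "0" else r.sire,
            dam=None if r.dam == "0" else r.dam,
            sex=r.sex,
            cohort=r.cohort,
        )
        for r in df.itertuples(index=False)
    ]
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT genotypes for every roster individual."""
    chroms = sorted(table.sites["chrom"].unique(), key=chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        samples = table.individuals
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, row in enumerate(table.sites.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(g)] for g in table.genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path, roster: pd.DataFrame | str | Path) -> VariantTable:
    """Read a VCF with GT fields into a VariantTable.

    Multi-allelic records are decomposed into biallelic rows (one per alt
    allele); genotypes carrying a *different* alt allele are treated as
    missing in the decomposed record. Phased separators are accepted. Every
    VCF sample must appear in the roster.
    """
    from cyvcf2 import VCF

    if not isinstance(roster, pd.DataFrame):
        roster = read_roster(roster)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    known = set(roster["individual"])
    absent = [s for s in samples if s not in known]
    if absent:
        raise ValueError(f"VCF samples absent from roster: {absent[:5]}")
    roster_sub = roster.set_index("individual").loc[samples].reset_index()

    site_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    for record in vcf:
        gts = record.genotypes  # [a0, a1, phased] per sample
        for k, alt in enumerate(record.ALT, start=1):
            calls = np.empty(len(samples), dtype=np.int8)
            for s, g in enumerate(gts):
                a = [x for x in g[:-1] if x is not None]
                if len(a) != 2 or min(a) < 0:
                    calls[s] = MISSING
                elif a[0] == 0 and a[1] == 0:
                    calls[s] = HOM_REF
                elif a[0] == k and a[1] == k:
                    calls[s] = HOM_ALT
                elif k in a and 0 in a:
                    calls[s] = HET
                else:  # carries some other alt allele
                    calls[s] = MISSING
            vclass = "SNP" if len(record.REF) == 1 and len(alt) == 1 else "indel"
            site_rows.append(
                {"chrom": str(record.CHROM), "pos": int(record.POS),
                 "ref": record.REF, "alt": alt, "vclass": vclass}
            )
            geno_rows.append(calls)
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantTable(sites=sites, genotypes=genotypes, roster=roster_sub)


# ---------------------------------------------------------------------------
# FASTA / GFF3 gene models
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_fasta(model: GeneModel, path: str | Path) -> None:
    """Write the model's chromosome with N padding up to the cached locus."""
    padded = "N" * (model.locus_start - 1) + model.locus_seq
    write_fasta({model.chrom: padded}, path)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (m.exons[0].start, m.exons[-1].end)
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\tautozygmap\tgene\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tautozygmap\texon\t{e.start}\t{e.end}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )
            for i, c in enumerate(m.cds_intervals(), 1):
                fh.write(
                    f"{m.chrom}\tautozygmap\tCDS\t{c.start}\t{c.end}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n"
                )


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 (gene/exon/CDS features) and a FASTA."""
    import gffutils
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (GenomicInterval(str(gene.seqid), f.start, f.end)
             for f in db.children(gene, featuretype="exon")),
            key=lambda iv: iv.start,
        )
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons or not cds:
            raise ValueError(f"gene {gene.id} lacks exon or CDS features")
        chrom = str(gene.seqid)
        if chrom not in seqs:
            raise ValueError(f"chromosome {chrom} missing from FASTA")
        locus_start = exons[0].start
        locus_seq = seqs[chrom][locus_start - 1 : exons[-1].end]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=chrom,
                strand=gene.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
                locus_start=locus_start,
                locus_seq=locus_seq,
            )
        )
    return models


# ---------------------------------------------------------------------------
# ROH segments and mapped regions
# ---------------------------------------------------------------------------

def write_roh_tsv(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """Native 1-based inclusive ROH table."""
    rows = [
        {"individual": s.individual, "chrom": s.chrom, "start": s.start,
         "end": s.end, "n_snps": s.n_snps, "length_bp": s.length_bp}
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["individual", "chrom", "start", "end", "n_snps", "length_bp"]
    ).to_csv(path, sep="\t", index=False)


def read_roh_tsv(path: str | Path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ROHSegment(
            individual=str(r.individual), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), n_snps=int(r.n_snps),
        )
        for r in df.itertuples(index=False)
    ]


def write_roh_bed(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """BED (0-based half-open) projection of ROH segments."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.individual}\t{s.n_snps}\n")


def write_regions_tsv(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    from .mapping import interval_length_mb

    rows = [
        {"chrom": r.chrom, "start": r.start, "end": r.end,
         "length_bp": r.length_bp, "length_mb": interval_length_mb(r)}
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length_bp", "length_mb"]
    ).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples(index=False)]


def write_regions_bed(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
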