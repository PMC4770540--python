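"""End-to-end pipeline: QC -> ROH -> mapping -> variant filtering -> annotation -> stats.

Runs the whole autozygosity-mapping analysis from files on disk and writes
per-stage outputs plus a machine-readable ``summary.json``. The summary
contains no timestamps, so a rerun with identical inputs and configuration
is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as amio
from .consequence import apply_variant_translate, genomic_to_cds
from .core import GenomicInterval, Variant
from .mapping import exclude_control_homozygous, interval_length_mb, intersect_case_roh
from .popgen import GenotypeCounts, allele_frequency, expected_affected
from .qc import filter_autosomal, filter_call_rate, filter_hwe
from .roh import ROHParams, scan_all
from .variants import (
    classify_coding,
    panel_segregation_filter,
    recessive_compatible,
    restrict_to_region,
)
from .core import HET, HOM_ALT, HOM_REF

logger = logging.getLogger("autozygmap")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    ped: str
    map: str
    roster: str
    vcf: str
    gff3: str
    fasta: str
    out_dir: str
    min_call_rate: float = 0.9
    hwe_alpha: float = 1e-4
    roh_min_snps: int = 20
    roh_min_length_bp: int = 500_000
    roh_max_het: int = 0
    roh_max_missing: int = 2
    excluded_breeds: tuple[str, ...] = ("Ayrshire", "SwedishRed", "DanishRed")
    min_control_called_frac: float = 0.9
    region: Optional[str] = None  # "chrom:start-end" override of the mapped region

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "excluded_breeds" in raw:
            raw["excluded_breeds"] = tuple(raw["excluded_breeds"])
        return cls(**raw)

    def roh_params(self) -> ROHParams:
        return ROHParams(
            min_snps=self.roh_min_snps,
            min_length_bp=self.roh_min_length_bp,
            max_het=self.roh_max_het,
            max_missing=self.roh_max_missing,
        )

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_breeds"] = list(self.excluded_breeds)
        return d


def _parse_region(spec: str) -> GenomicInterval:
    chrom, span = spec.split(":")
    start, end = span.replace(",", "").split("-")
    return GenomicInterval(chrom, int(start), int(end))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary dictionary.

    Stage order: autosome/call-rate/HWE QC, per-individual ROH scan,
    case-ROH intersection with half-sib exclusion, interval variant
    filtering (recessive compatibility against controls, then panel
    segregation), coding classification and consequence annotation, and
    candidate allele-frequency statistics over the sequenced cohorts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "effective_config.json", "w") as fh:
        json.dump(config.effective(), fh, indent=2, sort_keys=True)
    logger.info("effective configuration: %s", config.effective())

    roster = amio.read_roster(config.roster)
    case_ids = roster.loc[roster["cohort"] == "case", "individual"].tolist()
    control_ids = roster.loc[roster["cohort"] == "control", "individual"].tolist()
    if not case_ids:
        raise ValueError("configuration error: roster contains no case individuals")

    # --- stage 1: genotype QC -------------------------------------------
    genotypes, marker_map = amio.read_ped_map(config.ped, config.map)
    n_input_markers = genotypes.n_markers
    genotypes, marker_map = filter_autosomal(genotypes, marker_map)
    n_autosomal = genotypes.n_markers
    genotypes, cr_report = filter_call_rate(genotypes, config.min_call_rate)
    genotypes, hwe_report = filter_hwe(genotypes, config.hwe_alpha)
    reports = [r for r in (cr_report, hwe_report) if not r.empty]
    qc_report = (
        pd.concat(reports, ignore_index=True) if reports else cr_report
    )
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    logger.info(
        "QC: %d -> %d autosomal -> %d post-filter markers, %d individuals",
        n_input_markers, n_autosomal, genotypes.n_markers, genotypes.n_individuals,
    )

    # --- stage 2: ROH ----------------------------------------------------
    segments = scan_all(genotypes, marker_map, config.roh_params())
    amio.write_roh_tsv(segments, out / "roh.tsv")
    amio.write_roh_bed(segments, out / "roh.bed")

    # --- stage 3: autozygosity mapping ----------------------------------
    cases_present = [c for c in case_ids if c in genotypes.individual_ids]
    if not cases_present:
        raise ValueError("no case individual survived genotype QC")
    by_ind: dict[str, list] = {}
    for s in segments:
        by_ind.setdefault(s.individual, []).append(s)
    case_segments = [by_ind.get(c, []) for c in cases_present]
    candidate_regions = intersect_case_roh(case_segments)
    noncase_array = [
        i for i in genotypes.individual_ids if i not in set(case_ids)
    ]
    control_segments = [by_ind.get(i, []) for i in noncase_array]
    regions, exclusion_report = exclude_control_homozygous(candidate_regions, control_segments)
    exclusion_report.to_csv(out / "region_exclusion.tsv", sep="\t", index=False)
    amio.write_regions_tsv(regions, out / "regions.tsv")
    amio.write_regions_bed(regions, out / "regions.bed")
    if config.region is not None:
        regions = [_parse_region(config.region)]
    logger.info("mapped regions: %s", [(r.chrom, r.start, r.end) for r in regions])

    # --- stage 4: variant filtering --------------------------------------
    table = amio.read_vcf(config.vcf, roster)
    gene_models = amio.read_gene_models(config.gff3, config.fasta)
    stage_counts = []
    survivors = []
    for region in regions:
        sub = restrict_to_region(table, region)
        n_region = sub.n_sites
        sub, _ = recessive_compatible(
            sub, cases_present, control_ids, config.min_control_called_frac
        )
        n_compatible = sub.n_sites
        sub = panel_segregation_filter(sub, excluded_breeds=config.excluded_breeds)
        n_panel = sub.n_sites
        labels = classify_coding(sub, gene_models)
        stage_counts.append(
            {
                "region": {"chrom": region.chrom, "start": region.start, "end": region.end},
                "n_in_region": n_region,
                "n_recessive_compatible": n_compatible,
                "n_after_panel_filter": n_panel,
                "n_coding": int((labels == "coding").sum()),
                "n_non_coding": int((labels == "non-coding").sum()),
            }
        )
        for i in range(sub.n_sites):
            survivors.append((sub.sites.iloc[i], sub.genotypes[i], labels[i], sub.roster))

    # --- stage 5: consequence annotation + stats -------------------------
    candidates = []
    for site, genos, label, sub_roster in survivors:
        variant = Variant(
            chrom=str(site["chrom"]), pos=int(site["pos"]),
            ref=str(site["ref"]), alt=str(site["alt"]),
        )
        record: dict = {
            "chrom": variant.chrom, "pos": variant.pos, "ref": variant.ref,
            "alt": variant.alt, "vclass": str(site["vclass"]), "classification": label,
        }
        if label == "coding":
            model = next(
                m for m in gene_models
                if m.chrom == variant.chrom
                and any(genomic_to_cds(m, p).is_coding
                        for p in range(variant.pos, variant.pos + len(variant.ref)))
            )
            csq = apply_variant_translate(model, variant)
            cds_proj = None
            for p in range(variant.pos, variant.pos + len(variant.ref)):
                proj = genomic_to_cds(model, p)
                if proj.is_coding:
                    cds_proj = proj.cds_pos
                    break
            record["gene"] = model.gene_id
            record["cds_pos"] = cds_proj
            record["consequence"] = {
                "kind": csq.kind,
                "ref_len": csq.ref_len,
                "mutant_len": csq.mutant_len,
                "frameshift": csq.frameshift,
                "first_altered": csq.first_altered,
                "termination_index": csq.termination_index,
                "residues_lost": csq.residues_lost,
                "percent_lost": csq.percent_lost,
                "cds_notation": csq.cds_notation,
                "protein_notation": csq.protein_notation,
            }
        seq_cols = sub_roster["cohort"].isin(["control", "panel"]).to_numpy()
        g = genos[seq_cols]
        counts = GenotypeCounts(
            int((g == HOM_REF).sum()), int((g == HET).sum()), int((g == HOM_ALT).sum())
        )
        freq = allele_frequency(counts)
        record["sequenced_cohort_stats"] = {
            "n_homref": counts.n_homref, "n_het": counts.n_het,
            "n_homalt": counts.n_homalt,
            "alt_frequency_percent": freq.percent,
            "expected_affected_per_100": expected_affected(freq.frequency, 100)[0],
        }
        candidates.append(record)

    summary = {
        "markers": {
            "input": n_input_markers,
            "autosomal": n_autosomal,
            "post_qc": genotypes.n_markers,
        },
        "individuals_post_qc": genotypes.n_individuals,
        "n_roh_segments": len(segments),
        "mapped_regions": [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "length_mb": interval_length_mb(r),
            }
            for r in regions
        ],
        "variant_filtering": stage_counts,
        "candidates": candidates,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
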