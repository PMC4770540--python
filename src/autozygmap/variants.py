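"""Recessive-compatibility variant filtering against control and panel cohorts.

The filtering cascade mirrors how a recessive candidate mutation is isolated
from multi-sample sequence data once a disease interval is mapped:

1. restrict the variant table to the mapped interval,
2. keep sites homozygous-alt in every affected individual and
   homozygous-ref in every called control (recessive compatibility),
3. drop sites at which any animal of a wider multi-breed panel — minus
   breeds closely related to the cases' breed — carries the alternate
   allele (a breed-specific recessive should not segregate elsewhere),
4. classify survivors as coding/non-coding against gene models.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass"]
COHORTS = {"case", "control", "panel", "halfsib"}


@dataclass
class VariantTable:
    """Per-site variant records with per-individual genotype codes.

    `sites` columns: chrom, pos (1-based), ref, alt, vclass (SNP|indel).
    `genotypes` is int8 of shape (n_sites, n_individuals), aligned with the
    `roster` rows (columns: individual, cohort, breed).
    """

    sites: pd.DataFrame = field(repr=False)
    genotypes: np.ndarray = field(repr=False)
    roster: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        sites = self.sites.reset_index(drop=True).copy()
        sites["chrom"] = sites["chrom"].astype(str)
        missing_cols = set(SITE_COLUMNS) - set(sites.columns)
        if missing_cols:
            raise ValueError(f"site table missing columns: {sorted(missing_cols)}")
        if (sites["ref"] == sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ at every site")
        for chrom, grp in sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within chromosome {chrom}")
        self.sites = sites
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        roster = self.roster.reset_index(drop=True).copy()
        if not {"individual", "cohort", "breed"} <= set(roster.columns):
            raise ValueError("roster requires columns individual, cohort, breed")
        unknown = set(roster["cohort"]) - COHORTS
        if unknown:
            raise ValueError(f"unknown cohort labels: {sorted(unknown)}")
        self.roster = roster
        if self.genotypes.shape != (len(self.sites), len(self.roster)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.roster)} individuals"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def individuals(self) -> list[str]:
        return self.roster["individual"].tolist()

    def cohort_columns(self, cohort: str) -> np.ndarray:
        return np.flatnonzero((self.roster["cohort"] == cohort).to_numpy())

    def columns_for(self, individual_ids: Sequence[str]) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [i for i in individual_ids if i not in lookup]
        if missing:
            raise KeyError(f"individuals absent from roster: {missing[:5]}")
        return np.array([lookup[i] for i in individual_ids], dtype=np.intp)

    def subset_sites(self, index: np.ndarray) -> "VariantTable":
        index = np.asarray(index)
        return VariantTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index, :],
            roster=self.roster,
        )


def restrict_to_region(table: VariantTable, region: GenomicInterval) -> VariantTable:
    """Sites with region.start <= pos <= region.end on the region's chromosome."""
    mask = (
        (table.sites["chrom"] == region.chrom)
        & (table.sites["pos"] >= region.start)
        & (table.sites["pos"] <= region.end)
    ).to_numpy()
    return table.subset_sites(np.flatnonzero(mask))


def recessive_compatible(
    table: VariantTable,
    cases: Sequence[str],
    controls: Sequence[str],
    min_control_called_frac: float = 0.9,
) -> tuple[VariantTable, pd.DataFrame]:
    """Sites homozygous-alt in all cases and homozygous-ref in all called controls.

    A site is dropped when any case genotype is missing or not hom-alt, when
    any called control is not hom-ref, or when fewer than
    `min_control_called_frac` of the controls are called (missing control
    calls are otherwise neutral). Returns the filtered table and a per-site
    report with an `n_control_called` counter.
    """
    if len(cases) == 0:
        raise ValueError("at least one case is required")
    case_cols = table.columns_for(cases)
    ctrl_cols = table.columns_for(controls)
    g_case = table.genotypes[:, case_cols]
    g_ctrl = table.genotypes[:, ctrl_cols]

    case_ok = (g_case == HOM_ALT).all(axis=1)
    ctrl_called = (g_ctrl != MISSING).sum(axis=1)
    ctrl_ok = ((g_ctrl == HOM_REF) | (g_ctrl == MISSING)).all(axis=1)
    if len(controls):
        called_ok = ctrl_called >= min_control_called_frac * len(controls)
    else:
        called_ok = np.ones(table.n_sites, dtype=bool)
    keep = case_ok & ctrl_ok & called_ok

    report = table.sites[["chrom", "pos", "ref", "alt"]].copy()
    report["n_control_called"] = ctrl_called
    report["case_hom_alt"] = case_ok
    report["control_hom_ref"] = ctrl_ok
    report["retained"] = keep
    return table.subset_sites(np.flatnonzero(keep)), report


def panel_segregation_filter(
    table: VariantTable,
    panel: Sequence[str] | None = None,
    excluded_breeds: Iterable[str] = (),
) -> VariantTable:
    """Drop sites at which the alternate allele segregates in the kept panel.

    Panel members whose breed is in `excluded_breeds` are ignored entirely;
    among the remaining panel animals, any het or hom-alt call removes the
    site. `panel=None` uses every roster individual with cohort == "panel".
    Unknown breed labels in `excluded_breeds` trigger a warning and are
    ignored.
    """
    if panel is None:
        panel_cols = table.cohort_columns("panel")
    else:
        panel_cols = table.columns_for(panel)
    breeds = table.roster["breed"].to_numpy()
    known = set(breeds[panel_cols])
    excluded = set(excluded_breeds)
    unknown = excluded - known
    if unknown:
        warnings.warn(
            f"excluded breeds absent from panel (ignored): {sorted(unknown)}",
            stacklevel=2,
        )
    kept_cols = panel_cols[~np.isin(breeds[panel_cols], sorted(excluded))]
    g = table.genotypes[:, kept_cols]
    carries_alt = ((g == HET) | (g == HOM_ALT)).any(axis=1)
    return table.subset_sites(np.flatnonzero(~carries_alt))


def classify_coding(table: VariantTable, gene_models: Sequence) -> np.ndarray:
    """Label each site "coding" or "non-coding" against gene-model CDS spans.

    A site is coding iff any affected reference base overlaps a CDS interval
    of any model. For a SNP that is the site position itself; for an indel
    the affected bases are the full reference footprint (anchor included)
    plus, for pure insertions, the base immediately 3' of the anchor, so an
    insertion inside a codon is caught.
    """
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for model in gene_models:
        for iv in model.cds_intervals():
            cds_by_chrom.setdefault(str(model.chrom), []).append((iv.start, iv.end))

    labels = np.empty(table.n_sites, dtype=object)
    for i, row in enumerate(table.sites.itertuples(index=False)):
        span_start = int(row.pos)
        span_end = int(row.pos) + len(row.ref) - 1
        if len(row.alt) > len(row.ref):  # insertion: include the next reference base
            span_end += 1
        hit = any(
            s <= span_end and span_start <= e
            for s, e in cds_by_chrom.get(str(row.chrom), [])
        )
        labels[i] = "coding" if hit else "non-coding"
    return labels
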