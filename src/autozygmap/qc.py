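"""Array-genotype quality control.

Marker- and individual-level filters as used in autozygosity mapping from
SNP-array data: autosome restriction, per-marker and per-individual call
rate, and an exact Hardy-Weinberg equilibrium test. The HWE test is the
exact conditional test (enumeration of heterozygote counts given allele
counts), which stays well defined at the cohort sizes typical for mapping
studies of rare recessive defects (tens of animals).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import GENOTYPE_CODES, HET, HOM_ALT, HOM_REF, MISSING

AUTOSOMES = frozenset(str(i) for i in range(1, 30))
VALID_CHROMS = AUTOSOMES | {"X", "Y", "MT", "unknown"}

_LN2 = float(np.log(2.0))


@dataclass
class MarkerMap:
    """Marker positions: id, chromosome label and 1-based bp coordinate.

    Chromosome labels are drawn from {1..29, X, Y, MT, unknown} (taurine
    autosome count); positions must be strictly increasing within each
    chromosome in row order. Optional `allele_ref`/`allele_alt` columns
    declare the two alleles used to collapse PED allele pairs.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos"}
        missing_cols = required - set(self.df.columns)
        if missing_cols:
            raise ValueError(f"marker map missing columns: {sorted(missing_cols)}")
        df = self.df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        bad = set(df["chrom"]) - VALID_CHROMS
        if bad:
            raise ValueError(f"invalid chromosome labels in marker map: {sorted(bad)}")
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        for chrom, grp in df.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return self.df["marker_id"].tolist()

    def subset(self, marker_ids: Sequence[str]) -> "MarkerMap":
        """Rows for `marker_ids`, preserving the requested order."""
        idx = self.df.set_index("marker_id")
        missing = [m for m in marker_ids if m not in idx.index]
        if missing:
            raise KeyError(f"markers absent from map: {missing[:5]}")
        return MarkerMap(idx.loc[list(marker_ids)].reset_index())


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for individuals x markers.

    Calls are int8 codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if not np.isin(self.calls, GENOTYPE_CODES).all():
            raise ValueError("genotype calls outside the {hom-ref, het, hom-alt, missing} alphabet")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in index],
            calls=self.calls[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            calls=self.calls[index, :],
        )

    def marker_call_rate(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.full(self.n_markers, np.nan)
        return (self.calls != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.full(self.n_individuals, np.nan)
        return (self.calls != MISSING).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n_homref, n_het, n_homalt) counts, shape (n_markers, 3)."""
        out = np.empty((self.n_markers, 3), dtype=np.int64)
        for k, code in enumerate((HOM_REF, HET, HOM_ALT)):
            out[:, k] = (self.calls == code).sum(axis=0)
        return out

    def vector(self, individual_id: str, marker_index: np.ndarray | None = None) -> np.ndarray:
        i = self.individual_ids.index(individual_id)
        row = self.calls[i]
        return row if marker_index is None else row[np.asarray(marker_index)]


def filter_autosomal(
    genotypes: GenotypeMatrix, marker_map: MarkerMap
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Keep only markers on autosomes 1..29, preserving marker order.

    X-, Y-, mitochondrial and unplaced markers are discarded. Every marker in
    the matrix must have a map entry.
    """
    sub = marker_map.subset(genotypes.marker_ids)
    keep = np.flatnonzero(sub.df["chrom"].isin(AUTOSOMES).to_numpy())
    return genotypes.take_markers(keep), MarkerMap(sub.df.iloc[keep].reset_index(drop=True))


def filter_call_rate(
    genotypes: GenotypeMatrix, min_rate: float = 0.9
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers, then individuals, with call rate below `min_rate`.

    An item is removed when its call rate is strictly below `min_rate`
    (retention requires a call rate of at least the threshold). Markers are
    filtered first, then individuals on the surviving markers; because each
    removal changes the other dimension's call rates, the two passes repeat
    until no further removal occurs, which makes the filter idempotent.
    Returns the filtered matrix and a removal report (item, kind, call_rate).
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    records: list[dict] = []
    g = genotypes

    changed = True
    while changed and g.n_markers and g.n_individuals:
        changed = False
        m_rate = g.marker_call_rate()
        drop_m = np.flatnonzero(m_rate < min_rate)
        if drop_m.size:
            changed = True
            for i in drop_m:
                records.append(
                    {"item": g.marker_ids[i], "kind": "marker",
                     "reason": "call_rate", "statistic": float(m_rate[i])}
                )
            g = g.take_markers(np.flatnonzero(m_rate >= min_rate))
        if not g.n_markers:
            break
        i_rate = g.individual_call_rate()
        drop_i = np.flatnonzero(i_rate < min_rate)
        if drop_i.size:
            changed = True
            for i in drop_i:
                records.append(
                    {"item": g.individual_ids[i], "kind": "individual",
                     "reason": "call_rate", "statistic": float(i_rate[i])}
                )
            g = g.take_individuals(np.flatnonzero(i_rate >= min_rate))

    report = pd.DataFrame(records, columns=["item", "kind", "reason", "statistic"])
    return g, report


def hwe_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, enumerates all heterozygote
    counts of matching parity and sums the probabilities of configurations no
    more likely than the observed one (two-sided exact test). Monomorphic
    sites return 1.0.
    """
    counts = (int(n_homref), int(n_het), int(n_homalt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one called genotype required")
    n_alt = 2 * counts[2] + counts[1]
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    rare_homs = (rare - hets) // 2
    common_homs = n - hets - rare_homs
    # log P(het count) under the conditional (Levene) distribution
    logp = (
        gammaln(n + 1)
        - gammaln(rare_homs + 1)
        - gammaln(hets + 1)
        - gammaln(common_homs + 1)
        + hets * _LN2
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.flatnonzero(hets == counts[1])[0]]
    p = probs[probs <= observed * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    counts = genotypes.genotype_counts()
    out = np.ones(genotypes.n_markers)
    for i, (a, b, c) in enumerate(counts):
        if a + b + c > 0:
            out[i] = hwe_test(a, b, c)
    return out


def filter_hwe(
    genotypes: GenotypeMatrix, alpha: float = 1e-4
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers deviating from Hardy-Weinberg equilibrium (p <= alpha).

    Markers are retained only when p > alpha, matching a "no deviation from
    HWE (P > 1e-4)" retention rule. Markers with zero called genotypes are
    retained (call-rate filtering is responsible for those).
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    pvals = hwe_pvalues(genotypes)
    keep = np.flatnonzero(pvals > alpha)
    removed = np.flatnonzero(pvals <= alpha)
    report = pd.DataFrame(
        [
            {"item": genotypes.marker_ids[i], "kind": "marker",
             "reason": "hwe", "statistic": float(pvals[i])}
            for i in removed
        ],
        columns=["item", "kind", "reason", "statistic"],
    )
    return genotypes.take_markers(keep), report
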