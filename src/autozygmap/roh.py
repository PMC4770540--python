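"""Runs-of-homozygosity detection.

A run is defined directly (no sliding-window heuristic): a maximal stretch
of consecutive markers, bounded on both ends by homozygous calls, that
contains at most `max_het` heterozygous and at most `max_missing` missing
calls. Runs qualify when they hold at least `min_snps` homozygous calls and
span at least `min_length_bp`. With the defaults (20 homozygous SNPs,
500 kb, no heterozygote allowed) this realises the classic
"20 contiguous homozygous SNPs over >= 500 kb" criterion for sparse
~50k arrays; the small missing-call allowance substitutes for imputation
of sporadically missing genotypes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import HET, HOM_ALT, HOM_REF, MISSING, chrom_sort_key
from .qc import GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 20
    min_length_bp: int = 500_000
    max_het: int = 0
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.min_length_bp < 0 or self.max_het < 0 or self.max_missing < 0:
            raise ValueError("ROH parameters must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """A detected run: 1-based inclusive bp span of the outermost homozygous SNPs."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int  # homozygous calls inside the run

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def scan_roh(
    genotypes: Sequence[int] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    params: ROHParams = ROHParams(),
    *,
    individual: str = "",
    chrom: str = "",
) -> list[ROHSegment]:
    """Scan one individual's genotype vector along one chromosome.

    `genotypes` uses the package's 4-state codes and must align with the
    strictly increasing `positions`. Candidate runs are windows with
    homozygous endpoints whose heterozygous/missing content is within the
    allowance; windows contained in a larger candidate are discarded, the
    min-SNP and min-length thresholds are applied, and of any overlapping
    survivors the leftmost is kept, so reported segments are maximal,
    positionally ordered and non-overlapping.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    pos = np.asarray(positions, dtype=np.int64)
    if g.shape != pos.shape or g.ndim != 1:
        raise ValueError("genotypes and positions must be 1-D arrays of equal length")
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    n = len(g)
    if n == 0:
        return []

    hom = (g == HOM_REF) | (g == HOM_ALT)
    if not hom.any():
        return []
    ph = np.concatenate(([0], np.cumsum(g == HET)))
    pm = np.concatenate(([0], np.cumsum(g == MISSING)))
    phom = np.concatenate(([0], np.cumsum(hom)))

    # prev_hom[j]: index of the last homozygous marker at or before j
    prev_hom = np.where(hom, np.arange(n), -1)
    np.maximum.accumulate(prev_hom, out=prev_hom)

    # For each homozygous start i, push the window end as far right as the
    # het/missing allowance permits; the feasible end is monotone in i, so a
    # single pointer suffices. Trim the end back to a homozygous call.
    candidates: list[tuple[int, int]] = []  # (start index, end index)
    j = 0
    last_end = -1
    for i in np.flatnonzero(hom):
        if j < i:
            j = int(i)
        while (
            j + 1 < n
            and ph[j + 2] - ph[i] <= params.max_het
            and pm[j + 2] - pm[i] <= params.max_missing
        ):
            j += 1
        end = int(prev_hom[j])
        # ends are non-decreasing in i: keeping only the first start per
        # distinct end discards windows contained in an earlier candidate
        if end > last_end:
            candidates.append((int(i), end))
            last_end = end

    # overlap resolution is purely positional (leftmost maximal window wins)
    # and happens before thresholding, so that raising min_snps/min_length
    # can only drop runs, never surface different ones
    tiling: list[tuple[int, int]] = []
    prev_kept_end = -1
    for i, e in candidates:
        if i <= prev_kept_end:
            continue
        tiling.append((i, e))
        prev_kept_end = e

    segments: list[ROHSegment] = []
    for i, e in tiling:
        n_hom = int(phom[e + 1] - phom[i])
        span = int(pos[e] - pos[i] + 1)
        if n_hom >= params.min_snps and span >= params.min_length_bp:
            segments.append(
                ROHSegment(
                    individual=individual,
                    chrom=str(chrom),
                    start=int(pos[i]),
                    end=int(pos[e]),
                    n_snps=n_hom,
                )
            )
    return segments


def scan_all(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Apply `scan_roh` per individual and chromosome on a QC'd matrix.

    Output is ordered by (individual roster order, chromosome, start).
    """
    sub = marker_map.subset(genotypes.marker_ids)
    chroms = sorted(sub.df["chrom"].unique(), key=chrom_sort_key)
    by_chrom = {
        c: np.flatnonzero((sub.df["chrom"] == c).to_numpy()) for c in chroms
    }
    segments: list[ROHSegment] = []
    for i, ind in enumerate(genotypes.individual_ids):
        row = genotypes.calls[i]
        for c in chroms:
            idx = by_chrom[c]
            segments.extend(
                scan_roh(
                    row[idx],
                    sub.df["pos"].to_numpy()[idx],
                    params,
                    individual=ind,
                    chrom=c,
                )
            )
    return segments
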