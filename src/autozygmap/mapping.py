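"""Autozygosity mapping: intersect case ROH, exclude regions homozygous in controls.

Coordinates are 1-based inclusive throughout; interval lengths in Mb are
(end - start + 1) / 1e6 with half-up rounding, which reproduces printed
interval sizes such as 8.42 Mb for 22,308,682..30,733,648.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .core import GenomicInterval, chrom_sort_key, round_half_up
from .roh import ROHSegment


def _union(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive spans; spans touching at adjacent bp coalesce."""
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_case_roh(
    case_segments: Sequence[Sequence[ROHSegment]],
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least one ROH of *every* case.

    `case_segments` holds one segment list per affected individual. Within a
    case, overlapping or bp-adjacent segments are treated as continuous
    coverage. Only chromosomes covered in all cases can contribute. The
    result is ordered by (chromosome, start) and is invariant under
    permutation of the cases.
    """
    if len(case_segments) == 0:
        raise ValueError("at least one case is required")
    per_case: list[dict[str, list[tuple[int, int]]]] = []
    for segs in case_segments:
        cover: dict[str, list[tuple[int, int]]] = {}
        for s in segs:
            cover.setdefault(s.chrom, []).append((s.start, s.end))
        per_case.append({c: _union(v) for c, v in cover.items()})

    shared_chroms = set(per_case[0])
    for cov in per_case[1:]:
        shared_chroms &= set(cov)

    regions: list[GenomicInterval] = []
    for chrom in sorted(shared_chroms, key=chrom_sort_key):
        acc = per_case[0][chrom]
        for cov in per_case[1:]:
            acc = _intersect(acc, cov[chrom])
            if not acc:
                break
        regions.extend(GenomicInterval(chrom, s, e) for s, e in acc)
    return regions


def exclude_control_homozygous(
    regions: Sequence[GenomicInterval],
    control_segments: Sequence[Sequence[ROHSegment]],
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Drop candidate regions fully covered by an ROH of any control.

    A region is excluded only when a single control run (after merging that
    control's overlapping runs) spans it entirely — a control homozygous over
    the whole candidate segment rules out the region, while partial overlap
    neither excludes nor trims. Returns the surviving regions and a report
    listing, per region, the controls whose homozygosity covered it.
    """
    per_control: list[tuple[str, dict[str, list[tuple[int, int]]]]] = []
    for segs in control_segments:
        if not segs:
            continue
        name = segs[0].individual
        cover: dict[str, list[tuple[int, int]]] = {}
        for s in segs:
            cover.setdefault(s.chrom, []).append((s.start, s.end))
        per_control.append((name, {c: _union(v) for c, v in cover.items()}))

    kept: list[GenomicInterval] = []
    records: list[dict] = []
    for region in regions:
        covering = [
            name
            for name, cover in per_control
            if any(s <= region.start and region.end <= e for s, e in cover.get(region.chrom, []))
        ]
        records.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "excluded": bool(covering),
                "covering_controls": ",".join(covering),
            }
        )
        if not covering:
            kept.append(region)
    report = pd.DataFrame(
        records, columns=["chrom", "start", "end", "excluded", "covering_controls"]
    )
    return kept, report


def interval_length_mb(interval: GenomicInterval, decimals: int = 2) -> float:
    """Interval length in megabases, half-up rounded at `decimals`."""
    return round_half_up(interval.length_bp / 1e6, decimals)
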