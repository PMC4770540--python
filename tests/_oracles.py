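"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by exhaustive enumeration or by literally
editing sequences, sharing no code path with the functions under test.
"""
from fractions import Fraction
from math import comb, factorial

import numpy as np
from Bio.Seq import Seq

from autozygmap.core import HET, HOM_ALT, HOM_REF, MISSING


def brute_force_roh(genotypes, positions, params):
    """Enumerate every marker sub-interval; keep maximal qualifying runs.

    Returns (start bp, end bp, n homozygous SNPs) tuples in positional order.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions)
    n = len(g)
    hom = (g == HOM_REF) | (g == HOM_ALT)
    ph = np.concatenate(([0], np.cumsum(g == HET)))
    pm = np.concatenate(([0], np.cumsum(g == MISSING)))
    phh = np.concatenate(([0], np.cumsum(hom)))

    windows = []
    for i in range(n):
        if not hom[i]:
            continue
        for j in range(i, n):
            if not hom[j]:
                continue
            if ph[j + 1] - ph[i] <= params.max_het and pm[j + 1] - pm[i] <= params.max_missing:
                windows.append((i, j))
    maximal = [
        w
        for w in windows
        if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in windows)
    ]
    maximal.sort()
    tiling = []
    last_end = -1
    for i, j in maximal:
        if i <= last_end:
            continue
        tiling.append((i, j))
        last_end = j
    out = []
    for i, j in tiling:
        n_hom = int(phh[j + 1] - phh[i])
        span = int(pos[j] - pos[i] + 1)
        if n_hom >= params.min_snps and span >= params.min_length_bp:
            out.append((int(pos[i]), int(pos[j]), n_hom))
    return out


def hwe_exact_enumeration(n_homref, n_het, n_homalt):
    """Exact-rational HWE p-value by full enumeration of heterozygote counts."""
    n = n_homref + n_het + n_homalt
    n_alt = 2 * n_homalt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0

    def prob(h):
        ra = (rare - h) // 2
        co = n - h - ra
        multinomial = Fraction(factorial(n), factorial(ra) * factorial(h) * factorial(co))
        return multinomial * 2**h * Fraction(
            factorial(rare) * factorial(2 * n - rare), factorial(2 * n)
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    observed = probs[n_het]
    return float(sum(p for p in probs.values() if p <= observed))


def grid_intersection(case_segment_lists, chrom_length):
    """Per-bp boolean coverage intersection over a bounded coordinate space."""
    chroms = set()
    for segs in case_segment_lists:
        chroms |= {s.chrom for s in segs}
    result = {}
    for chrom in chroms:
        cover = np.ones(chrom_length, dtype=bool)
        for segs in case_segment_lists:
            case_cov = np.zeros(chrom_length, dtype=bool)
            for s in segs:
                if s.chrom == chrom:
                    case_cov[s.start - 1 : s.end] = True
            cover &= case_cov
        runs = []
        in_run = False
        for i in range(chrom_length):
            if cover[i] and not in_run:
                start = i + 1
                in_run = True
            elif not cover[i] and in_run:
                runs.append((start, i))
                in_run = False
        if in_run:
            runs.append((start, chrom_length))
        if runs:
            result[chrom] = runs
    return result


def edit_and_translate(model, del_genomic_pos):
    """Delete one base from the genomic locus, re-splice, translate directly.

    `del_genomic_pos` must be strictly inside a CDS exon piece (not its first
    or last base), so exon boundaries never coincide with the deleted base.
    Returns (mutant protein length, stop_found, first altered residue).
    """
    lo = model.locus_start
    seq = model.locus_seq
    g = del_genomic_pos
    mutated = seq[: g - lo] + seq[g - lo + 1 :]

    def adj(p):
        return p - 1 if p > g else p

    pieces = [
        mutated[adj(iv.start) - lo : adj(iv.end) - lo + 1] for iv in model.cds_intervals()
    ]
    mut_cds = "".join(pieces)
    ref_pieces = [seq[iv.start - lo : iv.end - lo + 1] for iv in model.cds_intervals()]
    ref_cds = "".join(ref_pieces)
    if model.strand == "-":
        mut_cds = str(Seq(mut_cds).reverse_complement())
        ref_cds = str(Seq(ref_cds).reverse_complement())

    ref_prot = str(Seq(ref_cds).translate())[:-1]
    mut_full = str(Seq(mut_cds[: len(mut_cds) - len(mut_cds) % 3]).translate())
    stop = mut_full.find("*")
    stop_found = stop >= 0
    mut_len = stop if stop_found else len(mut_full)
    mut_prot = mut_full[:mut_len]

    first_altered = None
    for i in range(min(len(ref_prot), mut_len)):
        if ref_prot[i] != mut_prot[i]:
            first_altered = i + 1
            break
    if first_altered is None and (mut_len != len(ref_prot) or not stop_found):
        first_altered = min(len(ref_prot), mut_len) + 1
    return mut_len, stop_found, first_altered
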