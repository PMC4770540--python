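"""Allele/carrier frequency estimates and Hardy-Weinberg expectations.

Used for validating a candidate allele in a survey cohort (carrier counts
-> allele frequency) and for the population-incidence argument: under
random mating a recessive allele at frequency q yields q^2 * n expected
affected individuals among n.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .core import round_half_up


@dataclass(frozen=True)
class GenotypeCounts:
    n_homref: int
    n_het: int
    n_homalt: int

    def __post_init__(self) -> None:
        if min(self.n_homref, self.n_het, self.n_homalt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt


class AlleleFrequency(NamedTuple):
    frequency: float  # alternate-allele frequency in [0, 1]
    percent: float  # same value in %, half-up rounded at one decimal


def allele_frequency(counts: GenotypeCounts) -> AlleleFrequency:
    """Alternate-allele frequency (2*hom-alt + het) / (2*total)."""
    if counts.total < 1:
        raise ValueError("at least one genotype required")
    q = (2 * counts.n_homalt + counts.n_het) / (2 * counts.total)
    return AlleleFrequency(frequency=q, percent=round_half_up(100 * q, 1))


def expected_affected(q: float, n: int) -> tuple[float, int]:
    """Expected number of affected homozygotes among `n` under HWE.

    Returns (q^2 * n, nearest integer with half-up ties).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    expectation = q * q * n
    return expectation, int(round_half_up(expectation, 0))


def hwe_expected_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Expected (hom-ref, het, hom-alt) counts under HWE at the observed allele frequency."""
    n = counts.total
    q = allele_frequency(counts).frequency
    p = 1.0 - q
    return (n * p * p, 2 * n * p * q, n * q * q)
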