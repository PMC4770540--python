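"""Shared primitives: genotype codes, genomic intervals, small variants, rounding."""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

# 4-state biallelic genotype alphabet used throughout the package.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT, MISSING)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round `x` at `decimals` with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; reported frequencies,
    interval lengths in Mb and truncation percentages use conventional
    half-up ties instead, so 1.135 -> 1.14 at two decimals.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def chrom_sort_key(chrom: str) -> tuple:
    """Deterministic chromosome ordering: 1..n numerically, then X, Y, MT, rest."""
    c = str(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 1, "Y": 2, "MT": 3}
    if c in special:
        return (1, special[c], "")
    return (2, 0, c)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic span (both endpoints included)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} exceeds end {self.end} on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end

    def covers(self, other: "GenomicInterval") -> bool:
        """True when `other` lies fully inside this interval."""
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class Variant:
    """A small sequence variant in VCF-style representation.

    `pos` is the 1-based coordinate of the first base of `ref`. Shared
    leading/trailing bases between `ref` and `alt` are permitted (the
    consequence annotator trims to the minimal edit itself).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if any(b not in "ACGTN" for b in allele.upper()):
                raise ValueError(f"non-nucleotide character in {name} allele {allele!r}")

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @classmethod
    def from_string(cls, spec: str) -> "Variant":
        """Parse a ``chrom:pos:ref:alt`` literal, e.g. ``13:24301425:GG:G``."""
        parts = spec.split(":")
        if len(parts) != 4:
            raise ValueError(f"expected chrom:pos:ref:alt, got {spec!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom=chrom, pos=int(pos), ref=ref.upper(), alt=alt.upper())

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
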