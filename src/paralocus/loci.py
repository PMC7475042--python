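"""Locus definitions and default genomic coordinates for the NOTCH2/NOTCH2NL family.

The NOTCH2NL genes (NOTCH2NLA, -B, -C at 1q21.1 and the pseudogene NOTCH2NLR at
1p12) arose from segmental duplications of the 5' part of NOTCH2. On a
reference genome in which the NOTCH2NL loci are masked, reads from every family
member pile up on the parent NOTCH2 locus, so all coordinates in this package
are expressed on the parent locus (hg38 chr1), 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

PARENT = "NOTCH2"
NL_LOCI = ("NOTCH2NLR", "NOTCH2NLC", "NOTCH2NLA", "NOTCH2NLB")
ALL_LOCI = (PARENT,) + NL_LOCI

#: loci with abundant SUNs whose allele counts come straight from mean SUN
#: frequency; NOTCH2NLA/B are resolved afterwards from the remainder.
CORE_LOCI = (PARENT, "NOTCH2NLR", "NOTCH2NLC")
AB_PAIR = ("NOTCH2NLA", "NOTCH2NLB")

CHROM = "chr1"
#: NOTCH2-only (single-copy) region used as the two-allele depth baseline.
SINGLE_COPY_REGION = (119_908_310, 119_989_035)
#: region shared by NOTCH2 and all NOTCH2NL duplicons (depth ~ total alleles).
MULTICOPY_REGION = (119_990_490, 120_087_745)
#: maximal duplicon interval within which SUNs are considered. The region end
#: defaults to the multicopy-region end; both bounds are configurable.
SUN_REGION = (119_990_474, 120_087_745)


@dataclass(frozen=True)
class LocusDefinition:
    """One locus of a paralog set, in genomic coordinates (1-based inclusive)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_parent: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be '+' or '-'")


def validate_paralog_set(loci: Iterable[LocusDefinition]) -> None:
    loci = list(loci)
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise ValueError("locus names must be unique within a paralog set")
    if sum(l.is_parent for l in loci) != 1:
        raise ValueError("exactly one locus must be the parent")


def default_paralog_set() -> list[LocusDefinition]:
    """The five-member NOTCH2 family with hg38 gene spans (approximate gene
    bodies; only names, strands and the parent flag matter downstream)."""
    return [
        LocusDefinition(PARENT, CHROM, 119_911_553, 120_069_662, "-", is_parent=True),
        LocusDefinition("NOTCH2NLR", CHROM, 120_705_669, 120_801_220, "+"),
        LocusDefinition("NOTCH2NLA", CHROM, 146_151_908, 146_229_032, "-"),
        LocusDefinition("NOTCH2NLB", CHROM, 148_602_849, 148_679_774, "-"),
        LocusDefinition("NOTCH2NLC", CHROM, 149_390_621, 149_471_833, "+"),
    ]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end
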