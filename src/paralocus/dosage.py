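"""Functional-variant allele dosage from pooled read fractions.

Because all NOTCH2NL paralogs are >99.9% identical, a variant's reads cannot
be assigned to a locus directly; instead the fraction of reads supporting the
variant allele, multiplied by the genome's total family allele count, counts
how many alleles carry it. This is how lineage-specific coding variants in
archaic genomes (e.g. the Neanderthal M40I seen in 17/242 reads of an
11-allele genome = one allele) and the Exon1 promoter-variant classes are
quantified. For exome cohorts mapped to the unmasked reference, the same
logic uses the read depth at the paralogous position where the variant allele
is annotated, divided by the summed depth over all paralogous positions
(multimapping reads included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._util import round_half_away
from .genotyper import PileupSite

EXON1A = "Exon1A-(Low)"
EXON1B = "Exon1B-(High)"
EXON1C = "Exon1C-(X-low)"
EXON2_SPLICE = "Exon2B-(Splice-mut)"
N232S = "Nea-N232S"


@dataclass(frozen=True)
class VariantDosage:
    name: str
    frequency: float
    allele_count: int
    reads_supporting: int
    reads_total: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if self.allele_count < 0:
            raise ValueError("allele_count must be non-negative")


def allele_count_from_reads(
    ad: int, dp: int, total_alleles: int, name: str = "variant"
) -> VariantDosage:
    """Allele count = round(supporting-read fraction x total alleles).

    Rounds half away from zero. Example: 17 of 242 reads in an 11-allele
    genome -> 0.77 alleles -> 1 allele.
    """
    if dp <= 0:
        raise ValueError("no coverage")
    if not 0 <= ad <= dp:
        raise ValueError("require 0 <= ad <= dp")
    if total_alleles < 1:
        raise ValueError("total_alleles must be >= 1")
    freq = ad / dp
    return VariantDosage(name, freq, round_half_away(freq * total_alleles), ad, dp)


@dataclass(frozen=True)
class PositionMember:
    """One locus's copy of a paralogous position on the unmasked reference."""

    locus: str
    chrom: str
    start: int  # 1-based inclusive, as printed
    end: int
    orientation: str  # + | -
    ref_seq: str


@dataclass(frozen=True)
class ParalogousPositionGroup:
    """The same ancestral position in every family member, for exome cohorts
    where reads are spread over all loci rather than pooled on the parent."""

    name: str
    members: tuple[PositionMember, ...]
    variant_locus: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a paralogous group needs >= 2 members")
        if sum(m.locus == self.variant_locus for m in self.members) != 1:
            raise ValueError("exactly one member must be the variant locus")

    def member(self, locus: str) -> PositionMember:
        for m in self.members:
            if m.locus == locus:
                return m
        raise KeyError(locus)


def paralog_group_frequency(
    depths: Mapping[str, float], group: ParalogousPositionGroup
) -> float | None:
    """Variant-locus read depth over the summed depth of all members.

    Valid only where the variant allele is annotated on the reference at one
    locus, so variant-carrying reads preferentially map there. Returns None
    (missing) when no member has coverage.
    """
    if any(d < 0 for d in depths.values()):
        raise ValueError("depths must be non-negative")
    total = sum(depths.get(m.locus, 0.0) for m in group.members)
    if total == 0:
        return None
    return depths.get(group.variant_locus, 0.0) / total


def exon1_variant_counts(
    pileups: Mapping[str, PileupSite],
    total_alleles_int: int,
    ab_pair_total: int,
) -> dict[str, int]:
    """Allele counts of the three Exon1 classes for one individual.

    The A-type (ATG>ATA start-codon loss) and C-type (2-bp deletion) counts
    come from their variant-read fractions times the total allele count; the
    B-type (full-length, high output) count is inferred as the A/B pair total
    minus the A-type count, clamped at zero, because no direct B marker exists
    in the 5' region.
    """
    counts: dict[str, int] = {}
    for key, label in (("Exon1A", EXON1A), ("Exon1C", EXON1C)):
        site = pileups.get(key)
        if site is None:
            raise ValueError(f"missing pileup site for {label}")
        if site.dp <= 0:
            raise ValueError(f"no coverage at {label}")
        counts[label] = round_half_away(site.ad_alt / site.dp * total_alleles_int)
    counts[EXON1B] = max(ab_pair_total - counts[EXON1A], 0)
    return counts


def builtin_position_tables() -> dict[str, ParalogousPositionGroup]:
    """The paralogous-position tables used for exome-cohort frequencies.

    hg38 coordinates, orientations and reference bases for the Exon1 A-type
    variant (annotated on NOTCH2NLA), the Exon2 splice-site variant (annotated
    on NOTCH2NLB) and the Neanderthal N232S site. N232S is carried by no
    reference locus (all printed bases are ancestral); its ``variant_locus``
    is set to NOTCH2NLA for bookkeeping and group-frequency calls are only
    meaningful for the two reference-annotated variants.
    """
    exon1a = ParalogousPositionGroup(
        EXON1A,
        (
            PositionMember("NOTCH2", "chr1", 120_069_403, 120_069_404, "-", "ATG"),
            PositionMember("NOTCH2NLR", "chr1", 120_724_179, 120_724_180, "+", "ATG"),
            PositionMember("NOTCH2NLA", "chr1", 146_228_778, 146_228_779, "-", "ATA"),
            PositionMember("NOTCH2NLB", "chr1", 148_679_531, 148_679_532, "-", "ATG"),
            PositionMember("NOTCH2NLC", "chr1", 149_390_853, 149_390_854, "+", "ATG"),
        ),
        variant_locus="NOTCH2NLA",
    )
    exon2 = ParalogousPositionGroup(
        EXON2_SPLICE,
        (
            PositionMember("NOTCH2", "chr1", 120_029_988, 120_029_989, "-", "T"),
            PositionMember("NOTCH2NLR", "chr1", 120_763_625, 120_763_626, "+", "A"),
            PositionMember("NOTCH2NLA", "chr1", 146_189_382, 146_189_383, "-", "T"),
            PositionMember("NOTCH2NLB", "chr1", 148_640_098, 148_640_099, "-", "C"),
            PositionMember("NOTCH2NLC", "chr1", 149_430_931, 149_430_932, "+", "A"),
        ),
        variant_locus="NOTCH2NLB",
    )
    n232s = ParalogousPositionGroup(
        N232S,
        (
            PositionMember("NOTCH2", "chr1", 119_997_052, 119_997_053, "-", "T"),
            PositionMember("NOTCH2NLR", "chr1", 120_793_439, 120_793_440, "+", "A"),
            PositionMember("NOTCH2NLA", "chr1", 146_156_535, 146_156_536, "-", "T"),
            PositionMember("NOTCH2NLB", "chr1", 148_607_465, 148_607_466, "-", "T"),
            PositionMember("NOTCH2NLC", "chr1", 149_463_769, 149_463_770, "+", "A"),
        ),
        variant_locus="NOTCH2NLA",
    )
    return {g.name: g for g in (exon1a, exon2, n232s)}


def position_tables_to_bed(groups: Mapping[str, ParalogousPositionGroup]) -> str:
    """Export the position tables as BED (0-based half-open)."""
    lines = []
    for g in groups.values():
        for m in g.members:
            lines.append(
                f"{m.chrom}\t{m.start - 1}\t{m.end}\t"
                f"{g.name}|{m.locus}|{m.ref_seq}\t0\t{m.orientation}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
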