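"""Derivation and management of singly unique nucleotides (SUNs).

A SUN is a variant carried by exactly one member of a paralog family; in a
pooled pileup over the parent locus its allele frequency is proportional to the
number of alleles of that one paralog, which is what makes per-paralog
copy-number separation possible. SUNs are found by aligning each duplicate
locus to the parent and keeping the columns where a single paralog differs
from the parent and from every other paralog.

Coordinates of all records are 1-based positions on the parent locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .loci import SUN_REGION, CHROM, LocusDefinition

logger = logging.getLogger(__name__)

_KINDS = ("SNV", "insertion", "deletion")
_GAP = "-"


@dataclass(frozen=True, order=True)
class SunRecord:
    """One paralog-identifying variant, projected onto parent coordinates.

    ``sun_base`` is the allele unique to ``paralog``; ``parent_base`` is the
    allele every other family member carries at that column. For a parent
    (NOTCH2) marker — a column where all duplicates share one derived allele —
    ``sun_base`` is the parent's own base, which on a masked reference is the
    REF allele of the pileup. Indels use ``-`` for the absent side: a deletion
    is anchored at the first deleted parent base, an insertion at the parent
    base preceding it, both left-aligned.
    """

    position: int
    paralog: str
    parent_base: str
    sun_base: str
    kind: str = "SNV"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown SUN kind {self.kind!r}")
        if self.parent_base == self.sun_base:
            raise ValueError("parent_base and sun_base must differ")
        if self.position < 1:
            raise ValueError("position must be 1-based positive")


@dataclass(frozen=True)
class SunCatalog:
    records: tuple[SunRecord, ...]
    paralog_set: tuple[LocusDefinition, ...] = ()
    sun_region: tuple[int, int] = SUN_REGION
    chrom: str = CHROM

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(sorted(self.records)))
        seen: dict[tuple[int, str], str] = {}
        for r in self.records:
            key = (r.position, r.sun_base)
            if key in seen and seen[key] != r.paralog:
                raise ValueError(f"(position, sun_base) {key} claimed by two paralogs")
            seen[key] = r.paralog

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_paralog(self, name: str) -> tuple[SunRecord, ...]:
        return tuple(r for r in self.records if r.paralog == name)

    @property
    def paralogs(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(r.paralog for r in self.records))


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def _left_align(seq: str, start: int, allele: str) -> tuple[int, str]:
    """Left-normalize an indel: rotate it leftwards over ``seq`` (0-based
    ``start``) while the base preceding it equals its last base."""
    while start > 0 and allele and seq[start - 1] == allele[-1]:
        allele = seq[start - 1] + allele[:-1]
        start -= 1
    return start, allele


def _pairwise_variants(parent: str, paralog: str, name: str, anchor: int) -> dict:
    """Align one paralog to the parent and list its differences.

    Returns {(position, sun_allele, kind): parent_allele}. Raises if the pair
    aligns at <80% identity, which signals a mis-specified input rather than a
    diverged duplicate.
    """
    aln = _aligner().align(parent, paralog)[0]
    gapped_parent, gapped_paralog = str(aln[0]), str(aln[1])
    ncols = len(gapped_parent)
    matches = sum(a == b for a, b in zip(gapped_parent, gapped_paralog))
    if ncols and matches / ncols < 0.80:
        raise ValueError(f"paralog {name!r} aligns at <80% identity to the parent")

    variants: dict[tuple[int, str, str], str] = {}
    ppos = 0  # 0-based parent offset of the current column
    i = 0
    while i < ncols:
        pb, qb = gapped_parent[i], gapped_paralog[i]
        if pb != _GAP and qb != _GAP:
            if pb != qb:
                variants[(anchor + ppos, qb, "SNV")] = pb
            ppos += 1
            i += 1
        elif qb == _GAP:  # deletion in paralog
            j = i
            while j < ncols and gapped_paralog[j] == _GAP and gapped_parent[j] != _GAP:
                j += 1
            deleted = gapped_parent[i:j]
            start0, deleted = _left_align(parent, ppos, deleted)
            variants[(anchor + start0, _GAP, "deletion")] = deleted
            ppos += j - i
            i = j
        else:  # insertion in paralog
            j = i
            while j < ncols and gapped_parent[j] == _GAP and gapped_paralog[j] != _GAP:
                j += 1
            inserted = gapped_paralog[i:j]
            start0, inserted = _left_align(parent, ppos, inserted)
            # anchored at the preceding parent base
            variants[(anchor + max(start0 - 1, 0), inserted, "insertion")] = _GAP
            i = j
    return variants


def derive_suns(
    parent_sequence: str,
    paralog_sequences: Mapping[str, str],
    *,
    anchor: int = 1,
    parent_name: str = "NOTCH2",
    include_parent: bool = False,
    sun_region: tuple[int, int] | None = None,
    paralog_set: Sequence[LocusDefinition] = (),
    chrom: str = CHROM,
) -> SunCatalog:
    """Find SUNs by pairwise global alignment of each paralog to the parent.

    A variant allele at a parent position is a SUN when exactly one paralog
    carries it; alleles shared by two or more paralogs are ambiguous markers
    and dropped. Uniqueness is decided per (position, allele), so two distinct
    alternates at one column can each be a SUN of its own paralog.

    With ``include_parent=True``, a column where *every* paralog carries the
    same alternate yields a marker for the parent itself (the parent's base is
    then the singly unique allele), which the genotyper needs to estimate the
    parent's allele count from pooled pileups.
    """
    if not parent_sequence or not paralog_sequences:
        raise ValueError("no sequences")
    for name, seq in paralog_sequences.items():
        if not seq:
            raise ValueError("no sequences")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"paralog {name!r}: non-ACGTN characters {sorted(bad)}")

    per_paralog = {
        name: _pairwise_variants(parent_sequence.upper(), seq.upper(), name, anchor)
        for name, seq in paralog_sequences.items()
    }
    carriers: dict[tuple[int, str, str], list[str]] = {}
    parent_alleles: dict[tuple[int, str, str], str] = {}
    for name, variants in per_paralog.items():
        for key, pallele in variants.items():
            carriers.setdefault(key, []).append(name)
            parent_alleles[key] = pallele

    records: list[SunRecord] = []
    for (pos, allele, kind), names in carriers.items():
        pallele = parent_alleles[(pos, allele, kind)]
        if len(names) == 1:
            records.append(SunRecord(pos, names[0], pallele, allele, kind))
        elif len(names) >= 2:
            if include_parent and len(names) == len(paralog_sequences) and kind == "SNV":
                # all duplicates share this alternate: the parent base is unique
                records.append(SunRecord(pos, parent_name, allele, pallele, "SNV"))
            else:
                logger.debug("dropping shared variant at %d (%s) carried by %s", pos, allele, names)

    region = sun_region if sun_region is not None else (anchor, anchor + len(parent_sequence) - 1)
    return SunCatalog(tuple(records), tuple(paralog_set), region, chrom)


def filter_suns_by_region(catalog: SunCatalog, region: tuple[int, int]) -> SunCatalog:
    """Keep only records with region.start <= position <= region.end."""
    start, end = region
    if start > end:
        raise ValueError(f"inverted region {start}-{end}")
    kept = tuple(r for r in catalog.records if start <= r.position <= end)
    return SunCatalog(kept, catalog.paralog_set, (start, end), catalog.chrom)


def write_sun_bed(catalog: SunCatalog) -> str:
    """Serialize a catalog as BED (0-based half-open).

    The name column packs ``paralog|parent_base|sun_base|kind`` so the record
    round-trips exactly. A deletion's interval spans the deleted parent bases.
    """
    lines = []
    for r in catalog.records:
        span = len(r.parent_base) if r.kind == "deletion" else 1
        lines.append(
            f"{catalog.chrom}\t{r.position - 1}\t{r.position - 1 + span}\t"
            f"{r.paralog}|{r.parent_base}|{r.sun_base}|{r.kind}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_sun_bed(
    text: str,
    paralog_set: Sequence[LocusDefinition] = (),
    sun_region: tuple[int, int] = SUN_REGION,
) -> SunCatalog:
    records = []
    chrom = CHROM
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"SUN BED line {lineno}: expected >=4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start = int(fields[1])
            name_parts = fields[3].split("|")
            paralog, parent_base, sun_base, kind = name_parts
        except (ValueError, IndexError) as exc:
            raise ValueError(f"SUN BED line {lineno}: malformed record") from exc
        records.append(SunRecord(start + 1, paralog, parent_base, sun_base, kind))
    return SunCatalog(tuple(records), tuple(paralog_set), sun_region, chrom)
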