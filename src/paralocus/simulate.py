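"""Ground-truthed synthetic individuals and cohorts.

The generator emulates what the pipeline actually consumes after mapping to a
NOTCH2NL-masked reference: a per-position depth track over the single-copy and
multicopy regions, and a pileup table (DP / allele depths) at SUN and variant
positions. Depth at a position is Poisson with mean ``base_depth x local
allele count / 2`` (the single-copy region always carries two alleles); the
allele depth of a SUN or variant allele is Binomial(DP, carrying alleles /
local total). Interlocus gene-conversion tracts move SUN carriage between
paralogs without changing copy number, and point variants plant
lineage-specific alleles at configured allele counts.

Presets encode the genome configurations the analysis is built around: the
modal modern human (ten alleles, two per locus), an Altai-Neanderthal-like
genome (eleven alleles with an extra NOTCH2NLA/B allele, a NOTCH2->NOTCH2NLR
conversion tract, and the M40I / N232S variants), and a Denisova3-like genome
(NOTCH2NLR homozygously deleted, six NOTCH2NL alleles all carrying the
Exon1 C-type variant, plus E258A).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .genotyper import PileupSite
from .loci import (
    AB_PAIR,
    ALL_LOCI,
    CHROM,
    MULTICOPY_REGION,
    NL_LOCI,
    PARENT,
    SINGLE_COPY_REGION,
    SUN_REGION,
)
from .sun_catalog import SunCatalog, SunRecord

PRESET_NAMES = ("modern_human_standard", "neanderthal_altai_like", "denisova3_like")

# fixed synthetic positions (parent-locus coordinates) for the point variants;
# the Exon1A and N232S anchors reuse the printed NOTCH2 paralogous positions,
# the others are synthetic positions inside the multicopy region.
VARIANT_POSITIONS = {
    "Exon1A": 120_069_404,
    "Exon1C": 120_069_410,
    "Exon2_splice": 120_029_989,
    "M40I": 120_069_380,
    "N232S": 119_997_053,
    "E258A": 120_030_500,
}


@dataclass(frozen=True)
class ConversionTract:
    """Non-reciprocal transfer of ``donor`` sequence onto ``n_alleles`` of the
    ``acceptor`` locus over [start, end] (parent coordinates)."""

    donor: str
    acceptor: str
    start: int
    end: int
    n_alleles: int

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PointVariant:
    """A lineage-specific allele carried by ``n_alleles`` drawn from the
    ``carriers`` loci pool."""

    name: str
    position: int
    carriers: tuple[str, ...]
    n_alleles: int
    ref_base: str = "A"
    alt_base: str = "G"


@dataclass(frozen=True)
class GenomeConfig:
    """Ground truth for one simulated individual."""

    locus_alleles: Mapping[str, int]
    conversion_tracts: tuple[ConversionTract, ...] = ()
    point_variants: tuple[PointVariant, ...] = ()
    base_depth: float = 30.0
    seed: int = 0
    single_copy_region: tuple[int, int] = SINGLE_COPY_REGION
    multicopy_region: tuple[int, int] = MULTICOPY_REGION
    #: per-locus duplicon extent inside the multicopy region; loci absent from
    #: the mapping span the whole region (NOTCH2NLB is the largest duplicon).
    duplicon_extents: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, n in self.locus_alleles.items():
            if n < 0:
                raise ValueError(f"{locus}: negative allele count")
        mc_s, mc_e = self.multicopy_region
        for t in self.conversion_tracts:
            if not (mc_s <= t.start <= t.end <= mc_e):
                raise ValueError(f"tract {t.donor}>{t.acceptor} outside the multicopy region")
            if t.n_alleles > self.locus_alleles.get(t.acceptor, 0):
                raise ValueError(f"tract converts more {t.acceptor} alleles than exist")
        for v in self.point_variants:
            pool = sum(self.locus_alleles.get(l, 0) for l in v.carriers)
            if v.n_alleles > pool:
                raise ValueError(f"variant {v.name}: n_alleles exceeds its carrier pool")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")

    @property
    def total_alleles(self) -> int:
        return int(sum(self.locus_alleles.values()))

    @property
    def ab_pair_total(self) -> int:
        return int(sum(self.locus_alleles.get(l, 0) for l in AB_PAIR))

    def local_total(self, position: int) -> int:
        """Allele count contributing depth at a multicopy-region position."""
        total = self.locus_alleles.get(PARENT, 0)
        for locus in NL_LOCI:
            s, e = self.duplicon_extents.get(locus, self.multicopy_region)
            if s <= position <= e:
                total += self.locus_alleles.get(locus, 0)
        return total

    def sun_carriers(self, paralog: str, position: int) -> int:
        """Alleles carrying ``paralog``'s sequence at ``position`` after
        applying any conversion tract covering it."""
        carrying = self.locus_alleles.get(paralog, 0)
        for t in self.conversion_tracts:
            if t.covers(position):
                if t.acceptor == paralog:
                    carrying -= t.n_alleles
                if t.donor == paralog:
                    carrying += t.n_alleles
        return int(np.clip(carrying, 0, self.local_total(position)))


def preset(name: str, base_depth: float = 30.0, seed: int = 0) -> GenomeConfig:
    """A named study-condition genome configuration."""
    if name == "modern_human_standard":
        alleles = {PARENT: 2, "NOTCH2NLR": 2, "NOTCH2NLC": 2, "NOTCH2NLA": 2, "NOTCH2NLB": 2}
        variants = (
            PointVariant("Exon1A", VARIANT_POSITIONS["Exon1A"], ("NOTCH2NLA",), 2),
            PointVariant("Exon1C", VARIANT_POSITIONS["Exon1C"], ("NOTCH2NLC",), 2),
        )
        tracts: tuple[ConversionTract, ...] = ()
    elif name == "neanderthal_altai_like":
        # 2 NOTCH2 + 9 NOTCH2NL: the extra A/B-pair allele is placed on
        # NOTCH2NLA (the data cannot resolve A vs B for the gain).
        alleles = {PARENT: 2, "NOTCH2NLR": 2, "NOTCH2NLC": 2, "NOTCH2NLA": 3, "NOTCH2NLB": 2}
        variants = (
            PointVariant("Exon1A", VARIANT_POSITIONS["Exon1A"], ("NOTCH2NLA",), 2),
            PointVariant("Exon1C", VARIANT_POSITIONS["Exon1C"], ("NOTCH2NLC",), 2),
            PointVariant("M40I", VARIANT_POSITIONS["M40I"], ("NOTCH2NLA", "NOTCH2NLB"), 1),
            PointVariant("N232S", VARIANT_POSITIONS["N232S"], ("NOTCH2NLA", "NOTCH2NLB"), 2),
        )
        tracts = (
            ConversionTract(PARENT, "NOTCH2NLR", MULTICOPY_REGION[0] + 10,
                            MULTICOPY_REGION[1] - 1_745, 1),
        )
    elif name == "denisova3_like":
        alleles = {PARENT: 2, "NOTCH2NLR": 0, "NOTCH2NLC": 2, "NOTCH2NLA": 2, "NOTCH2NLB": 2}
        variants = (
            PointVariant("Exon1C", VARIANT_POSITIONS["Exon1C"],
                         ("NOTCH2NLC", "NOTCH2NLA", "NOTCH2NLB"), 6),
            PointVariant("E258A", VARIANT_POSITIONS["E258A"], ("NOTCH2NLA", "NOTCH2NLB"), 2),
        )
        tracts = ()
    else:
        raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
    return GenomeConfig(alleles, tracts, variants, base_depth=base_depth, seed=seed)


def synthetic_sun_catalog(
    n_per_locus: Mapping[str, int] | None = None,
    sun_region: tuple[int, int] | None = None,
    seed: int = 0,
) -> SunCatalog:
    """Plant SUN positions for each family member inside the SUN region.

    Defaults mirror the family's marker structure: many SUNs for NOTCH2,
    NOTCH2NLR and NOTCH2NLC; few for NOTCH2NLA and NOTCH2NLB, with the
    NOTCH2NLB SUNs confined to the 3' half of the region so the 5' half has
    A-markers only (the situation the complement-track inference exists for).
    NOTCH2 markers carry the reference base as their unique allele.
    """
    if sun_region is None:
        # clip the configured SUN region to the simulated multicopy region
        sun_region = (max(SUN_REGION[0], MULTICOPY_REGION[0]),
                      min(SUN_REGION[1], MULTICOPY_REGION[1]))
    if n_per_locus is None:
        n_per_locus = {PARENT: 30, "NOTCH2NLR": 30, "NOTCH2NLC": 30,
                       "NOTCH2NLA": 8, "NOTCH2NLB": 8}
    rng = np.random.default_rng(seed)
    start, end = sun_region
    mid = (start + end) // 2
    pool = rng.permutation(np.arange(start, end + 1))
    cursor = 0
    records: list[SunRecord] = []
    for locus, n in n_per_locus.items():
        taken = 0
        while taken < n:
            pos = int(pool[cursor]); cursor += 1
            if locus == "NOTCH2NLB" and pos <= mid:
                continue
            if locus == PARENT:
                # parent marker: unique allele is the reference base
                records.append(SunRecord(pos, locus, parent_base="G", sun_base="A"))
            else:
                records.append(SunRecord(pos, locus, parent_base="A", sun_base="G"))
            taken += 1
    return SunCatalog(tuple(records), sun_region=sun_region)


def simulate_depth(config: GenomeConfig, rng: np.random.Generator | None = None) -> DepthTrack:
    """Poisson depth over the span covering both analysis regions.

    Position rate = base_depth x local allele count / 2: the single-copy
    region always represents two alleles, the multicopy region the sum over
    duplicons spanning the position. Positions outside either region (the gap
    between them) are simulated at the two-allele rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sc_s, sc_e = config.single_copy_region
    mc_s, mc_e = config.multicopy_region
    start = min(sc_s, mc_s)
    end = max(sc_e, mc_e)
    positions = np.arange(start, end + 1)
    rates = np.full(positions.size, config.base_depth, dtype=float)

    in_mc = (positions >= mc_s) & (positions <= mc_e)
    if config.duplicon_extents:
        local = np.full(positions.size, config.locus_alleles.get(PARENT, 0), dtype=float)
        for locus in NL_LOCI:
            s, e = config.duplicon_extents.get(locus, config.multicopy_region)
            span = (positions >= s) & (positions <= e)
            local[span] += config.locus_alleles.get(locus, 0)
        rates[in_mc] = config.base_depth * local[in_mc] / 2.0
    else:
        rates[in_mc] = config.base_depth * config.total_alleles / 2.0
    depths = rng.poisson(rates)
    return DepthTrack(CHROM, start, depths)


def simulate_pileups(
    config: GenomeConfig,
    catalog: SunCatalog,
    rng: np.random.Generator | None = None,
) -> list[PileupSite]:
    """Pileup rows at every SUN position and every configured point variant.

    DP ~ Poisson(base_depth x local total / 2); the depth of a record's unique
    allele ~ Binomial(DP, carrying / local total), written to the REF or ALT
    allele-depth column depending on which side of the pileup carries it (the
    reference sequence is the parent's, so parent markers support REF).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mc_s, mc_e = config.multicopy_region
    sites: list[PileupSite] = []
    for rec in catalog.records:
        if not (mc_s <= rec.position <= mc_e):
            raise ValueError(f"SUN position {rec.position} outside the simulated region")
        total = config.local_total(rec.position)
        dp = int(rng.poisson(config.base_depth * total / 2.0))
        carrying = config.sun_carriers(rec.paralog, rec.position)
        ad_sun = int(rng.binomial(dp, carrying / total)) if total > 0 and dp > 0 else 0
        if rec.paralog == PARENT:
            # masked reference: the parent's unique base is the REF allele
            sites.append(PileupSite(CHROM, rec.position, rec.sun_base, rec.parent_base,
                                    dp, ad_sun, dp - ad_sun))
        else:
            sites.append(PileupSite(CHROM, rec.position, rec.parent_base, rec.sun_base,
                                    dp, dp - ad_sun, ad_sun))
    for var in config.point_variants:
        if not (mc_s <= var.position <= mc_e):
            raise ValueError(f"variant {var.name} position outside the simulated region")
        total = config.local_total(var.position)
        dp = int(rng.poisson(config.base_depth * total / 2.0))
        ad_alt = int(rng.binomial(dp, var.n_alleles / total)) if total > 0 and dp > 0 else 0
        sites.append(PileupSite(CHROM, var.position, var.ref_base, var.alt_base,
                                dp, dp - ad_alt, ad_alt))
    return sorted(sites, key=lambda s: s.position)


@dataclass
class SimulatedIndividual:
    sample_id: str
    truth: GenomeConfig
    depth_track: DepthTrack
    pileups: list[PileupSite]


def simulate_individual(
    config: GenomeConfig,
    catalog: SunCatalog,
    sample_id: str = "sim",
) -> SimulatedIndividual:
    """Depth track + pileup table for one genome, reproducible under its seed."""
    rng = np.random.default_rng(config.seed)
    track = simulate_depth(config, rng)
    pileups = simulate_pileups(config, catalog, rng)
    return SimulatedIndividual(sample_id, config, track, pileups)


def individual_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-individual seed below 2^31."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % (2**31))


@dataclass
class SimulatedCohort:
    individuals: list[SimulatedIndividual]
    catalog: SunCatalog
    truth_table: pd.DataFrame


def simulate_cohort(
    n: int,
    preset_name: str = "modern_human_standard",
    mixture: Mapping[str, float] | None = None,
    exon1a_frequency: float | None = None,
    base_depth: float = 30.0,
    seed: int = 0,
    catalog: SunCatalog | None = None,
) -> SimulatedCohort:
    """Simulate ``n`` independent individuals sharing one SUN catalog.

    ``mixture`` maps preset names to sampling probabilities (default: all
    individuals from ``preset_name``). ``exon1a_frequency`` optionally makes
    the Exon1 A-type variant segregate: each individual carries
    Binomial(A/B pair total, frequency) A-type alleles, with the B-type count
    implicitly the complement. The truth table records the configuration of
    every individual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if catalog is None:
        catalog = synthetic_sun_catalog(seed=seed)
    rng = np.random.default_rng(seed)
    if mixture:
        names = list(mixture)
        probs = np.asarray([mixture[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        chosen = rng.choice(names, size=n, p=probs)
    else:
        chosen = [preset_name] * n

    individuals: list[SimulatedIndividual] = []
    rows = []
    for i in range(n):
        cfg = preset(chosen[i], base_depth=base_depth, seed=individual_seed(seed, i))
        if exon1a_frequency is not None:
            k = int(rng.binomial(cfg.ab_pair_total, exon1a_frequency))
            variants = tuple(v for v in cfg.point_variants if v.name != "Exon1A")
            variants += (PointVariant("Exon1A", VARIANT_POSITIONS["Exon1A"], AB_PAIR, k),)
            cfg = replace(cfg, point_variants=variants)
        sample_id = f"S{i:04d}"
        individuals.append(simulate_individual(cfg, catalog, sample_id))
        row = {"sample": sample_id, "preset": chosen[i], "seed": cfg.seed,
               "total_alleles": cfg.total_alleles}
        row.update({locus: cfg.locus_alleles.get(locus, 0) for locus in ALL_LOCI})
        for v in cfg.point_variants:
            row[f"var_{v.name}"] = v.n_alleles
        rows.append(row)
    truth = pd.DataFrame(rows).fillna(0)
    return SimulatedCohort(individuals, catalog, truth)
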