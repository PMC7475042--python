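"""End-to-end orchestration: depth ratio -> SUN genotype -> dosage -> profile.

The stages mirror the analysis order: combined allele count from the
multicopy/single-copy depth ratio; per-paralog allele counts from SUN
frequencies (with the cohort population filter and the NOTCH2>NOTCH2NLR
conversion correction); point-variant dosages and Exon1-class counts; and the
per-SUN allele-count track with conversion-segment calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conversion import (
    ConversionSegment,
    SunTrack,
    call_conversion_segments,
    inferred_complement_track,
    per_sun_allele_track,
)
from .coverage import DepthTrack, RegionSet, TotalAlleleEstimate, mean_depth, total_allele_count
from .dosage import EXON1A, EXON1B, EXON1C, VariantDosage, allele_count_from_reads, exon1_variant_counts
from .genotyper import (
    AlleleCountEstimate,
    PileupSite,
    SunFrequencyTable,
    locus_allele_counts,
    n2_nlr_conversion_correction,
    population_filter,
    sun_frequencies,
)
from .loci import AB_PAIR, ALL_LOCI, MULTICOPY_REGION, SINGLE_COPY_REGION, SUN_REGION
from .sun_catalog import SunCatalog, SunRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters with the analysis defaults."""

    single_copy_region: tuple[int, int] = SINGLE_COPY_REGION
    multicopy_region: tuple[int, int] = MULTICOPY_REGION
    sun_region: tuple[int, int] = SUN_REGION
    repeat_intervals: tuple[tuple[int, int], ...] = ()
    sun_filter_threshold: float = 0.67
    sun_filter_statistic: str = "median"
    expected_sun_fraction: float = 0.2  # 2 carrying alleles / 10 total, modal
    segment_default_count: int = 2
    segment_min_run: int = 3
    #: variant name -> pileup position, for dosage extraction
    variant_sites: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sun_filter_threshold <= 1.0:
            raise ValueError("sun filter threshold must lie in (0, 1]")
        for name, (s, e) in (
            ("single_copy_region", self.single_copy_region),
            ("multicopy_region", self.multicopy_region),
            ("sun_region", self.sun_region),
        ):
            if s > e:
                raise ValueError(f"{name} is inverted")


@dataclass
class SampleReport:
    """Everything the pipeline computes for one individual."""

    sample: str
    total: TotalAlleleEstimate
    allele_counts: AlleleCountEstimate
    dosages: dict[str, VariantDosage]
    exon1_counts: dict[str, int]
    track: SunTrack
    segments: list[ConversionSegment]

    def to_row(self) -> dict:
        row = {
            "sample": self.sample,
            "ratio": self.total.ratio,
            "total_real": self.total.total_alleles_real,
            "total_int": self.total.total_alleles_int,
        }
        row.update(self.allele_counts.counts)
        row["flags"] = ";".join(self.allele_counts.flags)
        for name, d in self.dosages.items():
            row[f"var_{name}"] = d.allele_count
        for name, c in self.exon1_counts.items():
            row[name] = c
        return row


def estimate_total(track: DepthTrack, config: PipelineConfig) -> TotalAlleleEstimate:
    """Combined allele count from the repeat-masked depth ratio."""
    single = RegionSet([config.single_copy_region], list(config.repeat_intervals))
    multi = RegionSet([config.multicopy_region], list(config.repeat_intervals))
    return total_allele_count(mean_depth(track, multi), mean_depth(track, single))


def analyze_sample(
    sample: str,
    track: DepthTrack,
    pileups: Sequence[PileupSite],
    catalog: SunCatalog,
    config: PipelineConfig,
    retained: Sequence[SunRecord] | None = None,
    freqs: SunFrequencyTable | None = None,
) -> SampleReport:
    """Run every per-sample stage; ``retained`` carries the cohort-level SUN
    filter decision (all catalog records when absent)."""
    total = estimate_total(track, config)
    if freqs is None:
        freqs = sun_frequencies(pileups, catalog, sample)
    if retained is None:
        retained = list(catalog.records)

    est = locus_allele_counts(freqs, retained, total.total_alleles_int)
    est = n2_nlr_conversion_correction(est)

    by_pos = {s.position: s for s in pileups}
    dosages: dict[str, VariantDosage] = {}
    for name, position in config.variant_sites.items():
        site = by_pos.get(position)
        if site is None or site.dp == 0:
            # absent from this dataset (or zero coverage): simply not reported
            logger.debug("%s: no usable pileup for variant %s", sample, name)
            continue
        dosages[name] = allele_count_from_reads(
            site.ad_alt, site.dp, total.total_alleles_int, name
        )

    exon1: dict[str, int] = {}
    ex_sites = {
        key: by_pos.get(config.variant_sites[key])
        for key in ("Exon1A", "Exon1C")
        if key in config.variant_sites
    }
    if len(ex_sites) == 2 and all(s is not None for s in ex_sites.values()):
        ab_total = sum(est.counts.get(l, 0) for l in AB_PAIR)
        exon1 = exon1_variant_counts(ex_sites, total.total_alleles_int, ab_total)

    sun_track = per_sun_allele_track(freqs.restrict(retained), total.total_alleles_int)
    segments = call_conversion_segments(
        sun_track, config.segment_default_count, config.segment_min_run
    )
    return SampleReport(sample, total, est, dosages, exon1, sun_track, segments)


def process_cohort(
    samples: Sequence[tuple[str, DepthTrack, Sequence[PileupSite]]],
    catalog: SunCatalog,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list[SampleReport]]:
    """Cohort-level run: the population SUN filter is computed across all
    samples, then every sample is analyzed against the retained SUN set."""
    freq_tables = {
        sample: sun_frequencies(pileups, catalog, sample)
        for sample, _, pileups in samples
    }
    cohort = SunFrequencyTable.concat(list(freq_tables.values()))
    retained = population_filter(
        cohort,
        catalog,
        expected_fraction=config.expected_sun_fraction,
        threshold=config.sun_filter_threshold,
        statistic=config.sun_filter_statistic,
    )
    reports = [
        analyze_sample(sample, track, pileups, catalog, config,
                       retained=retained, freqs=freq_tables[sample])
        for sample, track, pileups in samples
    ]
    table = pd.DataFrame([r.to_row() for r in reports])
    return table, reports
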