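"""Per-paralog allele counts from SUN pileup frequencies.

At a SUN position the fraction of reads carrying the paralog's unique allele
estimates (alleles of that paralog) / (total family alleles). The genotyper

1. computes per-SUN frequencies from allele depth (AD) and total depth (DP),
2. drops SUNs whose cohort-normalized frequency is not clearly present in the
   population (ambiguous or polymorphic markers),
3. converts mean per-locus frequency x total allele count into integer counts
   for NOTCH2, NOTCH2NLR and NOTCH2NLC (many SUNs each, so the mean is
   stable), and
4. assigns the remaining alleles to the NOTCH2NLA/NOTCH2NLB pair by the ratio
   of their mean SUN frequencies, because those two loci have few SUNs and
   convert into each other frequently.

A final correction handles NOTCH2 > NOTCH2NLR interlocus gene conversion,
which makes a genome look like 3 x NOTCH2 / 1 x NOTCH2NLR when it physically
carries two of each.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import largest_remainder_split, round_half_away
from .loci import AB_PAIR, CORE_LOCI, PARENT
from .sun_catalog import SunCatalog, SunRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PileupSite:
    """One position's pooled read support for one individual."""

    chrom: str
    position: int
    ref_base: str
    alt_base: str
    dp: int
    ad_ref: int
    ad_alt: int

    def __post_init__(self) -> None:
        if min(self.dp, self.ad_ref, self.ad_alt) < 0:
            raise ValueError("depths must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("ad_ref + ad_alt exceeds dp")


class SunFrequencyTable:
    """Observed SUN allele frequencies, per sample and per SUN record.

    Backed by a DataFrame with one row per (sample, SUN) and columns
    ``sample, position, paralog, sun_base, frequency``; ``frequency`` is NaN
    where the site had zero depth (missing, not zero).
    """

    COLUMNS = ["sample", "position", "paralog", "sun_base", "frequency"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"frequency table missing columns {sorted(missing)}")
        ok = df["frequency"].isna() | df["frequency"].between(0.0, 1.0)
        if not ok.all():
            raise ValueError("frequencies must lie in [0, 1]")
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample"]))

    def for_sample(self, sample: str) -> "SunFrequencyTable":
        return SunFrequencyTable(self.df[self.df["sample"] == sample])

    def restrict(self, retained: Iterable[SunRecord]) -> "SunFrequencyTable":
        keys = {(r.position, r.sun_base) for r in retained}
        mask = [
            (p, b) in keys
            for p, b in zip(self.df["position"], self.df["sun_base"])
        ]
        return SunFrequencyTable(self.df[mask])

    def mean_locus_frequency(self, paralog: str) -> float:
        vals = self.df.loc[self.df["paralog"] == paralog, "frequency"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    @staticmethod
    def concat(tables: Sequence["SunFrequencyTable"]) -> "SunFrequencyTable":
        return SunFrequencyTable(pd.concat([t.df for t in tables], ignore_index=True))


def sun_frequencies(
    pileups: Iterable[PileupSite],
    catalog: SunCatalog,
    sample: str = "sample",
) -> SunFrequencyTable:
    """Per-SUN allele frequency AD/DP for one individual.

    Each catalog record is matched to the pileup row at its position and its
    frequency is read from whichever allele column carries the record's unique
    base: AD_alt/DP for ordinary paralog SUNs, AD_ref/DP for parent markers
    (the parent's base *is* the reference on a masked genome). Rows whose
    alleles match no record are skipped with a warning; zero-depth sites are
    recorded as missing.
    """
    by_pos: dict[int, PileupSite] = {}
    for site in pileups:
        by_pos[site.position] = site

    rows = []
    catalog_positions = {r.position for r in catalog.records}
    for site in by_pos.values():
        if site.position in catalog_positions:
            alleles = {site.ref_base, site.alt_base}
            if not any(
                r.sun_base in alleles
                for r in catalog.records
                if r.position == site.position
            ):
                logger.warning(
                    "pileup at %d (%s>%s) matches no catalog allele; skipped",
                    site.position, site.ref_base, site.alt_base,
                )
    for rec in catalog.records:
        site = by_pos.get(rec.position)
        if site is None:
            continue
        if rec.sun_base == site.alt_base:
            supporting = site.ad_alt
        elif rec.sun_base == site.ref_base:
            supporting = site.ad_ref
        else:
            continue
        freq = supporting / site.dp if site.dp > 0 else float("nan")
        rows.append((sample, rec.position, rec.paralog, rec.sun_base, freq))
    return SunFrequencyTable(pd.DataFrame(rows, columns=SunFrequencyTable.COLUMNS))


def population_filter(
    cohort_freqs: SunFrequencyTable,
    catalog: SunCatalog,
    *,
    expected_fraction: float | Mapping[str, float] = 0.2,
    threshold: float = 0.67,
    statistic: str = "median",
) -> list[SunRecord]:
    """Retain SUNs that look genuinely fixed on their paralog across a cohort.

    A SUN of a two-allele paralog in a ten-allele genome is expected at
    frequency 2/10; a marker whose cohort median observed/expected ratio is
    not strictly above ``threshold`` (default 0.67) is treated as ambiguous or
    population-polymorphic (e.g. a common SNP) and dropped. ``expected_fraction``
    may be a scalar or a per-paralog mapping. A single-sample cohort cannot
    support the filter, so it passes everything with a warning.
    """
    if statistic not in {"median", "mean"}:
        raise ValueError("statistic must be 'median' or 'mean'")
    samples = cohort_freqs.samples
    if len(samples) < 2:
        logger.warning("population filter needs >=2 samples; retaining all SUNs")
        return list(catalog.records)

    agg = np.median if statistic == "median" else np.mean
    retained = []
    grouped = cohort_freqs.df.groupby(["position", "sun_base"])["frequency"]
    stats = {key: float(agg(vals.dropna())) if vals.notna().any() else float("nan")
             for key, vals in grouped}
    for rec in catalog.records:
        exp = (
            expected_fraction.get(rec.paralog, 0.2)
            if isinstance(expected_fraction, Mapping)
            else expected_fraction
        )
        obs = stats.get((rec.position, rec.sun_base))
        if obs is None or math.isnan(obs) or exp <= 0:
            continue
        if obs / exp > threshold:
            retained.append(rec)
    logger.info("population filter retained %d/%d SUNs", len(retained), len(catalog))
    return retained


@dataclass(frozen=True)
class AlleleCountEstimate:
    """Integer allele counts per locus for one individual."""

    counts: dict[str, int]
    total_int: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("allele counts must be non-negative")
        if sum(self.counts.values()) != self.total_int:
            raise ValueError("per-locus counts must sum to the total")


def locus_allele_counts(
    freqs: SunFrequencyTable,
    retained: Iterable[SunRecord],
    total_alleles_int: int,
) -> AlleleCountEstimate:
    """Turn one sample's SUN frequencies into per-locus allele counts.

    NOTCH2 / NOTCH2NLR / NOTCH2NLC counts are ``round(mean frequency x
    total)``; what remains of the total goes to the NOTCH2NLA/B pair, split by
    the ratio of their mean SUN frequencies with largest-remainder rounding so
    the counts conserve the total exactly. A negative remainder (noisy data)
    is clamped to zero and flagged.
    """
    if total_alleles_int < 2:
        raise ValueError("total_alleles_int must be >= 2")
    retained = list(retained)
    table = freqs.restrict(retained)

    flags: list[str] = []
    counts: dict[str, int] = {}
    for locus in CORE_LOCI:
        if not any(r.paralog == locus for r in retained):
            raise ValueError(f"no retained SUNs for required locus {locus}")
        mean_f = table.mean_locus_frequency(locus)
        if math.isnan(mean_f):
            raise ValueError(f"no retained SUNs for required locus {locus}")
        counts[locus] = max(round_half_away(mean_f * total_alleles_int), 0)

    remaining = total_alleles_int - sum(counts.values())
    if remaining < 0:
        flags.append("negative A/B remainder clamped to 0")
        remaining = 0

    mean_ab = []
    for locus in AB_PAIR:
        f = table.mean_locus_frequency(locus)
        mean_ab.append(0.0 if math.isnan(f) else max(f, 0.0))
    a, b = largest_remainder_split(remaining, mean_ab)
    counts[AB_PAIR[0]], counts[AB_PAIR[1]] = a, b

    return AlleleCountEstimate(counts, sum(counts.values()), tuple(flags))


def n2_nlr_conversion_correction(estimate: AlleleCountEstimate) -> AlleleCountEstimate:
    """Undo apparent NOTCH2 gains caused by NOTCH2 > NOTCH2NLR gene conversion.

    A genome whose NOTCH2NLR alleles were partly overwritten by NOTCH2
    sequence shows a complementary excess of NOTCH2 (e.g. 3 NOTCH2 / 1
    NOTCH2NLR). When NOTCH2 = 2+k and NOTCH2NLR = 2-k with k >= 1, k alleles
    are reassigned back to NOTCH2NLR; the total is unchanged. No-op otherwise.
    """
    n2 = estimate.counts.get(PARENT, 0)
    nlr = estimate.counts.get("NOTCH2NLR", 0)
    k = n2 - 2
    if k >= 1 and nlr == 2 - k:
        counts = dict(estimate.counts)
        counts[PARENT] = 2
        counts["NOTCH2NLR"] = 2
        return AlleleCountEstimate(
            counts, estimate.total_int, estimate.flags + ("N2>NLR conversion corrected",)
        )
    return estimate
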