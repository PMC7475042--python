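"""SUN genotyping: frequencies, the population filter, A/B split, corrections."""

import math

import numpy as np
import pandas as pd
import pytest

from paralocus.genotyper import (
    AlleleCountEstimate,
    PileupSite,
    SunFrequencyTable,
    locus_allele_counts,
    n2_nlr_conversion_correction,
    population_filter,
    sun_frequencies,
)
from paralocus.pipeline import PipelineConfig, analyze_sample
from paralocus.simulate import preset, simulate_individual, synthetic_sun_catalog
from paralocus.sun_catalog import SunCatalog, SunRecord
from paralocus.loci import ALL_LOCI


def site(pos, dp, ad_alt, ref="A", alt="G"):
    return PileupSite("chr1", pos, ref, alt, dp, dp - ad_alt, ad_alt)


def catalog_at(positions, paralog="NOTCH2NLC"):
    return SunCatalog(
        tuple(SunRecord(p, paralog, "A", "G") for p in positions), sun_region=(1, 10**9)
    )


def freq_table(rows):
    return SunFrequencyTable(pd.DataFrame(rows, columns=SunFrequencyTable.COLUMNS))


class TestSunFrequencies:
    def test_simple_division(self):
        table = sun_frequencies([site(10, 100, 20)], catalog_at([10]))
        assert table.df["frequency"].tolist() == [0.20]

    def test_zero_depth_is_missing_not_zero(self):
        table = sun_frequencies([site(10, 0, 0)], catalog_at([10]))
        assert math.isnan(table.df["frequency"].iloc[0])

    def test_parent_marker_reads_reference_column(self):
        # NOTCH2 marker: its unique base is the pileup REF
        cat = SunCatalog((SunRecord(10, "NOTCH2", parent_base="G", sun_base="A"),))
        table = sun_frequencies([site(10, 100, 80, ref="A", alt="G")], cat)
        assert table.df["frequency"].iloc[0] == pytest.approx(0.20)

    def test_unmatched_allele_skipped(self):
        cat = SunCatalog((SunRecord(10, "NLA", "A", "T"),))
        table = sun_frequencies([site(10, 100, 20, ref="C", alt="G")], cat)
        assert len(table.df) == 0

    def test_matches_per_site_division_oracle(self):
        rng = np.random.default_rng(1)
        positions = np.arange(1, 51)
        dps = rng.integers(1, 300, size=50)
        ads = np.array([rng.integers(0, dp + 1) for dp in dps])
        sites = [site(int(p), int(dp), int(ad)) for p, dp, ad in zip(positions, dps, ads)]
        table = sun_frequencies(sites, catalog_at(positions))
        assert np.allclose(table.df["frequency"].to_numpy(), ads / dps)


class TestPopulationFilter:
    def _cohort(self, per_sample_freqs, positions):
        rows = []
        for sample, freqs in per_sample_freqs.items():
            for pos, f in zip(positions, freqs):
                rows.append((sample, pos, "NOTCH2NLC", "G", f))
        return freq_table(rows)

    def test_fully_present_sun_retained(self):
        cat = catalog_at([1, 2])
        cohort = self._cohort({"s1": [0.2, 0.2], "s2": [0.2, 0.2]}, [1, 2])
        retained = population_filter(cohort, cat, expected_fraction=0.2)
        assert {r.position for r in retained} == {1, 2}

    def test_exactly_at_threshold_is_excluded(self):
        # normalized frequency exactly 0.67 in every sample: strict > drops it
        cat = catalog_at([1])
        cohort = self._cohort({"s1": [0.2 * 0.67], "s2": [0.2 * 0.67]}, [1])
        assert population_filter(cohort, cat, expected_fraction=0.2) == []

    def test_common_snp_in_half_the_cohort_excluded(self):
        # a population SNP looks like a SUN in half the samples only
        cat = catalog_at([1])
        cohort = self._cohort(
            {"s1": [0.2], "s2": [0.2], "s3": [0.0], "s4": [0.0]}, [1]
        )
        retained = population_filter(cohort, cat, expected_fraction=0.2)
        assert retained == []  # median normalized frequency 0.5 < 0.67

    def test_single_sample_passes_all_with_warning(self, caplog):
        cat = catalog_at([1, 2])
        cohort = self._cohort({"only": [0.0, 0.0]}, [1, 2])
        with caplog.at_level("WARNING", logger="paralocus.genotyper"):
            retained = population_filter(cohort, cat)
        assert len(retained) == 2
        assert any("single" in m or ">=2 samples" in m for m in caplog.messages)

    def test_never_removes_sun_at_full_normalized_frequency(self):
        rng = np.random.default_rng(3)
        cat = catalog_at(list(range(1, 21)))
        cohort = self._cohort(
            {f"s{i}": [0.2] * 20 for i in range(6)}, list(range(1, 21))
        )
        assert len(population_filter(cohort, cat, expected_fraction=0.2)) == 20


def one_sample_table(locus_freqs, n_suns=5):
    """Frequency table with n_suns identical-frequency SUNs per locus."""
    rows = []
    pos = 1
    for locus, f in locus_freqs.items():
        for _ in range(n_suns):
            rows.append(("s", pos, locus, "G", f))
            pos += 1
    return freq_table(rows)


def records_of(table):
    return [
        SunRecord(int(p), paralog, "A", "G")
        for p, paralog in zip(table.df["position"], table.df["paralog"])
    ]


class TestLocusAlleleCounts:
    def test_modal_configuration(self):
        table = one_sample_table(
            {"NOTCH2": 0.2, "NOTCH2NLR": 0.2, "NOTCH2NLC": 0.2,
             "NOTCH2NLA": 0.2, "NOTCH2NLB": 0.2}
        )
        est = locus_allele_counts(table, records_of(table), 10)
        assert est.counts == dict.fromkeys(ALL_LOCI, 2)
        assert est.total_int == 10

    def test_homozygous_deletion_counts_zero(self):
        table = one_sample_table(
            {"NOTCH2": 0.25, "NOTCH2NLR": 0.0, "NOTCH2NLC": 0.25,
             "NOTCH2NLA": 0.25, "NOTCH2NLB": 0.25}
        )
        est = locus_allele_counts(table, records_of(table), 8)
        assert est.counts["NOTCH2NLR"] == 0
        assert est.total_int == 8

    def test_ab_split_follows_frequency_ratio(self):
        # total 10, core loci take 6, A:B mean frequencies 0.3:0.1 -> 3:1
        table = one_sample_table(
            {"NOTCH2": 0.2, "NOTCH2NLR": 0.2, "NOTCH2NLC": 0.2,
             "NOTCH2NLA": 0.3, "NOTCH2NLB": 0.1}
        )
        est = locus_allele_counts(table, records_of(table), 10)
        assert est.counts["NOTCH2NLA"] == 3 and est.counts["NOTCH2NLB"] == 1

    def test_counts_always_conserve_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            freqs = {l: float(rng.uniform(0, 0.35)) for l in ALL_LOCI}
            total = int(rng.integers(2, 14))
            table = one_sample_table(freqs)
            est = locus_allele_counts(table, records_of(table), total)
            assert sum(est.counts.values()) == est.total_int == total

    def test_negative_remainder_clamps_and_flags(self):
        table = one_sample_table(
            {"NOTCH2": 0.5, "NOTCH2NLR": 0.5, "NOTCH2NLC": 0.5,
             "NOTCH2NLA": 0.1, "NOTCH2NLB": 0.1}
        )
        est = locus_allele_counts(table, records_of(table), 5)
        assert est.counts["NOTCH2NLA"] == est.counts["NOTCH2NLB"] == 0
        assert any("clamped" in f for f in est.flags)

    def test_missing_core_locus_named_in_error(self):
        table = one_sample_table({"NOTCH2": 0.2, "NOTCH2NLC": 0.2})
        with pytest.raises(ValueError, match="NOTCH2NLR"):
            locus_allele_counts(table, records_of(table), 10)


class TestConversionCorrection:
    def _est(self, n2, nlr):
        counts = {"NOTCH2": n2, "NOTCH2NLR": nlr, "NOTCH2NLC": 2,
                  "NOTCH2NLA": 2, "NOTCH2NLB": 2}
        return AlleleCountEstimate(counts, sum(counts.values()))

    def test_three_one_corrects_to_two_two(self):
        out = n2_nlr_conversion_correction(self._est(3, 1))
        assert out.counts["NOTCH2"] == out.counts["NOTCH2NLR"] == 2
        assert "N2>NLR conversion corrected" in out.flags
        assert out.total_int == 10

    def test_balanced_genome_untouched(self):
        est = self._est(2, 2)
        assert n2_nlr_conversion_correction(est) is est

    def test_generalizes_to_four_zero(self):
        out = n2_nlr_conversion_correction(self._est(4, 0))
        assert out.counts["NOTCH2"] == out.counts["NOTCH2NLR"] == 2

    def test_non_complementary_excess_not_corrected(self):
        est = self._est(3, 2)  # total shift, not conversion-like
        assert n2_nlr_conversion_correction(est).counts == est.counts


class TestSyntheticRecovery:
    def test_per_locus_counts_recovered_in_at_least_95_percent(self, catalog, pipeline_config):
        hits = 0
        reps = 100
        for seed in range(reps):
            cfg = preset("modern_human_standard", 30, seed=seed)
            ind = simulate_individual(cfg, catalog, "s")
            rep = analyze_sample("s", ind.depth_track, ind.pileups, catalog, pipeline_config)
            hits += rep.allele_counts.counts == {l: 2 for l in ALL_LOCI}
        assert hits >= 95

    def test_dropping_one_sun_never_changes_counts(self, catalog, modal_individual, pipeline_config):
        base = analyze_sample("modal", modal_individual.depth_track,
                              modal_individual.pileups, catalog, pipeline_config)
        for drop in range(len(catalog)):
            retained = [r for i, r in enumerate(catalog.records) if i != drop]
            rep = analyze_sample("modal", modal_individual.depth_track,
                                 modal_individual.pileups, catalog, pipeline_config,
                                 retained=retained)
            assert rep.allele_counts.counts == base.allele_counts.counts
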