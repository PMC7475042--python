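"""Shared study setup for the numbered analysis scripts.

One deterministic synthetic cohort stands in for the modern-human panel
(30 individuals, modal ten-allele genomes, Exon1 A-type variant segregating at
allele frequency 0.8 on the four A/B alleles) plus one Altai-Neanderthal-like
and one Denisova3-like genome. Scripts re-simulate it from the fixed seed
rather than shipping per-position files; every script therefore sees the same
data.
"""

from pathlib import Path

from paralocus.pipeline import PipelineConfig
from paralocus.simulate import (
    VARIANT_POSITIONS,
    preset,
    simulate_cohort,
    simulate_individual,
)

COHORT_SEED = 2026
COHORT_N = 30
BASE_DEPTH = 30.0
EXON1A_FREQ = 0.8  # most individuals carry 3-4 of 4 A/B alleles as A-type

RESULTS = Path(__file__).resolve().parent.parent / "results"


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(variant_sites=VARIANT_POSITIONS)


def modern_cohort():
    return simulate_cohort(
        COHORT_N, "modern_human_standard",
        exon1a_frequency=EXON1A_FREQ, base_depth=BASE_DEPTH, seed=COHORT_SEED,
    )


def archaic_individuals(catalog):
    alt = simulate_individual(
        preset("neanderthal_altai_like", BASE_DEPTH, seed=COHORT_SEED + 1), catalog, "Altai_like"
    )
    den = simulate_individual(
        preset("denisova3_like", BASE_DEPTH, seed=COHORT_SEED + 2), catalog, "Denisova3_like"
    )
    return [alt, den]


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
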