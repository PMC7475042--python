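"""Population tests of the Exon1 allele-count distribution.

Compares the cohort's observed Exon1A-(Low) allele counts against the
two-locus (AABB x AABB) polygenic expectation with a Kolmogorov-Smirnov test,
runs Kruskal-Wallis + Dunn across simulated groups, and Holm-adjusts all p
values. Also draws the exome-scale expected frequency distribution with loss
adjustment estimated from the cohort genotypes.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_SEED, ensure_results, modern_cohort, pipeline_config

from paralocus.dosage import EXON1A
from paralocus.pipeline import process_cohort
from paralocus.popstats import (
    ExpectedDistributionSpec,
    POLYGENIC_PROBS,
    dunn_test,
    expected_polygenic_sample,
    expected_ukb_sample,
    holm_adjust,
    ks_two_sample,
    simons_expected_spec,
)


def main() -> None:
    results = ensure_results()
    cohort = modern_cohort()
    config = pipeline_config()
    samples = [(i.sample_id, i.depth_track, i.pileups) for i in cohort.individuals]
    table, _ = process_cohort(samples, cohort.catalog, config)

    observed = table[EXON1A].to_numpy(dtype=float)
    # expectation under segregation at the cohort's configured 0.8 frequency:
    # Binomial(4, 0.8) category probabilities
    from scipy.stats import binom

    probs = tuple(binom.pmf(range(5), 4, 0.8))
    spec = ExpectedDistributionSpec((0, 1, 2, 3, 4), probs, 2790, 0.34, seed=COHORT_SEED)
    expected = expected_polygenic_sample(spec)
    ks = ks_two_sample(observed, np.round(expected))
    print(f"KS observed-vs-expected Exon1A counts: D={ks.statistic:.3f} p={ks.p_value:.3f}")

    # canonical 1:4:6:4:1 expectation for reference
    aabb = expected_polygenic_sample(simons_expected_spec(seed=COHORT_SEED))
    ks2 = ks_two_sample(observed, np.round(aabb))
    print(f"KS observed-vs-1:4:6:4:1 expectation: D={ks2.statistic:.3f} p={ks2.p_value:.3g}")

    groups = [observed,
              np.round(expected[:500]),
              np.round(aabb[:500])]
    dunn = dunn_test(groups, labels=["observed", "segregating-0.8", "AABBxAABB"])
    print(f"Kruskal-Wallis H={dunn.statistic:.2f} p={dunn.p_value:.3g}; Dunn pairs:")
    for a, b, z, raw, adj in dunn.pairwise:
        print(f"  {a} vs {b}: z={z:+.2f} p={raw:.3g} holm={adj:.3g}")

    # exome-scale expectation, loss rates estimated from the cohort genotypes
    loss_nlc = float((table["NOTCH2NLC"] < 2).mean())
    loss_nlr = float((table["NOTCH2NLR"] < 2).mean())
    ukb = expected_ukb_sample(n=50_000, loss_rate_nlc=loss_nlc,
                              loss_rate_nlr=loss_nlr, seed=COHORT_SEED)
    print(f"exome-scale expected frequencies: n={ukb.size}, mean {ukb.mean():.4f} "
          f"(loss rates NLC {loss_nlc:.2f}, NLR {loss_nlr:.2f})")

    payload = {
        "ks_observed_vs_segregating": {"D": ks.statistic, "p": ks.p_value},
        "ks_observed_vs_aabb": {"D": ks2.statistic, "p": ks2.p_value},
        "kruskal_wallis": {"H": dunn.statistic, "p": dunn.p_value},
        "dunn_pairs": [list(p) for p in dunn.pairwise],
        "holm_example": holm_adjust([ks.p_value, ks2.p_value]),
        "ukb_expected_mean": float(ukb.mean()),
    }
    (results / "population_stats.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {results / 'population_stats.json'}")


if __name__ == "__main__":
    main()
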