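"""Per-SUN allele-count tracks and interlocus gene-conversion segments.

Builds the cohort-median track, profiles the Altai-like genome (which carries
a NOTCH2->NOTCH2NLR conversion tract), infers the NOTCH2NLB complement track
in the 5' region, and exports called segments as BED.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import archaic_individuals, ensure_results, modern_cohort, pipeline_config

from paralocus.conversion import (
    call_conversion_segments,
    cohort_median_track,
    inferred_complement_track,
    per_sun_allele_track,
    segments_to_bed,
)
from paralocus.genotyper import sun_frequencies
from paralocus.pipeline import analyze_sample


def main() -> None:
    results = ensure_results()
    cohort = modern_cohort()
    config = pipeline_config()

    tracks = []
    for ind in cohort.individuals:
        freqs = sun_frequencies(ind.pileups, cohort.catalog, ind.sample_id)
        tracks.append(per_sun_allele_track(freqs, ind.truth.total_alleles))
    median = cohort_median_track(tracks)
    median.df.to_csv(results / "cohort_median_track.tsv", sep="\t", index=False)

    altai = archaic_individuals(cohort.catalog)[0]
    rep = analyze_sample(altai.sample_id, altai.depth_track, altai.pileups,
                         cohort.catalog, config)
    rep.track.df.to_csv(results / "altai_like_track.tsv", sep="\t", index=False)
    (results / "altai_like_segments.bed").write_text(
        segments_to_bed(rep.segments, cohort.catalog.chrom))

    # complement inference on the 5' half, where NOTCH2NLB has no SUNs
    region = cohort.catalog.sun_region
    mid = (region[0] + region[1]) // 2
    a_track = rep.track.for_paralog("NOTCH2NLA")
    b_inferred = inferred_complement_track(a_track, rep.allele_counts.counts["NOTCH2NLA"]
                                           + rep.allele_counts.counts["NOTCH2NLB"],
                                           region=(region[0], mid))
    b_inferred.df.to_csv(results / "altai_like_b_inferred.tsv", sep="\t", index=False)

    cohort_segments = call_conversion_segments(median, config.segment_default_count,
                                               config.segment_min_run)
    print(f"cohort-median track: {len(median)} SUNs; "
          f"{len(cohort_segments)} recurrent deviation segments")
    print(f"Altai-like genome: {len(rep.segments)} segments called:")
    for s in rep.segments:
        print(f"  {s.paralog} {s.direction} x{s.magnitude} "
              f"chr1:{s.start}-{s.end}")
    print(f"wrote tracks and segments under {results}")


if __name__ == "__main__":
    main()
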