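"""Per-SUN allele-count tracks and interlocus gene-conversion segments.

Multiplying each SUN's observed frequency by the genome's total allele count
gives a position-wise allele-count track along the locus. Runs of SUNs whose
count deviates from the expected two alleles mark stretches where one paralog's
sequence has overwritten another's (interlocus gene conversion). For the
NOTCH2NLA/NOTCH2NLB pair the 5' region carries no B-specific SUNs, so the B
track there is inferred as the complement of the A track against the pair
total (modally four alleles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .genotyper import SunFrequencyTable


@dataclass
class SunTrack:
    """Ordered (position, paralog, allele_count_real) observations.

    ``df`` has columns ``position, paralog, count_real`` (plus ``count_median``
    for cohort tracks), sorted by position.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"position", "paralog", "count_real"}
        if not need <= set(self.df.columns):
            raise ValueError(f"track requires columns {sorted(need)}")
        if (self.df["count_real"] < 0).any():
            raise ValueError("allele counts must be non-negative")
        self.df = self.df.sort_values("position", kind="stable").reset_index(drop=True)

    def for_paralog(self, name: str) -> "SunTrack":
        return SunTrack(self.df[self.df["paralog"] == name])

    def __len__(self) -> int:
        return len(self.df)


def per_sun_allele_track(freqs: SunFrequencyTable, total_alleles_int: int) -> SunTrack:
    """Scale one sample's SUN frequencies to allele counts; missing sites are
    omitted rather than zero-filled."""
    df = freqs.df.dropna(subset=["frequency"]).copy()
    df["count_real"] = df["frequency"] * total_alleles_int
    return SunTrack(df[["position", "paralog", "count_real"]])


def cohort_median_track(tracks: Sequence[SunTrack]) -> SunTrack:
    """Median allele count per SUN across samples (the cohort-level view used
    to spot recurrent conversion)."""
    if not tracks:
        raise ValueError("no tracks")
    cat = pd.concat([t.df for t in tracks], ignore_index=True)
    med = (
        cat.groupby(["position", "paralog"], as_index=False)["count_real"]
        .median()
        .rename(columns={"count_real": "count_median"})
    )
    med["count_real"] = med["count_median"]
    return SunTrack(med[["position", "paralog", "count_real", "count_median"]])


def inferred_complement_track(
    track_a: SunTrack,
    pair_total: int,
    complement_paralog: str = "NOTCH2NLB",
    region: tuple[int, int] | None = None,
) -> SunTrack:
    """Infer the B-paralog track where it has no SUNs of its own.

    At each A-SUN position, B count = pair_total - A count, clamped at zero
    (e.g. four combined A+B alleles and three A alleles imply one B allele).
    """
    if pair_total is None:
        raise ValueError("pair_total is required")
    df = track_a.df
    if region is not None:
        s, e = region
        df = df[(df["position"] >= s) & (df["position"] <= e)]
    out = df[["position"]].copy()
    out["paralog"] = complement_paralog
    out["count_real"] = np.maximum(pair_total - df["count_real"].to_numpy(), 0.0)
    return SunTrack(out)


@dataclass(frozen=True)
class ConversionSegment:
    """A maximal run of SUNs deviating from the expected allele count."""

    start: int
    end: int
    paralog: str
    direction: str  # gain | loss
    magnitude: int  # alleles, >= 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.direction not in {"gain", "loss"}:
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.magnitude < 1:
            raise ValueError("magnitude must be >= 1")


def call_conversion_segments(
    track: SunTrack,
    default_count: int = 2,
    min_run: int = 3,
) -> list[ConversionSegment]:
    """Call conversion segments as runs of same-direction deviations.

    A segment is a maximal run of >= ``min_run`` consecutive SUNs (per
    paralog) whose rounded allele count deviates from ``default_count`` in the
    same direction; its magnitude is the median rounded deviation in the run.
    Shorter runs are treated as noise.
    """
    segments: list[ConversionSegment] = []
    for paralog in dict.fromkeys(track.df["paralog"]):
        sub = track.for_paralog(paralog).df
        positions = sub["position"].to_numpy()
        dev = np.array([round_half_away(c) - default_count for c in sub["count_real"]])
        sign = np.sign(dev)
        i = 0
        n = len(sign)
        while i < n:
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j < n and sign[j] == sign[i]:
                j += 1
            if j - i >= min_run:
                run = dev[i:j]
                segments.append(
                    ConversionSegment(
                        start=int(positions[i]),
                        end=int(positions[j - 1]),
                        paralog=paralog,
                        direction="gain" if sign[i] > 0 else "loss",
                        magnitude=int(round_half_away(float(np.median(np.abs(run))))),
                    )
                )
            i = j
    return segments


def segments_to_bed(segments: Sequence[ConversionSegment], chrom: str = "chr1") -> str:
    """BED (0-based half-open) export, name = paralog:direction:magnitude."""
    lines = [
        f"{chrom}\t{s.start - 1}\t{s.end}\t{s.paralog}:{s.direction}:{s.magnitude}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
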