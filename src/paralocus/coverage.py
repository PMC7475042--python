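"""Combined allele-count estimation from the multicopy/single-copy depth ratio.

On a reference with the NOTCH2NL loci masked, every family read maps onto the
parent NOTCH2 locus, so mean depth over the shared (multicopy) region is
proportional to the combined number of NOTCH2 + NOTCH2NL alleles, while a
NOTCH2-only region carries exactly two alleles in any genome. The combined
allele count is therefore ``2 x (multicopy mean depth / single-copy mean
depth)``. Repeat intervals are masked before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_away


@dataclass
class DepthTrack:
    """Per-position read depth over one contiguous genomic span.

    ``start`` is the 1-based position of ``depths[0]``.
    """

    chrom: str
    start: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError("depths must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.depths.size - 1


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s > e:
            raise ValueError(f"inverted interval {s}-{e}")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class RegionSet:
    """Intervals to average over, minus repeat intervals to mask.

    All intervals are 1-based inclusive; overlapping intervals are merged on
    construction and the exclusions are subtracted before any mean is taken.
    """

    intervals: list[tuple[int, int]]
    excluded: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _merge(list(self.intervals))
        self.excluded = _merge(list(self.excluded))

    def mask_over(self, start: int, length: int) -> np.ndarray:
        """Boolean mask (length ``length``, first position ``start``) of
        positions inside the intervals and outside the exclusions."""
        pos = np.arange(start, start + length)
        mask = np.zeros(length, dtype=bool)
        for s, e in self.intervals:
            mask |= (pos >= s) & (pos <= e)
        for s, e in self.excluded:
            mask &= ~((pos >= s) & (pos <= e))
        return mask


def mean_depth(track: DepthTrack, regions: RegionSet) -> float:
    """Arithmetic mean depth over unmasked in-region positions."""
    mask = regions.mask_over(track.start, track.depths.size)
    if not mask.any():
        raise ValueError("empty region after masking")
    return float(track.depths[mask].mean())


@dataclass(frozen=True)
class TotalAlleleEstimate:
    """Combined NOTCH2 + NOTCH2NL allele count for one individual."""

    ratio: float
    total_alleles_real: float
    total_alleles_int: int


def total_allele_count(multi_mean: float, single_mean: float) -> TotalAlleleEstimate:
    """Convert the multicopy/single-copy depth ratio into an allele count.

    The single-copy region represents two alleles in every genome, so the
    combined count is twice the ratio; the integer estimate rounds half away
    from zero.
    """
    if single_mean <= 0:
        raise ValueError("uninformative single-copy coverage")
    ratio = multi_mean / single_mean
    real = 2.0 * ratio
    return TotalAlleleEstimate(ratio, real, round_half_away(real))
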