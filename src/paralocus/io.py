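"""Readers and writers for the pipeline's plain-text formats.

Internal coordinates are 1-based inclusive (matching printed genomic
coordinates); BED and bedGraph are 0-based half-open and convert at the
boundary. The pileup dialect is the 7-column table produced by
``bcftools query -f '%CHROM\\t%POS\\t%REF\\t%ALT{0} [\\t%DP\\t%AD{0}\\t%AD{1}]\\n'``:
CHROM, POS (1-based), REF, ALT, DP, AD_ref, AD_alt, with '#'-prefixed header
lines tolerated.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .coverage import DepthTrack
from .genotyper import PileupSite


def parse_pileup_table(text: str) -> list[PileupSite]:
    sites = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"pileup line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            chrom, pos, ref, alt, dp, ad_ref, ad_alt = fields
            sites.append(PileupSite(chrom, int(pos), ref, alt, int(dp), int(ad_ref), int(ad_alt)))
        except ValueError as exc:
            raise ValueError(f"pileup line {lineno}: {exc}") from exc
    return sites


def write_pileup_table(sites: Iterable[PileupSite]) -> str:
    lines = ["#CHROM\tPOS\tREF\tALT\tDP\tAD_ref\tAD_alt"]
    for s in sites:
        lines.append(f"{s.chrom}\t{s.position}\t{s.ref_base}\t{s.alt_base}\t{s.dp}\t{s.ad_ref}\t{s.ad_alt}")
    return "\n".join(lines) + "\n"


def parse_bedgraph(text: str) -> DepthTrack:
    """Expand a bedGraph into a per-position track; gaps inside the covered
    span are depth 0."""
    intervals = []
    chrom = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"bedGraph line {lineno}: expected 4 columns, got {len(fields)}")
        try:
            c, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"bedGraph line {lineno}: {exc}") from exc
        if chrom is None:
            chrom = c
        elif c != chrom:
            raise ValueError(f"bedGraph line {lineno}: multiple chromosomes not supported")
        if end <= start:
            raise ValueError(f"bedGraph line {lineno}: empty or inverted interval")
        intervals.append((start, end, value))
    if not intervals:
        raise ValueError("empty bedGraph")
    lo = min(s for s, _, _ in intervals)
    hi = max(e for _, e, _ in intervals)
    depths = np.zeros(hi - lo, dtype=float)
    for start, end, value in intervals:
        depths[start - lo:end - lo] = value
    return DepthTrack(chrom, lo + 1, depths)


def write_bedgraph(track: DepthTrack) -> str:
    """Run-length-compressed bedGraph of a depth track."""
    depths = np.asarray(track.depths)
    change = np.flatnonzero(np.diff(depths)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [depths.size]])
    start0 = track.start - 1
    lines = [
        f"{track.chrom}\t{start0 + s}\t{start0 + e}\t{_fmt(depths[s])}"
        for s, e in zip(starts, ends)
    ]
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_bed(text: str) -> list[tuple[str, int, int, str | None]]:
    """BED intervals as (chrom, start 1-based, end, name-or-None)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: expected >=3 columns, got {len(fields)}")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: {exc}") from exc
        if end <= start:
            raise ValueError(f"BED line {lineno}: empty or inverted interval")
        out.append((chrom, start + 1, end, fields[3] if len(fields) > 3 else None))
    return out


def write_bed(intervals: Sequence[tuple[str, int, int, str | None]]) -> str:
    lines = []
    for chrom, start, end, name in intervals:
        base = f"{chrom}\t{start - 1}\t{end}"
        lines.append(base + (f"\t{name}" if name is not None else ""))
    return "\n".join(lines) + ("\n" if lines else "")
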