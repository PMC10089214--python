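"""ROSE-style enhancer/superenhancer calling.

Candidate enhancer peaks that overlap a promoter window (TSS +/- 2 kb) are
excluded unless they are embedded in a larger acetylation-positive chromatin
domain (their 12.5-kb stitched cluster also contains a non-promoter peak).
Retained peaks are stitched at +/-12.5 kb, each stitched region is scored by
its input-subtracted ChIP signal (both tracks scaled to per-million), and the
enhancer-vs-superenhancer cut point is the geometric inflection of the
score-vs-rank curve: with ranks and scores each rescaled to [0, 1], the point
where a slope-1 line is tangent to the ascending curve, i.e. the point
maximizing y - x.  Enhancers strictly above the cutoff score are called super.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .intervals import (GeneModel, GenomicInterval, IntervalSet,
                        promoter_window, stitch)
from .tracks import SignalTrack, region_signal

__all__ = ["StitchedEnhancer", "SECallResult", "exclude_promoter_peaks",
           "score_stitched_enhancers", "call_superenhancers", "rose_pipeline"]

DEFAULT_STITCH_GAP = 12_500
DEFAULT_TSS_WINDOW = 2_000


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: int
    chip_signal: float  # per-million region sum
    input_signal: float
    score: float = field(init=False)
    rank: int = 0

    def __post_init__(self) -> None:
        self.score = max(self.chip_signal - self.input_signal, 0.0)


@dataclass
class SECallResult:
    enhancers: list[StitchedEnhancer]  # rank order (1 = highest score)
    cutoff_score: float
    is_super: list[bool]

    @property
    def n_super(self) -> int:
        return sum(self.is_super)

    def superenhancers(self) -> list[StitchedEnhancer]:
        return [e for e, s in zip(self.enhancers, self.is_super) if s]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tconstituents\tchip\tinput\tscore\trank\tis_super\n")
            for e, s in zip(self.enhancers, self.is_super):
                iv = e.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.constituents}\t"
                         f"{e.chip_signal:.6f}\t{e.input_signal:.6f}\t{e.score:.6f}\t"
                         f"{e.rank}\t{int(s)}\n")


@dataclass
class ExclusionReport:
    excluded: list[GenomicInterval]
    rescued: list[GenomicInterval]  # promoter-overlapping but embedded
    retained: int


def exclude_promoter_peaks(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    tss_window: int = DEFAULT_TSS_WINDOW,
    max_gap: int = DEFAULT_STITCH_GAP,
) -> tuple[IntervalSet, ExclusionReport]:
    """Drop peaks overlapping TSS +/- ``tss_window``, rescuing embedded ones.

    A promoter-overlapping peak is kept when, after provisionally stitching
    ALL peaks at ``max_gap``, its stitched region also contains at least one
    peak that does not touch a promoter (it sits inside a larger
    acetylation-positive domain).  With no genes supplied every peak is
    retained and a warning is issued.
    """
    if not genes:
        warnings.warn("no gene models supplied; promoter exclusion skipped")
        return peaks, ExclusionReport([], [], len(peaks))
    promoters = IntervalSet(
        promoter_window(g, upstream=tss_window, downstream=tss_window) for g in genes
    )
    is_prom = [promoters.any_overlap(p) for p in peaks]
    stitched = stitch(peaks, max_gap)
    # map each peak to its stitched region (peaks are contained by construction)
    region_has_distal: dict[tuple, bool] = {}
    peak_region: list[tuple] = []
    for p, prom in zip(peaks, is_prom):
        hits = [r for r in stitched.overlapping(p)]
        key = (hits[0].chrom, hits[0].start, hits[0].end)
        peak_region.append(key)
        if not prom:
            region_has_distal[key] = True
    retained, excluded, rescued = [], [], []
    for p, prom, key in zip(peaks, is_prom, peak_region):
        if not prom:
            retained.append(p)
        elif region_has_distal.get(key, False):
            retained.append(p)
            rescued.append(p)
        else:
            excluded.append(p)
    return (IntervalSet(retained, genome=peaks.genome),
            ExclusionReport(excluded, rescued, len(retained)))


def score_stitched_enhancers(
    peaks: IntervalSet,
    chip: SignalTrack,
    input_track: SignalTrack,
    max_gap: int = DEFAULT_STITCH_GAP,
) -> list[StitchedEnhancer]:
    """Stitch peaks and score each region by input-subtracted ChIP signal.

    Both tracks are scaled to per-million mapped reads before the region
    sums, so libraries of different depth are comparable; the difference is
    floored at 0.  Returned list is in rank order (descending score, ties by
    genomic position).
    """
    if not chip.total_reads or not input_track.total_reads:
        raise ValueError("both tracks need total_reads for per-million scaling")
    stitched = stitch(peaks, max_gap)
    out = []
    for region in stitched:
        c = region_signal(chip, region, "sum") * 1e6 / chip.total_reads
        i = region_signal(input_track, region, "sum") * 1e6 / input_track.total_reads
        out.append(StitchedEnhancer(region, int(region.score or 1), c, i))
    out.sort(key=lambda e: (-e.score, e.interval.chrom, e.interval.start, e.interval.end))
    for r, e in enumerate(out, start=1):
        e.rank = r
    return out


def inflection_cutoff(scores: np.ndarray) -> float:
    """Cut-point score via the slope-1 tangent on the unit-rescaled curve.

    Scores are sorted ascending; x = rank index and y = score are each
    rescaled to [0, 1].  The ascending score curve is (empirically) convex,
    so the point where a line of slope 1 is tangent to it from below is the
    point of maximal distance below the diagonal: the index minimizing
    y - x.  Degenerate inputs (all scores equal, or fewer than 3) return the
    maximum score so nothing is called super.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return float(s[-1]) if n else 0.0
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    return float(s[int(np.argmin(y - x))])


def call_superenhancers(enhancers: Sequence[StitchedEnhancer]) -> SECallResult:
    """Partition ranked enhancers into typical and super at the inflection.

    Enhancers with score strictly above the cutoff are flagged super.  With
    fewer than 3 enhancers or a flat score curve everything is typical.
    """
    enhancers = sorted(enhancers, key=lambda e: e.rank)
    scores = np.array([e.score for e in enhancers])
    if len(scores) < 3:
        if len(scores):
            warnings.warn("fewer than 3 enhancers; none called super")
        cutoff = float(scores.max()) if len(scores) else 0.0
        return SECallResult(list(enhancers), cutoff, [False] * len(scores))
    cutoff = inflection_cutoff(scores)
    flags = [bool(e.score > cutoff) for e in enhancers]
    return SECallResult(list(enhancers), cutoff, flags)


def rose_pipeline(
    peaks: IntervalSet,
    chip: SignalTrack,
    input_track: SignalTrack,
    genes: Sequence[GeneModel] = (),
    tss_window: int = DEFAULT_TSS_WINDOW,
    max_gap: int = DEFAULT_STITCH_GAP,
) -> tuple[SECallResult, ExclusionReport]:
    """Full E/SE call: promoter exclusion -> stitch + score -> inflection cut."""
    retained, report = exclude_promoter_peaks(peaks, genes, tss_window, max_gap)
    enhancers = score_stitched_enhancers(retained, chip, input_track, max_gap)
    return call_superenhancers(enhancers), report
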