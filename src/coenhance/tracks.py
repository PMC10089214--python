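"""Interval-valued signal tracks (bedGraph) and binned BPM profile matrices.

A :class:`SignalTrack` is a step function over the genome: non-overlapping
(start, end, value) steps per chromosome.  Profiles are computed in fixed-width
bins inside a window centered on each region midpoint and can be scaled to
bins per million mapped reads (BPM = raw bin signal x 1e6 / total mapped
reads, deepTools-compatible semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet

__all__ = ["SignalTrack", "ProfileMatrix", "read_bedgraph", "write_bedgraph",
           "region_signal", "profile_matrix"]


class SignalTrack:
    """Sorted, non-overlapping signal steps per chromosome.

    ``total_reads`` is the library size used for per-million scaling; when
    not supplied it stays ``None`` and BPM operations on this track error.
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 total_reads: Optional[int] = None):
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: step with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping steps")
            if np.any(~np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"{chrom}: values must be finite and >= 0")
            self.steps[chrom] = (starts, ends, values)
            total += float(np.sum(values * (ends - starts)))
        self.total_signal = total
        self.total_reads = total_reads

    @classmethod
    def from_intervals(cls, entries: Sequence[tuple[str, int, int, float]],
                       total_reads: Optional[int] = None) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in entries:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        steps = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            a = np.array(rows, dtype=float)
            steps[chrom] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
        return cls(steps, total_reads=total_reads)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.steps)


def read_bedgraph(path: str | Path, total_reads: Optional[int] = None) -> SignalTrack:
    """Read a 4-column bedGraph.  Overlapping steps or negative values error
    with the offending line number.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if v < 0:
                raise ValueError(f"line {lineno}: negative value {v}")
            entries.append((chrom, s, e, v))
    try:
        return SignalTrack.from_intervals(entries, total_reads=total_reads)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def _interval_sum(track: SignalTrack, chrom: str, lo: int, hi: int) -> float:
    """Sum of value x overlap-span for steps intersecting [lo, hi)."""
    if chrom not in track.steps or hi <= lo:
        return 0.0
    starts, ends, values = track.steps[chrom]
    i = np.searchsorted(ends, lo, side="right")
    j = np.searchsorted(starts, hi, side="left")
    if i >= j:
        return 0.0
    s = np.maximum(starts[i:j], lo)
    e = np.minimum(ends[i:j], hi)
    span = np.maximum(e - s, 0)
    return float(np.sum(values[i:j] * span))


def region_signal(track: SignalTrack, region: GenomicInterval, stat: str = "sum") -> float:
    """Signal over a region: ``sum`` of value x span, or ``mean`` per bp."""
    total = _interval_sum(track, region.chrom, region.start, region.end)
    if stat == "sum":
        return total
    if stat == "mean":
        return total / len(region)
    raise ValueError(f"unknown stat {stat!r}")


@dataclass
class ProfileMatrix:
    """Regions x bins signal matrix around region midpoints."""

    values: np.ndarray  # (n_regions, n_bins)
    window_bp: int
    bin_bp: int
    normalization: str  # "raw" | "bpm"
    out_of_bounds: np.ndarray = field(default=None)  # bool mask, bins clipped at chrom edge

    @property
    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0) if len(self.values) else np.zeros(0)

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")


def profile_matrix(track: SignalTrack, regions: IntervalSet, window_bp: int = 3000,
                   bin_bp: int = 100, normalize: str = "bpm") -> tuple[ProfileMatrix, np.ndarray]:
    """Binned signal in a ``window_bp`` window centered on each region midpoint.

    Returns the matrix and its column-mean vector (the average profile).
    Bins falling below coordinate 0 are zero-filled and flagged in
    ``out_of_bounds``.  BPM requires ``track.total_reads``.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be divisible by bin_bp")
    if normalize not in ("raw", "bpm"):
        raise ValueError(f"unknown normalization {normalize!r}")
    if normalize == "bpm" and not track.total_reads:
        raise ValueError("BPM normalization requires track.total_reads")
    n_bins = window_bp // bin_bp
    half = window_bp // 2
    mat = np.zeros((len(regions), n_bins))
    oob = np.zeros((len(regions), n_bins), dtype=bool)
    genome = regions.genome or {}
    for ri, r in enumerate(regions):
        mid = r.midpoint
        w0 = mid - half
        limit = genome.get(r.chrom)
        for b in range(n_bins):
            lo = w0 + b * bin_bp
            hi = lo + bin_bp
            if hi <= 0 or (limit is not None and lo >= limit):
                oob[ri, b] = True
                continue
            if lo < 0:
                oob[ri, b] = True
                lo = 0
            if limit is not None and hi > limit:
                oob[ri, b] = True
                hi = limit
            mat[ri, b] = _interval_sum(track, r.chrom, lo, hi)
    if normalize == "bpm":
        mat = mat * (1e6 / track.total_reads)
    pm = ProfileMatrix(mat, window_bp, bin_bp, normalize, oob)
    return pm, pm.column_means
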