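"""Chromatin-state classification of regions from histone-mark peak sets.

Enhancer states follow the standard mark combinatorics: active enhancers are
H3K4me1+/H3K4me3-/H3K27ac+, poised enhancers H3K4me1+/H3K4me3-/H3K27ac-.
H3K4me3 presence dominates and yields promoter_like regardless of the other
marks; everything else is unmarked.  Mark presence is >= 1 bp overlap with
the corresponding peak set by default (an optional minimum overlap fraction
of the region can be required instead).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import GenomicInterval, IntervalSet

__all__ = ["StateCall", "classify_regions", "state_counts", "write_state_calls"]

STATES = ("active_enhancer", "poised_enhancer", "promoter_like", "unmarked")


@dataclass(frozen=True)
class StateCall:
    region: GenomicInterval
    has_k4me1: bool
    has_k4me3: bool
    has_k27ac: bool
    state: str


def _state_from_flags(k4me1: bool, k4me3: bool, k27ac: bool) -> str:
    if k4me3:
        return "promoter_like"
    if k4me1 and k27ac:
        return "active_enhancer"
    if k4me1:
        return "poised_enhancer"
    return "unmarked"


def _present(region: GenomicInterval, marks: IntervalSet, min_fraction: float) -> bool:
    if min_fraction <= 0:
        return marks.any_overlap(region)
    covered = 0
    for m in marks.overlapping(region):
        covered += min(region.end, m.end) - max(region.start, m.start)
    return covered / len(region) >= min_fraction


def classify_regions(
    regions: IntervalSet,
    k4me1: IntervalSet,
    k4me3: IntervalSet,
    k27ac: IntervalSet,
    min_fraction: float = 0.0,
) -> list[StateCall]:
    """Assign each region exactly one chromatin state from its mark overlaps."""
    out = []
    for r in regions:
        f1 = _present(r, k4me1, min_fraction)
        f3 = _present(r, k4me3, min_fraction)
        fa = _present(r, k27ac, min_fraction)
        out.append(StateCall(r, f1, f3, fa, _state_from_flags(f1, f3, fa)))
    return out


def state_counts(calls: Sequence[StateCall]) -> dict[str, int]:
    c = Counter(call.state for call in calls)
    return {s: c.get(s, 0) for s in STATES}


def write_state_calls(calls: Sequence[StateCall], tsv_path: str | Path,
                      summary_path: str | Path | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tstart\tend\thas_k4me1\thas_k4me3\thas_k27ac\tstate\n")
        for c in calls:
            r = c.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{int(c.has_k4me1)}\t"
                     f"{int(c.has_k4me3)}\t{int(c.has_k27ac)}\t{c.state}\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(state_counts(calls), fh, indent=2, sort_keys=True)
            fh.write("\n")
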