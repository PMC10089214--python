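"""Seeded generators for every pipeline input, with ground truth attached.

Each generator is a pure function of (parameters, seed).  A master seed fans
out to per-stage child streams as ``default_rng([seed, STAGE_ID])`` with the
stage ids in :data:`STAGE_IDS`, so any stage can be regenerated independently
of the others.

Study conditions emulated: two ChIP-seq peak sets with a planted co-bound
fraction at < 1 kb; ChIP/input signal tracks containing planted
superenhancers (clusters of 3-6 constituent peaks at ~10x the typical
enhancer signal density); histone-mark peak sets realizing planted
active/poised/promoter chromatin states; and NB count matrices with planted
log2 fold changes plus gene-set collections in which some sets are enriched
for same-direction DE genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .gsea import GeneSet, GeneSetCollection
from .intervals import GeneModel, GenomicInterval, IntervalSet
from .tracks import SignalTrack

__all__ = ["STAGE_IDS", "child_rng", "simulate_genome", "simulate_cooccupancy",
           "simulate_enhancer_peaks", "simulate_se_signal",
           "simulate_state_marks", "simulate_counts",
           "SimulatedGenome", "SimulatedCooccupancy", "SimulatedSESignal",
           "SimulatedMarks", "SimulatedCounts"]

STAGE_IDS = {"genome": 1, "cooccupancy": 2, "enhancers": 3, "se_signal": 4,
             "marks": 5, "counts": 6}


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage child stream of the master seed (documented counter scheme)."""
    return np.random.default_rng([int(seed), STAGE_IDS[stage]])


# ---------------------------------------------------------------------------
# genome / genes
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]


DEFAULT_BIOTYPE_MIX = {"protein_coding": 1.0}


def simulate_genome(n_chroms: int = 3, chrom_len: int = 30_000_000,
                    n_genes: int = 500,
                    biotype_mix: Optional[dict[str, float]] = None,
                    seed: int = 0) -> SimulatedGenome:
    """Uniformly place non-overlapping genes on ``n_chroms`` chromosomes.

    Strands are Bernoulli(0.5); biotypes are drawn from ``biotype_mix``
    (probabilities, normalized).  Transcript spans are 2-20 kb and exonic
    lengths 0.5 kb up to the span.  Placement is rejection-sampled; an
    infeasible density errors after a bounded number of attempts.
    """
    rng = child_rng(seed, "genome")
    mix = biotype_mix or DEFAULT_BIOTYPE_MIX
    bt_names = sorted(mix)
    bt_p = np.array([mix[b] for b in bt_names], dtype=float)
    bt_p = bt_p / bt_p.sum()
    chrom_sizes = {f"chr{i+1}": chrom_len for i in range(n_chroms)}
    chroms = sorted(chrom_sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes = []
    attempts_cap = 200 * max(n_genes, 1)
    attempts = 0
    gi = 0
    while gi < n_genes:
        attempts += 1
        if attempts > attempts_cap:
            raise ValueError("gene density infeasible: placement attempts exhausted")
        chrom = chroms[rng.integers(len(chroms))]
        span = int(rng.integers(2_000, 20_001))
        start = int(rng.integers(0, chrom_sizes[chrom] - span))
        end = start + span
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = bt_names[rng.choice(len(bt_names), p=bt_p)]
        length = int(rng.integers(500, span + 1))
        gid = f"gene{gi+1:05d}"
        genes.append(GeneModel(gid, gid.upper(), chrom, strand, start, end,
                               biotype, length))
        gi += 1
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return SimulatedGenome(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# co-occupancy peaks
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCooccupancy:
    set_a: IntervalSet
    set_b: IntervalSet
    truth: pd.DataFrame  # one row per A peak: name, cobound, planted_distance

    @property
    def true_fraction(self) -> float:
        return float(self.truth["cobound"].mean()) if len(self.truth) else 0.0


def _pick_slots(chrom_sizes: dict[str, int], slot_width: int, n: int,
                rng: np.random.Generator) -> list[tuple[str, int]]:
    slots = []
    for chrom in sorted(chrom_sizes):
        for i in range(chrom_sizes[chrom] // slot_width):
            slots.append((chrom, i * slot_width))
    if n > len(slots):
        raise ValueError(f"placement infeasible: need {n} slots, have {len(slots)}")
    idx = rng.choice(len(slots), size=n, replace=False)
    return [slots[i] for i in sorted(idx)]


def simulate_cooccupancy(chrom_sizes: dict[str, int], n_a: int = 1000,
                         n_b: int = 1000, cobound_fraction: float = 0.6,
                         max_dist: int = 1000, seed: int = 0) -> SimulatedCooccupancy:
    """Two peak sets with a planted co-bound fraction at edge distance < max_dist.

    A co-bound A peak gets a B partner at edge gap Uniform{0..max_dist-1};
    solo A peaks and surplus B peaks sit in their own slots, guaranteeing
    >= 5 x max_dist separation from the other factor, so the truth label is
    unambiguous.
    """
    if not 0 <= cobound_fraction <= 1:
        raise ValueError("cobound_fraction must be in [0, 1]")
    rng = child_rng(seed, "cooccupancy")
    n_cobound = int(round(cobound_fraction * n_a))
    n_extra_b = max(n_b - n_cobound, 0)
    slot_width = 20 * max(max_dist, 500)
    margin = 5 * max_dist
    slots = _pick_slots(chrom_sizes, slot_width, n_a + n_extra_b, rng)
    order = rng.permutation(n_a + n_extra_b)
    a_peaks, b_peaks, rows = [], [], []
    for j in range(n_a):
        chrom, s0 = slots[order[j]]
        wa = int(rng.integers(200, 801))
        a_start = s0 + margin
        a = GenomicInterval(chrom, a_start, a_start + wa, name=f"A{j+1:05d}")
        a_peaks.append(a)
        cob = j < n_cobound
        d = int(rng.integers(0, max_dist)) if cob else -1
        if cob:
            wb = int(rng.integers(200, 801))
            b_start = a.end + d
            b_peaks.append(GenomicInterval(chrom, b_start, b_start + wb,
                                           name=f"B{j+1:05d}"))
        rows.append({"name": a.name, "chrom": chrom, "start": a.start,
                     "end": a.end, "cobound": cob, "planted_distance": d})
    for j in range(n_extra_b):
        chrom, s0 = slots[order[n_a + j]]
        wb = int(rng.integers(200, 801))
        b_start = s0 + margin
        b_peaks.append(GenomicInterval(chrom, b_start, b_start + wb,
                                       name=f"Bx{j+1:05d}"))
    truth = pd.DataFrame(rows)
    return SimulatedCooccupancy(IntervalSet(a_peaks, genome=chrom_sizes),
                                IntervalSet(b_peaks, genome=chrom_sizes), truth)


# ---------------------------------------------------------------------------
# superenhancer signal
# ---------------------------------------------------------------------------

def simulate_enhancer_peaks(chrom_sizes: dict[str, int], n: int = 100,
                            seed: int = 0, min_separation: int = 30_000
                            ) -> IntervalSet:
    """Isolated candidate enhancer peaks, each > ``min_separation`` apart so
    every peak stitches into its own region at the 12.5-kb gap.
    """
    rng = child_rng(seed, "enhancers")
    slot_width = min_separation + 10_000
    slots = _pick_slots(chrom_sizes, slot_width, n, rng)
    peaks = []
    for j, (chrom, s0) in enumerate(slots):
        w = int(rng.integers(500, 1_501))
        start = s0 + 2_000
        peaks.append(GenomicInterval(chrom, start, start + w, name=f"E{j+1:04d}"))
    return IntervalSet(peaks, genome=chrom_sizes)


@dataclass
class SimulatedSESignal:
    peaks: IntervalSet          # ordinary + planted SE constituent peaks
    chip: SignalTrack
    input_track: SignalTrack
    truth: pd.DataFrame         # planted regions: chrom, start, end, is_super


def simulate_se_signal(peaks: IntervalSet, se_clusters: int = 5,
                       enrichment_ratio: float = 10.0, background: float = 1.0,
                       seed: int = 0, stitch_gap: int = 12_500
                       ) -> SimulatedSESignal:
    """Plant SE clusters next to ordinary enhancer peaks and emit signal tracks.

    Each cluster is 3-6 constituent peaks with consecutive gaps well inside
    the stitching range, placed > ``stitch_gap`` away from everything else,
    at ``enrichment_ratio`` x the typical per-bp ChIP density.  The input
    track is a flat ``background`` density with Poisson jitter on 10-kb
    bins.  Truth marks each planted stitched region and whether it is super.
    """
    if enrichment_ratio <= 0:
        raise ValueError("enrichment_ratio must be > 0")
    if peaks.genome is None:
        raise ValueError("peaks must carry a genome (chrom sizes)")
    rng = child_rng(seed, "se_signal")
    chrom_sizes = peaks.genome
    base_density = 5.0  # typical enhancer ChIP reads per bp, arbitrary units
    # find free slots for the clusters: reuse the slot grid, skipping slots
    # that collide with existing peaks (plus the stitching margin)
    slot_width = 2 * stitch_gap + 30_000
    all_slots = []
    for chrom in sorted(chrom_sizes):
        for i in range(chrom_sizes[chrom] // slot_width):
            all_slots.append((chrom, i * slot_width))
    occupied = []
    for chrom, s0 in all_slots:
        probe = GenomicInterval(chrom, max(s0 - stitch_gap, 0),
                                s0 + slot_width + stitch_gap)
        occupied.append(peaks.any_overlap(probe))
    free = [s for s, occ in zip(all_slots, occupied) if not occ]
    if se_clusters > len(free):
        raise ValueError("not enough free genome to place SE clusters")
    chosen = [free[i] for i in sorted(rng.choice(len(free), size=se_clusters,
                                                 replace=False))]
    cluster_peaks: list[GenomicInterval] = []
    truth_rows = []
    for ci, (chrom, s0) in enumerate(chosen):
        n_const = int(rng.integers(3, 7))
        pos = s0 + stitch_gap
        members = []
        for _ in range(n_const):
            w = int(rng.integers(500, 1_501))
            members.append(GenomicInterval(chrom, pos, pos + w,
                                           name=f"SE{ci+1:02d}"))
            pos += w + int(rng.integers(500, 3_001))
        cluster_peaks.extend(members)
        truth_rows.append({"chrom": chrom, "start": members[0].start,
                           "end": members[-1].end, "is_super": True,
                           "n_constituents": n_const})
    all_peaks = IntervalSet(list(peaks) + cluster_peaks, genome=chrom_sizes)
    for p in peaks:
        truth_rows.append({"chrom": p.chrom, "start": p.start, "end": p.end,
                           "is_super": False, "n_constituents": 1})
    truth = pd.DataFrame(truth_rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    chip_entries = []
    for p in all_peaks:
        dens = base_density * float(rng.lognormal(0.0, 0.25))
        if p.name and p.name.startswith("SE"):
            dens *= enrichment_ratio
        chip_entries.append((p.chrom, p.start, p.end, dens))
    input_entries = []
    if background > 0:
        bin_w = 10_000
        for chrom in sorted(chrom_sizes):
            n_bins = chrom_sizes[chrom] // bin_w
            lam = background * bin_w
            vals = rng.poisson(lam, size=n_bins) / bin_w
            for i, v in enumerate(vals):
                if v > 0:
                    input_entries.append((chrom, i * bin_w, (i + 1) * bin_w, float(v)))
    chip = SignalTrack.from_intervals(chip_entries)
    chip.total_reads = max(int(round(chip.total_signal)), 1)
    inp = SignalTrack.from_intervals(input_entries) if input_entries else \
        SignalTrack({}, total_reads=1)
    if input_entries:
        inp.total_reads = max(int(round(inp.total_signal)), 1)
    return SimulatedSESignal(all_peaks, chip, inp, truth)


# ---------------------------------------------------------------------------
# chromatin-state marks
# ---------------------------------------------------------------------------

@dataclass
class SimulatedMarks:
    regions: IntervalSet
    k4me1: IntervalSet
    k4me3: IntervalSet
    k27ac: IntervalSet
    truth: pd.DataFrame  # per region: planted state


DEFAULT_STATE_MIX = {"active_enhancer": 0.45, "poised_enhancer": 0.25,
                     "promoter_like": 0.15, "unmarked": 0.15}

_STATE_FLAGS = {
    "active_enhancer": (True, False, True),
    "poised_enhancer": (True, False, False),
    "promoter_like": (False, True, False),
    "unmarked": (False, False, False),
}


def simulate_state_marks(regions: IntervalSet,
                         state_mix: Optional[dict[str, float]] = None,
                         seed: int = 0) -> SimulatedMarks:
    """Draw a chromatin state per region and emit consistent mark peak sets.

    A mark peak covering the region center is emitted for every mark the
    planted state requires; absent marks get no peak near the region.
    """
    rng = child_rng(seed, "marks")
    mix = state_mix or DEFAULT_STATE_MIX
    names = sorted(mix)
    p = np.array([mix[s] for s in names], dtype=float)
    p = p / p.sum()
    k4me1, k4me3, k27ac = [], [], []
    rows = []
    for r in regions:
        state = names[rng.choice(len(names), p=p)]
        f1, f3, fa = _STATE_FLAGS[state]
        mid = r.midpoint
        half = max(len(r) // 4, 50)
        mark_iv = GenomicInterval(r.chrom, max(mid - half, 0), mid + half)
        if f1:
            k4me1.append(mark_iv)
        if f3:
            k4me3.append(mark_iv)
        if fa:
            k27ac.append(mark_iv)
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "state": state})
    return SimulatedMarks(regions, IntervalSet(k4me1), IntervalSet(k4me3),
                          IntervalSet(k27ac), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    matrix: CountMatrix
    collection: GeneSetCollection
    gene_truth: pd.DataFrame   # gene_id, true_lfc, is_de
    set_truth: pd.DataFrame    # set, planted, direction
    size_factors_true: pd.Series


def simulate_counts(n_genes: int = 2000, n_per_group: int = 10,
                    frac_de: float = 0.1, lfc_value: float = 2.0,
                    dispersion: float = 0.1,
                    lib_size_range: tuple[float, float] = (0.7, 1.4),
                    enriched_sets: int = 3, decoy_sets: int = 10,
                    set_size: int = 50, seed: int = 0,
                    groups: tuple[str, str] = ("WT", "dHET"),
                    biotype_mix: Optional[dict[str, float]] = None
                    ) -> SimulatedCounts:
    """NB count matrix with planted log2 fold changes and enriched gene sets.

    Counts ~ NB(mean = baseline x size_factor x 2^(LFC x group2), dispersion)
    with baselines log-normal around ~90 normalized counts.  A ``frac_de``
    share of genes get |LFC| = ``lfc_value`` with random sign.  Planted
    enriched sets draw 80% of members from same-direction DE genes; decoy
    sets are uniform random.  Gene biotypes default to protein_coding; pass a
    mix including rRNA/miRNA/pseudogene classes to exercise gene filters
    (those classes are never planted as DE).
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    rng = child_rng(seed, "counts")
    g1, g2 = groups
    gene_ids = [f"g{i+1:05d}" for i in range(n_genes)]
    baseline = np.exp(rng.normal(4.5, 1.0, size=n_genes)).clip(2.0, 5000.0)
    mix = biotype_mix or {"protein_coding": 1.0}
    bt_names = sorted(mix)
    bt_p = np.array([mix[b] for b in bt_names], dtype=float)
    bt_p = bt_p / bt_p.sum()
    biotypes = [bt_names[i] for i in rng.choice(len(bt_names), size=n_genes, p=bt_p)]
    pc = np.array([b == "protein_coding" for b in biotypes])
    lfc = np.zeros(n_genes)
    n_de = int(round(frac_de * n_genes))
    candidates = np.flatnonzero(pc) if pc.any() else np.arange(n_genes)
    if n_de > len(candidates):
        n_de = len(candidates)
    de_idx = rng.choice(candidates, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * lfc_value

    samples = [f"{g1}_{j+1}" for j in range(n_per_group)] + \
              [f"{g2}_{j+1}" for j in range(n_per_group)]
    group_of = {s: (g1 if s.startswith(g1 + "_") else g2) for s in samples}
    sf = rng.uniform(lib_size_range[0], lib_size_range[1], size=2 * n_per_group)
    is_g2 = np.array([group_of[s] == g2 for s in samples], dtype=float)
    mu = baseline[:, None] * sf[None, :] * (2.0 ** (lfc[:, None] * is_g2[None, :]))
    r = 1.0 / max(dispersion, 1e-8)
    p_nb = r / (r + mu)
    counts = rng.negative_binomial(r, p_nb)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    genes_df = pd.DataFrame({
        "symbol": [g.upper() for g in gene_ids],
        "biotype": biotypes,
        "chrom": ["chr1"] * n_genes,
        "length": rng.integers(500, 5001, size=n_genes),
    }, index=pd.Index(gene_ids, name="gene_id"))
    cm = CountMatrix(counts_df, genes_df, group_of)

    up_pool = [gene_ids[i] for i in de_idx[signs > 0]]
    down_pool = [gene_ids[i] for i in de_idx[signs < 0]]
    non_de = [g for i, g in enumerate(gene_ids) if lfc[i] == 0]
    sets, set_rows = [], []
    for si in range(enriched_sets):
        direction = "up" if si % 2 == 0 else "down"
        pool = up_pool if direction == "up" else down_pool
        n_sig = min(int(round(0.8 * set_size)), len(pool))
        members = list(rng.choice(pool, size=n_sig, replace=False)) + \
            list(rng.choice(non_de, size=set_size - n_sig, replace=False))
        name = f"planted_{direction}_{si+1}"
        sets.append(GeneSet(name, frozenset(members)))
        set_rows.append({"set": name, "planted": True, "direction": direction})
    for si in range(decoy_sets):
        members = list(rng.choice(gene_ids, size=set_size, replace=False))
        name = f"decoy_{si+1}"
        sets.append(GeneSet(name, frozenset(members)))
        set_rows.append({"set": name, "planted": False, "direction": "none"})

    gene_truth = pd.DataFrame({"gene_id": gene_ids, "true_lfc": lfc,
                               "is_de": lfc != 0})
    return SimulatedCounts(cm, GeneSetCollection(sets), gene_truth,
                           pd.DataFrame(set_rows),
                           pd.Series(sf, index=samples, name="size_factor"))
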