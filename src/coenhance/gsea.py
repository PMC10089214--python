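"""Preranked gene-set enrichment analysis (weighted Kolmogorov-Smirnov).

Given a ranked gene list (descending score) and a gene set, the running sum
increments by |score|^p / sum_hits |score|^p at each set member ("hit") and
decrements by 1/(N - N_hits) at each non-member.  The enrichment score ES is
the running-sum value of maximal absolute deviation from zero (sign kept);
the leading edge is the hits at or before the positive extremum (at or after
the negative one).  Significance comes from a gene-label permutation null:
size-matched random sets drawn from the ranking.  NES divides ES by the mean
|null ES| of the matching sign; the permutation p is the one-sided same-sign
tail fraction with add-one smoothing; FDR q follows the sign-stratified
ratio-of-tails scheme of the standard GSEA method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["RankedList", "GeneSet", "GeneSetCollection", "EnrichmentResult",
           "enrichment_score", "preranked_gsea", "run_signature_panel",
           "make_signature_sets", "read_gmt", "write_gmt",
           "read_ranked_tsv", "write_ranked_tsv"]


class RankedList:
    """Genes with scores, ordered by descending score (ties by gene name)."""

    def __init__(self, genes: Sequence[str], scores: Sequence[float]):
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("ranked genes must be unique")
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        self.genes = [genes[i] for i in order]
        self.scores = np.array([scores[i] for i in order], dtype=float)
        self.index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_de(cls, de_table: pd.DataFrame, metric: str = "wald") -> "RankedList":
        """Rank by a differential-expression statistic (default Wald z)."""
        return cls(list(de_table.index), list(de_table[metric]))


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))


class GeneSetCollection:
    def __init__(self, sets: Sequence[GeneSet] = ()):
        self.sets = list(sets)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            sets.append(GeneSet(f[0], frozenset(g for g in f[2:] if g)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write(s.name + "\t" + description + "\t" + "\t".join(sorted(s.genes)) + "\n")


def read_ranked_tsv(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return RankedList(list(df["gene"].astype(str)), list(df["score"].astype(float)))


def write_ranked_tsv(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_from_hits(hit_pos: np.ndarray, weights: np.ndarray, n_total: int
                  ) -> tuple[float, int]:
    """ES and extremum position from sorted hit positions and hit weights.

    ``weights`` are |score|^p at the hit positions (unnormalized).  The
    running sum only attains local extrema immediately after a hit (maxima
    candidates) or immediately before one / at the end (minima candidates),
    so only those points are evaluated.  Returns (ES, extremum position).
    Sign ties (|max| == |min|) resolve to the positive deviation.
    """
    k = len(hit_pos)
    miss_dec = 1.0 / (n_total - k)
    wsum = weights.sum()
    if wsum <= 0:  # all-zero scores at hits: fall back to unweighted hits
        w = np.full(k, 1.0 / k)
    else:
        w = weights / wsum
    cumw = np.cumsum(w)
    before = np.concatenate(([0.0], cumw[:-1])) - (hit_pos - np.arange(k)) * miss_dec
    after = cumw - (hit_pos - np.arange(k)) * miss_dec
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_max = after[i_max]
    es_min = before[i_min]
    # positive deviation wins ties (up to float noise in the cumsum)
    if es_max >= -es_min - 1e-12:
        return float(es_max), int(hit_pos[i_max])
    return float(es_min), int(hit_pos[i_min])


def enrichment_score(ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for one set.

    Returns (ES, full running-sum array, leading-edge gene list).  Errors if
    the set has no overlap with the ranking or covers it entirely.
    """
    n = len(ranked)
    hits = np.array(sorted(ranked.index[g] for g in gene_set.genes if g in ranked.index))
    if len(hits) == 0:
        raise ValueError(f"set {gene_set.name!r} has no overlap with the ranking")
    if len(hits) == n:
        raise ValueError(f"set {gene_set.name!r} covers the entire ranking")
    weights = np.abs(ranked.scores[hits]) ** weight_p
    es, ext_pos = _es_from_hits(hits, weights, n)
    # full running sum for plots / oracle checks
    running = np.empty(n)
    wsum = weights.sum()
    w_at = np.zeros(n)
    if wsum > 0:
        w_at[hits] = weights / wsum
    else:
        w_at[hits] = 1.0 / len(hits)
    miss = np.full(n, -1.0 / (n - len(hits)))
    miss[hits] = 0.0
    running = np.cumsum(w_at + miss)
    if es >= 0:
        leading = [ranked.genes[i] for i in hits if i <= ext_pos]
    else:
        leading = [ranked.genes[i] for i in hits if i >= ext_pos]
    return es, running, leading


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    q_fdr: float
    leading_edge: list[str]
    n_hits: int


def _null_es(ranked: RankedList, set_size: int, n_perm: int, weight_p: float,
             rng: np.random.Generator) -> np.ndarray:
    n = len(ranked)
    abs_scores = np.abs(ranked.scores) ** weight_p
    out = np.empty(n_perm)
    for b in range(n_perm):
        hits = np.sort(rng.choice(n, size=set_size, replace=False))
        out[b], _ = _es_from_hits(hits, abs_scores[hits], n)
    return out


def preranked_gsea(ranked: RankedList, collection: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0, weight_p: float = 1.0,
                   ) -> list[EnrichmentResult]:
    """Permutation GSEA over a collection; results ordered by descending NES.

    The null for each set is the ES of ``n_perm`` size-matched random gene
    sets drawn (seeded) from the ranking.  p = (b + 1) / (n_perm + 1) where b
    counts same-sign null ES at least as extreme; NES = ES / mean |same-sign
    null ES|; q is the ratio-of-tails FDR computed sign-stratified over the
    pooled null and observed NES.  Sets with no ranking overlap are skipped
    with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs: list[tuple[GeneSet, float, list[str], int]] = []
    null_by_set: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for gs in collection:
        overlap = sum(1 for g in gs.genes if g in ranked.index)
        if overlap == 0 or overlap == len(ranked):
            warnings.warn(f"set {gs.name!r}: no usable overlap; skipped")
            continue
        es, _, leading = enrichment_score(ranked, gs, weight_p)
        if overlap not in null_cache:
            null_cache[overlap] = _null_es(ranked, overlap, n_perm, weight_p, rng)
        obs.append((gs, es, leading, overlap))
        null_by_set.append(null_cache[overlap])

    # NES + permutation p per set
    nes_obs = np.empty(len(obs))
    p_perm = np.empty(len(obs))
    nes_null_all: list[np.ndarray] = []
    for i, ((gs, es, leading, k), null) in enumerate(zip(obs, null_by_set)):
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        if es >= 0:
            denom = mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else np.abs(null).mean()
        else:
            denom = mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else np.abs(null).mean()
        nes_obs[i] = es / denom
        # magnitude tail over the full null: uniform under the null and
        # attains 1/(n_perm+1) for a maximally enriched set
        b = int(np.sum(np.abs(null) >= abs(es)))
        p_perm[i] = (b + 1) / (n_perm + 1)
        # normalize the null the same way for the FDR pool
        nn = np.where(null >= 0,
                      null / (mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 1.0),
                      null / (mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 1.0))
        nes_null_all.append(nn)

    pool = np.concatenate(nes_null_all) if nes_null_all else np.zeros(0)
    results = []
    for i, (gs, es, leading, k) in enumerate(obs):
        nes = nes_obs[i]
        if nes >= 0:
            null_tail = np.mean(pool[pool >= 0] >= nes) if np.any(pool >= 0) else 0.0
            obs_tail = np.mean(nes_obs[nes_obs >= 0] >= nes)
        else:
            null_tail = np.mean(pool[pool < 0] <= nes) if np.any(pool < 0) else 0.0
            obs_tail = np.mean(nes_obs[nes_obs < 0] <= nes)
        q = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
        results.append(EnrichmentResult(gs.name, es, float(nes), float(p_perm[i]),
                                        float(q), leading, k))
    results.sort(key=lambda r: (-r.nes, r.name))
    return results


def run_signature_panel(ranked: RankedList, collection: GeneSetCollection,
                        alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
                        weight_p: float = 1.0) -> pd.DataFrame:
    """Score every signature in a panel; flag q < alpha with direction.

    Returns a tidy table (one row per set) suitable for overlay plotting.
    """
    res = preranked_gsea(ranked, collection, n_perm=n_perm, seed=seed,
                         weight_p=weight_p)
    rows = []
    for r in res:
        rows.append({
            "set": r.name, "es": r.es, "nes": r.nes, "p_perm": r.p_perm,
            "q_fdr": r.q_fdr, "n_hits": r.n_hits,
            "significant": r.q_fdr < alpha,
            "direction": "up" if r.nes >= 0 else "down",
            "leading_edge": ",".join(r.leading_edge),
        })
    return pd.DataFrame(rows)


def make_signature_sets(signature, up_name: Optional[str] = None,
                        down_name: Optional[str] = None) -> GeneSetCollection:
    """Wrap a differential-expression :class:`~coenhance.diffexpr.Signature`
    as two GMT-ready gene sets (skipping empty directions with a warning).
    """
    sets = []
    for direction, genes in (("up", signature.up), ("down", signature.down)):
        name = (up_name if direction == "up" else down_name) or \
            f"{signature.name}_{direction}"
        if not genes:
            warnings.warn(f"signature {signature.name!r} has no {direction} genes")
            continue
        sets.append(GeneSet(name, frozenset(genes)))
    return GeneSetCollection(sets)
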