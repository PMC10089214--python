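"""Interval data model, file formats, stitching, distances, annotation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from coenhance.intervals import (GeneModel, GenomicInterval, IntervalSet,
                                 UNREACHABLE, annotate_regions,
                                 assign_nearest_gene, nearest_distance,
                                 promoter_window, read_gene_models,
                                 read_intervals, stitch, top_genes_by_distance,
                                 write_gene_models_tsv, write_intervals)
from conftest import random_interval_set


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -5, 10)
    iv = GenomicInterval("chr1", 100, 200)
    assert len(iv) == 100 and iv.midpoint == 150


def test_interval_set_sorts_and_validates_genome():
    s = IntervalSet([GenomicInterval("chr1", 500, 600),
                     GenomicInterval("chr1", 100, 200)])
    assert [(i.start, i.end) for i in s] == [(100, 200), (500, 600)]
    with pytest.raises(ValueError):
        IntervalSet([GenomicInterval("chr1", 0, 2000)], genome={"chr1": 1000})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("content,dialect,expect", [
    ("chr1\t100\t200\n", "bed3", [("chr1", 100, 200, ".", None)]),
    ("chr1\t500\t600\nchr1\t100\t200\n", "bed3",
     [("chr1", 100, 200, ".", None), ("chr1", 500, 600, ".", None)]),
    ("chr1\t10\t20\tpk1\t0\t+\t7.5\t-1\t-1\t5\n", "narrowpeak",
     [("chr1", 10, 20, "+", 7.5)]),
])
def test_read_intervals_dialects(tmp_path, content, dialect, expect):
    p = tmp_path / "x.bed"
    p.write_text(content)
    got = [(i.chrom, i.start, i.end, i.strand, i.score)
           for i in read_intervals(p, dialect)]
    assert got == expect


def test_read_intervals_errors_name_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t100\t200\nchr1\t300\tnope\n")
    with pytest.raises(ValueError, match="line 2"):
        read_intervals(p, "bed3")
    p.write_text("chr1\t200\t100\n")
    with pytest.raises(ValueError, match="line 1"):
        read_intervals(p, "bed3")


@pytest.mark.parametrize("dialect", ["bed3", "bed6", "narrowpeak"])
def test_interval_roundtrip_exact(tmp_path, rng, dialect):
    s = random_interval_set(rng, 50)
    path = tmp_path / "rt.bed"
    write_intervals(s, path, dialect)
    back = read_intervals(path, dialect)
    assert [(i.chrom, i.start, i.end) for i in back] == \
           [(i.chrom, i.start, i.end) for i in s]


def test_read_gtf_coordinates_and_exon_union(tmp_path):
    gtf = (
        'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gA"; gene_name "A";\n'
        'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "gA";\n'
        'chr1\tsrc\texon\t1901\t2000\t.\t+\t.\tgene_id "gA";\n'
    )
    p = tmp_path / "x.gtf"
    p.write_text(gtf)
    (g,) = read_gene_models(p, "gtf")
    assert (g.tx_start, g.tx_end, g.tss) == (1000, 2000, 1000)
    assert g.length == 200  # union of two 100-bp exons


def test_minus_strand_tss():
    g = GeneModel("g1", "G1", "chr1", "-", 1000, 2000)
    assert g.tss == 1999


def test_gene_tsv_roundtrip(tmp_path):
    genes = [GeneModel("g1", "G1", "chr1", "+", 100, 5000, "protein_coding", 900),
             GeneModel("g2", "G2", "chr2", "-", 200, 9000, "rRNA", 1200)]
    p = tmp_path / "genes.tsv"
    write_gene_models_tsv(genes, p)
    assert read_gene_models(p, "tsv") == sorted(
        genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id))


# ---------------------------------------------------------------------------
# stitch
# ---------------------------------------------------------------------------

def test_stitch_gap_examples():
    s = IntervalSet([GenomicInterval("chr1", 100, 200),
                     GenomicInterval("chr1", 5000, 5100),
                     GenomicInterval("chr1", 20000, 20100)])
    out = stitch(s, 12_500)  # gaps: 4800 (merge) and 14900 (keep)
    assert [(i.start, i.end, i.score) for i in out] == \
        [(100, 5100, 2), (20000, 20100, 1)]
    assert len(stitch(IntervalSet([]), 100)) == 0
    touching = IntervalSet([GenomicInterval("chr1", 100, 200),
                            GenomicInterval("chr1", 200, 300)])
    assert [(i.start, i.end) for i in stitch(touching, 0)] == [(100, 300)]


def brute_force_stitch(intervals, max_gap):
    """All-pairs transitive merger (union-find), the independent oracle."""
    ivs = list(intervals)
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[i].distance_to(ivs[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    out = sorted(
        ((g[0].chrom, min(x.start for x in g), max(x.end for x in g), len(g))
         for g in groups.values()))
    return out


def test_stitch_matches_bruteforce(rng):
    for _ in range(50):
        s = random_interval_set(rng, int(rng.integers(0, 60)), span=20_000)
        gap = int(rng.integers(0, 3000))
        got = [(i.chrom, i.start, i.end, int(i.score)) for i in stitch(s, gap)]
        assert got == brute_force_stitch(s, gap)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 300)), max_size=40),
       st.integers(0, 500))
def test_stitch_idempotent_and_conservative(spec, gap):
    s = IntervalSet([GenomicInterval("chr1", a, a + w) for a, w in spec])
    once = stitch(s, gap)
    twice = stitch(once, gap)
    assert [(i.start, i.end) for i in once] == [(i.start, i.end) for i in twice]
    assert len(once) <= len(s)
    covered = [(i.start, i.end) for i in once]
    for iv in s:  # every input base inside some output interval
        assert any(a <= iv.start and iv.end <= b for a, b in covered)


# ---------------------------------------------------------------------------
# nearest distance
# ---------------------------------------------------------------------------

def test_nearest_distance_examples():
    q = IntervalSet([GenomicInterval("chr1", 1000, 1100)])
    assert nearest_distance(q, IntervalSet([GenomicInterval("chr1", 1150, 1250)]))[0].distance == 50
    assert nearest_distance(q, IntervalSet([GenomicInterval("chr1", 1050, 1250)]))[0].distance == 0
    far = nearest_distance(IntervalSet([GenomicInterval("chr2", 0, 10)]),
                           IntervalSet([GenomicInterval("chr1", 0, 10)]))
    assert far[0].distance == UNREACHABLE and far[0].nearest is None


def test_nearest_distance_matches_bruteforce(rng):
    for _ in range(20):
        q = random_interval_set(rng, int(rng.integers(1, 200)), span=50_000)
        s = random_interval_set(rng, int(rng.integers(1, 200)), span=50_000)
        got = nearest_distance(q, s)
        for hit in got:
            brute = min((hit.query.distance_to(x) for x in s), default=UNREACHABLE)
            assert hit.distance == brute


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@pytest.fixture
def one_gene():
    return [GeneModel("gA", "A", "chr1", "+", 10_000, 15_000)]


@pytest.mark.parametrize("start,end,expect", [
    (8_500, 8_600, "tss_proximal"),   # inside [TSS-2000, TSS+1000)
    (12_000, 12_100, "intragenic"),   # gene body, outside promoter
    (50_000, 50_100, "intergenic"),
])
def test_annotate_regions_categories(one_gene, start, end, expect):
    regions = IntervalSet([GenomicInterval("chr1", start, end)])
    assert annotate_regions(regions, one_gene) == [expect]


def test_annotate_minus_strand_promoter_is_mirrored():
    gene = [GeneModel("gB", "B", "chr1", "-", 10_000, 15_000)]  # TSS 14999
    win = promoter_window(gene[0])
    assert win.start == 14_999 - 1000 + 1 and win.end == 14_999 + 2000 + 1
    upstream_region = IntervalSet([GenomicInterval("chr1", 16_500, 16_600)])
    assert annotate_regions(upstream_region, gene) == ["tss_proximal"]


def test_annotate_partitions_regions(rng, one_gene):
    regions = random_interval_set(rng, 100, chroms=("chr1",), span=60_000)
    cats = annotate_regions(regions, one_gene)
    assert len(cats) == len(regions)
    assert set(cats) <= {"tss_proximal", "intragenic", "intergenic"}


# ---------------------------------------------------------------------------
# nearest gene assignment
# ---------------------------------------------------------------------------

def test_assign_nearest_gene_rank_and_ties():
    genes = [GeneModel("ga", "a", "chr1", "+", 10_000, 12_000),
             GeneModel("gb", "b", "chr1", "+", 30_000, 32_000)]
    region = IntervalSet([GenomicInterval("chr1", 10_000, 10_100)])  # midpoint 10050
    (per_region,) = assign_nearest_gene(region, genes, k=2)
    assert per_region[0].gene.gene_id == "ga" and per_region[0].distance == 50
    # equidistant TSSs: lexicographic gene_id wins
    tie_genes = [GeneModel("gz", "z", "chr1", "+", 9_000, 9_500),
                 GeneModel("ga", "a", "chr1", "+", 11_000, 11_500)]
    region = IntervalSet([GenomicInterval("chr1", 9_950, 10_050)])  # midpoint 10000
    (pr,) = assign_nearest_gene(region, tie_genes, k=1)
    assert pr[0].gene.gene_id == "ga"
    # k beyond gene count returns everything
    (pr,) = assign_nearest_gene(region, tie_genes, k=10)
    assert len(pr) == 2


def test_top_genes_by_distance_dedups():
    genes = [GeneModel("ga", "a", "chr1", "+", 1_000, 2_000),
             GeneModel("gb", "b", "chr1", "+", 50_000, 51_000)]
    regions = IntervalSet([GenomicInterval("chr1", 900, 1_100),
                           GenomicInterval("chr1", 1_100, 1_300)])
    ass = assign_nearest_gene(regions, genes, k=2)
    assert top_genes_by_distance(ass, 1) == ["ga"]
    assert top_genes_by_distance(ass, 5) == ["ga", "gb"]
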