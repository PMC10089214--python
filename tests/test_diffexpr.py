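"""Gene filters, TPM, size factors, NB Wald test, BH, clustering, orthologs."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from coenhance.diffexpr import (CountMatrix, FilterRules, bh_adjust, call_de,
                                cluster_samples, filter_genes, map_orthologs,
                                nb_wald_test, size_factors, tpm_normalize)


def toy_matrix(counts, biotypes=None, chroms=None, lengths=None, groups=None):
    counts = pd.DataFrame(counts)
    n = len(counts)
    genes = pd.DataFrame({
        "symbol": counts.index,
        "biotype": biotypes or ["protein_coding"] * n,
        "chrom": chroms or ["chr1"] * n,
        "length": lengths or [1000] * n,
    }, index=counts.index)
    return CountMatrix(counts, genes, groups or {})


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_filter_by_biotype_chrom_and_id():
    cm = toy_matrix(
        {"s1": [1, 2, 3, 4, 5]},
        biotypes=["protein_coding", "rRNA", "protein_coding",
                  "protein_coding", "protein_coding"],
        chroms=["chr1", "chr1", "chrY", "chr1", "chr1"],
    )
    cm.counts.index = ["a", "b", "c", "d", "e"]
    cm.genes.index = ["a", "b", "c", "d", "e"]
    rules = FilterRules(biotypes=frozenset({"rRNA"}),
                        chroms=frozenset({"chrY"}),
                        gene_ids=frozenset({"d"}))
    out, report = filter_genes(cm, rules)
    assert list(out.counts.index) == ["a", "e"]
    assert report == {"rRNA": 1, "chrY": 1, "gene_id_list": 1}


def test_empty_rules_identity():
    cm = toy_matrix({"s1": [1, 2]})
    out, report = filter_genes(cm, FilterRules())
    assert list(out.counts.index) == list(cm.counts.index)
    assert report == {}


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_closed_form():
    cm = toy_matrix({"s1": [10, 10]}, lengths=[1000, 2000])
    tpm = tpm_normalize(cm)
    assert tpm["s1"].tolist() == pytest.approx([2e6 / 3, 1e6 / 3])


def test_tpm_single_gene_and_zero_sample():
    cm = toy_matrix({"s1": [7]})
    assert tpm_normalize(cm)["s1"].iloc[0] == 1e6
    cm = toy_matrix({"s1": [0, 0]})
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = tpm_normalize(cm)
    assert (tpm["s1"] == 0).all()


def test_tpm_columns_sum_to_1e6(rng):
    counts = rng.integers(0, 500, size=(200, 4))
    counts[0] += 1  # keep every sample nonzero
    cm = toy_matrix(pd.DataFrame(counts, columns=list("abcd")),
                    lengths=list(rng.integers(200, 5000, size=200)))
    tpm = tpm_normalize(cm)
    assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)


def test_tpm_zero_length_errors():
    cm = toy_matrix({"s1": [1]}, lengths=[0])
    with pytest.raises(ValueError):
        tpm_normalize(cm)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_hand_example():
    cm = toy_matrix({"s1": [2, 2, 2], "s2": [4, 4, 4]})
    f = size_factors(cm)
    assert f["s1"] == pytest.approx(2 / np.sqrt(8))
    assert f["s2"] == pytest.approx(4 / np.sqrt(8))


def test_size_factors_recover_scaling(rng):
    base = rng.integers(5, 200, size=100)
    cm = toy_matrix(pd.DataFrame({"s1": base, "s2": base * 2}))
    f = size_factors(cm)
    assert f["s2"] / f["s1"] == pytest.approx(2.0)
    ident = toy_matrix(pd.DataFrame({"a": base, "b": base}))
    fi = size_factors(ident)
    assert fi["a"] == pytest.approx(fi["b"])


def test_size_factors_need_common_nonzero_gene():
    cm = toy_matrix({"s1": [0, 5], "s2": [5, 0]})
    with pytest.raises(ValueError, match="pseudocount"):
        size_factors(cm)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def two_group_matrix(rng, n_genes=50, n=4, lfc=0.0, mean=100.0, disp=0.1,
                     frac_de=1.0):
    """Two-group NB counts; ``frac_de`` of genes carry the planted LFC with
    alternating signs (sign balance keeps median-of-ratios size factors free
    of composition bias, as in the study-condition generator).
    """
    mu1 = np.full(n_genes, mean)
    lfc_vec = np.zeros(n_genes)
    n_de = int(round(frac_de * n_genes))
    lfc_vec[:n_de] = lfc * np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    mu2 = mu1 * 2.0 ** lfc_vec
    r = 1.0 / disp
    g1 = rng.negative_binomial(r, r / (r + mu1[:, None]), size=(n_genes, n))
    g2 = rng.negative_binomial(r, r / (r + mu2[:, None]), size=(n_genes, n))
    cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    counts = pd.DataFrame(np.hstack([g1, g2]), columns=cols)
    groups = {c: ("A" if c.startswith("A") else "B") for c in cols}
    return toy_matrix(counts, groups=groups)


def test_identical_groups_null_identity():
    vals = np.array([[10, 20, 30, 10, 20, 30]] * 5)
    counts = pd.DataFrame(vals, columns=["A0", "A1", "A2", "B0", "B1", "B2"])
    cm = toy_matrix(counts, groups={c: c[0] for c in counts.columns})
    de = nb_wald_test(cm, "A", "B")
    assert np.allclose(de.table["log2_fc"], 0.0)
    assert (de.table["p"] > 0.9).all()


def test_planted_lfc_recovered(rng):
    cm = two_group_matrix(rng, n_genes=200, n=10, lfc=2.0, frac_de=0.2)
    de = nb_wald_test(cm, "A", "B")
    signs = np.where(np.arange(40) % 2 == 0, 1.0, -1.0)
    planted = de.table["log2_fc"].iloc[:40] * signs
    assert abs(planted.mean() - 2.0) < 0.2
    assert abs(de.table["log2_fc"].iloc[40:].mean()) < 0.1


def test_group_size_guard():
    counts = pd.DataFrame({"A0": [1], "A1": [2], "B0": [3]})
    cm = toy_matrix(counts, groups={c: c[0] for c in counts.columns})
    with pytest.raises(ValueError, match=">= 2 samples"):
        nb_wald_test(cm, "A", "B")


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_hand_examples():
    assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.2]).tolist() == [0.2]
    assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_bruteforce_and_statsmodels(rng):
    for _ in range(10):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 200)))
        q = bh_adjust(p)
        assert q.tolist() == pytest.approx(brute_force_bh(list(p)), abs=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)


def test_bh_monotone_in_inputs(rng):
    p = rng.uniform(0, 1, size=50)
    q = bh_adjust(p)
    p2 = p.copy()
    i = int(rng.integers(50))
    p2[i] = min(1.0, p2[i] + 0.2)
    q2 = bh_adjust(p2)
    assert (q2 >= q - 1e-12).all()


# ---------------------------------------------------------------------------
# signature calling
# ---------------------------------------------------------------------------

def fake_de(qs, lfcs):
    idx = [f"g{i}" for i in range(len(qs))]
    table = pd.DataFrame({"base_mean": 100.0, "log2_fc": lfcs, "se": 0.1,
                          "wald": 1.0, "p": qs, "q": qs, "zero_group": 0},
                         index=idx)
    from coenhance.diffexpr import DEResult
    return DEResult(table, "A", "B")


def test_call_de_thresholds():
    de = fake_de([0.01, 0.01, 0.06], [np.log2(1.5), np.log2(1.1), np.log2(3.0)])
    sig = call_de(de, fdr=0.05, min_fc=1.2)
    assert sig.up == ["g0"] and sig.down == []


def test_call_de_direction_split():
    de = fake_de([0.01, 0.01, 0.01], [1.0, -1.0, -2.0])
    sig = call_de(de)
    assert sig.up == ["g0"] and sig.down == ["g1", "g2"]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def brute_force_upgma(dist):
    """Exhaustive agglomeration oracle returning the merge order."""
    clusters = {i: [i] for i in range(len(dist))}
    d = {(i, j): dist[i][j] for i in clusters for j in clusters if i < j}
    merges = []
    next_id = len(dist)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((sorted(clusters[i] + clusters[j]), h))
        merged = clusters[i] + clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        del clusters[i], clusters[j]
        newd = {}
        for (a, b), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            newd[(a, b)] = v
        for k in clusters:
            da = dist_lookup(d, k, i)
            db = dist_lookup(d, k, j)
            newd[tuple(sorted((k, next_id)))] = (ni * da + nj * db) / (ni + nj)
        clusters[next_id] = merged
        d = newd
        next_id += 1
    return merges


def dist_lookup(d, a, b):
    return d[tuple(sorted((a, b)))]


def test_cluster_examples_and_oracle():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.normal(0, 1, size=(30, 4)),
                        columns=["w1", "w2", "m1", "m2"])
    expr["w2"] = expr["w1"]  # duplicated sample merges first
    res = cluster_samples(expr, top_n=30)
    first_pair = sorted(res.linkage_matrix[0, :2].astype(int))
    assert [expr.columns[i] for i in first_pair] == ["w1", "w2"]
    assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
    # merge heights match the brute-force agglomeration oracle
    sub = expr.loc[res.genes_used]
    dist = 1 - np.corrcoef(sub.to_numpy().T)
    np.fill_diagonal(dist, 0)
    merges = brute_force_upgma(dist.tolist())
    assert np.allclose(sorted(m[1] for m in merges),
                       sorted(res.linkage_matrix[:, 2]), atol=1e-10)


def test_anticorrelated_distance_is_two():
    expr = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
    res = cluster_samples(expr, top_n=4)
    assert res.linkage_matrix[0, 2] == pytest.approx(2.0)


def test_cluster_needs_two_samples():
    with pytest.raises(ValueError):
        cluster_samples(pd.DataFrame({"a": [1.0, 2.0]}))


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

def test_map_orthologs_policies():
    mapping = pd.DataFrame({"mouse": ["Cd74", "Fyn", "Dup", "Dup"],
                            "human": ["CD74", "FYN", "D1", "D2"]})
    mapped, unmapped = map_orthologs(["Cd74", "Missing"], mapping)
    assert mapped == ["CD74"] and unmapped == ["Missing"]
    mapped, _ = map_orthologs(["Dup"], mapping, policy="keep_all")
    assert mapped == ["D1", "D2"]
    mapped, _ = map_orthologs(["Dup"], mapping, policy="first")
    assert mapped == ["D1"]
    # dedup preserves first occurrence
    mapped, _ = map_orthologs(["Cd74", "Cd74", "Fyn"], mapping)
    assert mapped == ["CD74", "FYN"]
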