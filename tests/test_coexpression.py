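"""Gene association, dendrograms, SIMPROF-style collapse, cluster reports."""

import numpy as np
import pandas as pd
import pytest

import phagestate as ps
from phagestate.containers import DataError
from tests.conftest import expression_from_array


def _planted_blocks(n_genes=150, n_samples=33, rho=0.8, n_blocks=3, seed=0):
    """Equi-correlated blocks: gene = sqrt(rho)*factor + sqrt(1-rho)*noise."""
    rng = np.random.default_rng(seed)
    sizes = [n_genes // n_blocks] * n_blocks
    sizes[-1] += n_genes - sum(sizes)
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
            labels.append(b)
    return np.array(rows), np.array(labels)


def test_association_diagonal_and_antipodal():
    x = np.array([[1.0, 2.0, 3.0, 4.0], [-1.0, -2.0, -3.0, -4.0], [4.0, 1.0, 3.0, 2.0]])
    assoc = ps.gene_association(expression_from_array(x))
    assert assoc.rho.iloc[0, 0] == pytest.approx(1.0)
    assert assoc.distance.iloc[0, 0] == 0.0
    assert assoc.rho.iloc[0, 1] == pytest.approx(-1.0)
    assert assoc.distance.iloc[0, 1] == pytest.approx(2.0)


def test_zero_variance_genes_dropped():
    x = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]])
    assoc = ps.gene_association(expression_from_array(x))
    assert assoc.dropped_genes == ["g000"]
    assert list(assoc.rho.index) == ["g001", "g002"]


def test_association_type_one_error_near_nominal():
    """Independent-noise null: fraction of pairs with p <= 0.1 ~ 0.1."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((200, 33))
    assoc = ps.gene_association(expression_from_array(x))
    iu = np.triu_indices(200, k=1)
    frac = float((assoc.p.to_numpy()[iu] <= 0.1).mean())
    assert 0.07 <= frac <= 0.13


def test_perfectly_correlated_pair_merges_first():
    x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 1.0, 3.0, 2.0]])
    assoc = ps.gene_association(expression_from_array(x))
    dend = ps.cluster_genes(assoc)
    # first merge joins the two perfectly correlated genes at height 0
    first = dend.linkage[0]
    merged = {dend.gene_ids[int(first[0])], dend.gene_ids[int(first[1])]}
    assert merged == {"g000", "g001"}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_merge_structure_invariant_to_gene_order():
    x, _ = _planted_blocks(n_genes=30, n_samples=20, seed=2)
    em = expression_from_array(x)
    d1 = ps.cluster_genes(ps.gene_association(em))
    perm = np.random.default_rng(0).permutation(30)
    em2 = ps.ExpressionMatrix(values=em.values.iloc[perm])
    d2 = ps.cluster_genes(ps.gene_association(em2))
    assert d1.gene_ids == d2.gene_ids
    assert np.allclose(d1.linkage, d2.linkage)


def test_planted_block_recovery_at_k3():
    from sklearn.metrics import adjusted_rand_score

    x, labels = _planted_blocks(seed=3)
    em = expression_from_array(x)
    dend = ps.cluster_genes(ps.gene_association(em))
    cut = dend.cut(3)
    ari = adjusted_rand_score(labels, cut.to_numpy())
    assert ari >= 0.9


def test_newick_export_parses(tmp_path):
    import skbio

    x, _ = _planted_blocks(n_genes=12, n_samples=15, seed=4)
    dend = ps.cluster_genes(ps.gene_association(expression_from_array(x)))
    path = tmp_path / "tree.nwk"
    dend.write_newick(path)
    tree = skbio.TreeNode.read(str(path))
    assert {t.name for t in tree.tips()} == set(dend.gene_ids)


def test_collapse_requires_enough_permutations():
    x, _ = _planted_blocks(n_genes=6, n_samples=10, seed=5)
    em = expression_from_array(x)
    dend = ps.cluster_genes(ps.gene_association(em))
    with pytest.raises(DataError):
        ps.collapse_indistinguishable(dend, em, n_perm=50)


def test_collapse_homogeneous_and_heterogeneous_nodes():
    """Copies-plus-noise collapse; anti-correlated block mixtures split."""
    rng = np.random.default_rng(6)
    n = 33
    sig = rng.standard_normal(n)
    homo = np.array([0.9 * sig + 0.44 * rng.standard_normal(n) for _ in range(8)])
    em = expression_from_array(homo)
    dend = ps.cluster_genes(ps.gene_association(em))
    groups = ps.collapse_indistinguishable(dend, em, alpha=0.05, n_perm=999, seed=0)
    assert groups == [sorted(em.values.index)]

    f = rng.standard_normal(n)
    hetero = np.vstack(
        [
            [0.9 * f + 0.44 * rng.standard_normal(n) for _ in range(4)],
            [-0.9 * f + 0.44 * rng.standard_normal(n) for _ in range(4)],
        ]
    )
    em2 = expression_from_array(hetero)
    dend2 = ps.cluster_genes(ps.gene_association(em2))
    groups2 = ps.collapse_indistinguishable(dend2, em2, alpha=0.05, n_perm=999, seed=0)
    assert all(len(g) <= 4 for g in groups2)
    blocks = [{f"g{i:03d}" for i in range(4)}, {f"g{i:03d}" for i in range(4, 8)}]
    for g in groups2:
        if len(g) > 1:
            assert set(g) <= blocks[0] or set(g) <= blocks[1]


def test_collapse_alpha_extremes():
    rng = np.random.default_rng(7)
    em = expression_from_array(rng.standard_normal((10, 20)))
    dend = ps.cluster_genes(ps.gene_association(em))
    root = ps.collapse_indistinguishable(dend, em, alpha=0.0, n_perm=99, seed=0)
    assert len(root) == 1 and len(root[0]) == 10  # never reject: root collapses
    leaves = ps.collapse_indistinguishable(dend, em, alpha=1.0, n_perm=99, seed=0)
    assert all(len(g) == 1 for g in leaves)  # always reject: all singletons


def test_collapse_is_hierarchical_partition(study_scale_dataset):
    """Collapsed groups partition the genes: disjoint and covering."""
    _, models, _, counts = study_scale_dataset
    phage = [g.gene_id for g in models if g.genome_id == "phage_MaLMM01like"]
    em = ps.log2_shift_matrix(ps.libsize_normalize(counts))
    em.values = em.values.loc[phage]
    assoc = ps.gene_association(em)
    dend = ps.cluster_genes(assoc)
    groups = ps.collapse_indistinguishable(dend, em, alpha=0.05, n_perm=199, seed=0)
    flat = [g for grp in groups for g in grp]
    assert sorted(flat) == sorted(assoc.rho.index)


def test_collapse_under_global_null_mostly_collapses():
    """Homogeneity is the null: under independence most non-singleton
    structure is retained as collapsed groups (few false splits)."""
    rng = np.random.default_rng(8)
    splits = 0
    for r in range(20):
        em = expression_from_array(rng.standard_normal((12, 25)))
        dend = ps.cluster_genes(ps.gene_association(em))
        groups = ps.collapse_indistinguishable(
            dend, em, alpha=0.05, n_perm=199, seed=r
        )
        splits += len(groups) > 1
    assert splits <= 5  # root-level false-split rate ~ alpha


def test_summarize_clusters_reports_markers(study_scale_dataset):
    _, models, truth, counts = study_scale_dataset
    phage = [g.gene_id for g in models if g.genome_id == "phage_MaLMM01like"]
    em = ps.log2_shift_matrix(ps.libsize_normalize(counts))
    em.values = em.values.loc[phage]
    assoc = ps.gene_association(em)
    dend = ps.cluster_genes(assoc)
    rep = ps.summarize_clusters(dend, assoc, k=3)
    assert rep["n_genes"].sum() == len(phage)
    all_markers = ",".join(rep["markers"])
    for m in ("gp091", "gp135", "gp136"):
        assert m in all_markers
    # lysogeny markers never share a cluster with the lytic marker
    for _, row in rep.iterrows():
        ms = set(row["markers"].split(",")) - {""}
        assert not ({"gp091"} <= ms and ({"gp135"} <= ms or {"gp136"} <= ms))


def test_summarize_k1_single_cluster():
    x, _ = _planted_blocks(n_genes=9, n_samples=12, seed=9)
    assoc = ps.gene_association(expression_from_array(x))
    dend = ps.cluster_genes(assoc)
    rep = ps.summarize_clusters(dend, assoc, k=1)
    assert len(rep) == 1 and rep["n_genes"].iloc[0] == 9


def test_independent_cluster_coexpression_near_type_one_rate():
    rng = np.random.default_rng(10)
    x = rng.standard_normal((40, 33))
    assoc = ps.gene_association(expression_from_array(x))
    dend = ps.cluster_genes(assoc)
    rep = ps.summarize_clusters(dend, assoc, k=1, edge_p=0.1)
    # each gene has 39 chances at p <= 0.1; expected hit fraction is high,
    # so instead check the pairwise edge rate directly
    iu = np.triu_indices(40, k=1)
    rate = float((assoc.p.to_numpy()[iu] <= 0.1).mean())
    assert 0.05 <= rate <= 0.15


def test_cut_k_larger_than_genes_errors():
    x, _ = _planted_blocks(n_genes=5, n_samples=10, seed=11)
    dend = ps.cluster_genes(ps.gene_association(expression_from_array(x)))
    with pytest.raises(DataError):
        dend.cut(6)
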