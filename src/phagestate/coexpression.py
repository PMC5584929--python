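"""Whole-genome co-expression clustering with significance-based collapse.

Genes are associated by Pearson correlation (distance 1 - rho), clustered
agglomeratively, and subtrees whose members' expression profiles are
statistically indistinguishable are collapsed into labeled groups by a
similarity-profile (SIMPROF-style) permutation test: homogeneity is the
null, so a node collapses when the test fails to reject at ``alpha`` and
is split (descend to children) when it rejects.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Gene-gene Pearson association with p-values and clustering distance."""

    rho: pd.DataFrame
    p: pd.DataFrame
    distance: pd.DataFrame  # 1 - rho, in [0, 2]
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over genes (scipy linkage encoding)."""

    linkage: np.ndarray
    gene_ids: list[str]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.gene_ids)
        return str(tree)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    def cut(self, k: int) -> pd.Series:
        """Partition into k major clusters (labels 1..k)."""
        if k > len(self.gene_ids):
            raise DataError(f"k={k} exceeds number of genes {len(self.gene_ids)}")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.gene_ids, name="cluster")


@dataclass
class CoexpressionTree:
    dendrogram: Dendrogram
    collapsed_groups: list[list[str]] = field(default_factory=list)
    major_clusters: Optional[pd.Series] = None


def gene_association(expr: ExpressionMatrix, min_samples: int = 3) -> AssociationResult:
    """Pearson rho over genes with two-sided t-based p-values.

    Zero-variance genes are removed first (their correlation is undefined)
    and logged by id.
    """
    n = expr.values.shape[1]
    if n < min_samples:
        raise DataError(f"need >= {min_samples} samples, got {n}")
    arr = expr.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    dropped = [g for g, s in zip(expr.genes, sd) if s == 0]
    if dropped:
        logger.warning("dropping zero-variance genes: %s", dropped)
    keep = sd > 0
    genes = [g for g, k in zip(expr.genes, keep) if k]
    if len(genes) < 2:
        raise DataError("fewer than 2 non-constant genes")
    x = arr[keep]
    rho = np.corrcoef(x)
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |rho| == 1
    np.fill_diagonal(p, 0.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    idx = pd.Index(genes, name="gene_id")
    return AssociationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        distance=pd.DataFrame(dist, index=idx, columns=idx),
        dropped_genes=dropped,
    )


def cluster_genes(assoc: AssociationResult, linkage: str = "average") -> Dendrogram:
    """Agglomerative dendrogram on d = 1 - rho.

    Genes are sorted lexicographically before linkage so the merge
    structure is independent of input order (ties broken by gene id).
    """
    if linkage not in ("average", "complete"):
        raise DataError(f"unsupported linkage {linkage!r}")
    genes = sorted(assoc.distance.index)
    d = assoc.distance.loc[genes, genes].to_numpy()
    if not np.all(np.isfinite(d)):
        i, j = np.argwhere(~np.isfinite(d))[0]
        raise DataError(f"non-finite distance between {genes[i]} and {genes[j]}")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage=Z, gene_ids=list(genes))


def _simprof_pvalue(
    x: np.ndarray, n_perm: int, seed_seq: np.random.SeedSequence
) -> float:
    """Similarity-profile permutation p for one node.

    Statistic: pi = mean |pairwise rho - mean pairwise rho|, the
    dispersion of the node's correlation profile. A homogeneous node
    (shared profile plus exchangeable noise, or pure noise) has a flat
    profile whose dispersion matches sampling noise; a node mixing
    distinct expression programs has both high and low pairwise rho and a
    dispersed profile. The null is built by permuting each gene's sample
    values independently (B = n_perm), which preserves marginals while
    destroying gene-gene association.
    """
    g, n = x.shape
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    iu = np.triu_indices(g, k=1)

    def profile_dispersion(zz: np.ndarray) -> float:
        rhos = (zz @ zz.T / n)[iu]
        return float(np.abs(rhos - rhos.mean()).mean())

    pi_obs = profile_dispersion(z)
    rng = np.random.default_rng(seed_seq)
    template = np.broadcast_to(np.arange(n), (g, n)).copy()
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permuted(template, axis=1)
        zp = np.take_along_axis(z, idx, axis=1)
        exceed += profile_dispersion(zp) >= pi_obs
    return (1 + exceed) / (n_perm + 1)


def collapse_indistinguishable(
    dendrogram: Dendrogram,
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> list[list[str]]:
    """Top-down collapse of statistically indistinguishable subtrees.

    Starting from the root, each node's gene set is tested for internal
    structure; if the null of homogeneity is rejected (p <= alpha) the
    test recurses into the children, otherwise the node becomes one
    collapsed group and its descendants are not tested. Returns the
    resulting partition (singletons included); collapsed groups proper
    are the entries with two or more genes.
    """
    if n_perm < 99:
        raise DataError("n_perm < 99 gives insufficient null resolution")
    if not (0.0 <= alpha <= 1.0):
        raise DataError("alpha must lie in [0, 1]")
    values = expr.values.loc[dendrogram.gene_ids].to_numpy(dtype=float)
    root = hierarchy.to_tree(dendrogram.linkage)
    groups: list[list[str]] = []
    seed_seq = np.random.SeedSequence(seed)

    stack = [root]
    while stack:
        node = stack.pop()
        leaves = node.pre_order(lambda leaf: leaf.id)
        if node.is_leaf() or len(leaves) == 1:
            groups.append([dendrogram.gene_ids[leaves[0]]])
            continue
        child_seed = seed_seq.spawn(1)[0]
        p = _simprof_pvalue(values[leaves], n_perm, child_seed)
        if p <= alpha:  # heterogeneous: split
            stack.append(node.get_right())
            stack.append(node.get_left())
        else:  # indistinguishable: collapse
            groups.append(sorted(dendrogram.gene_ids[i] for i in leaves))
    return groups


def _letter_labels(n: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    out = list(letters)
    i = 0
    while len(out) < n:
        out.extend(letters[i] + l for l in letters)
        i += 1
    return out[:n]


def collapsed_groups_frame(groups: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Letter-labeled table of the collapsed (multi-gene) branches."""
    multi = [g for g in groups if len(g) > 1]
    labels = _letter_labels(len(multi))
    rows = [
        {"branch": lab, "gene_id": gene}
        for lab, genes in zip(labels, multi)
        for gene in genes
    ]
    return pd.DataFrame(rows, columns=["branch", "gene_id"])


def summarize_clusters(
    dendrogram: Dendrogram,
    assoc: AssociationResult,
    markers: Sequence[str] = ("gp091", "gp135", "gp136"),
    k: int = 3,
    edge_p: float = 0.1,
) -> pd.DataFrame:
    """Major-cluster report at a k-cluster tree cut.

    Per cluster: size, member genes, marker content, and how many members
    are significantly co-expressed (p <= edge_p) with at least one other
    member.
    """
    clusters = dendrogram.cut(k)
    rows = []
    for label in sorted(clusters.unique()):
        genes = sorted(clusters.index[clusters == label])
        sub_p = assoc.p.loc[genes, genes].to_numpy().copy()
        np.fill_diagonal(sub_p, np.inf)
        n_coexpr = int(((sub_p <= edge_p).any(axis=1)).sum()) if len(genes) > 1 else 0
        rows.append(
            {
                "cluster": int(label),
                "n_genes": len(genes),
                "markers": ",".join(m for m in markers if m in genes),
                "n_coexpressed": n_coexpr,
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def build_coexpression_tree(
    expr: ExpressionMatrix,
    linkage: str = "average",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    k: int = 3,
) -> tuple[CoexpressionTree, AssociationResult]:
    """Association -> dendrogram -> collapse -> major clusters in one call."""
    assoc = gene_association(expr)
    dend = cluster_genes(assoc, linkage=linkage)
    groups = collapse_indistinguishable(dend, expr, alpha=alpha, n_perm=n_perm, seed=seed)
    tree = CoexpressionTree(
        dendrogram=dend,
        collapsed_groups=[g for g in groups if len(g) > 1],
        major_clusters=dend.cut(min(k, len(dend.gene_ids))),
    )
    return tree, assoc
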