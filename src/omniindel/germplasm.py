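"""Germplasm genetic-pattern analysis: distance, UPGMA tree, PCA.

Genotypes are coded as diploid alt-allele dosages (0, 1, 2; NaN missing).
The genetic distance is an allele-sharing dosage distance,
d(i, j) = mean_l |x_il - x_jl| / 2 over loci non-missing in both samples,
which is 0 for identical genotypes and 1 for opposite homozygotes at every
shared locus.  Trees are built by UPGMA (average linkage with cluster-size
weighting) with node heights equal to half the merge distance, so the
cophenetic distance between two leaves equals the average pairwise distance
between their clusters.  PCA operates on per-locus mean-imputed, centered
dosages; reported variance proportions are eigenvalue shares of the sample
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with explicit missing cells (NaN)."""

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray  # float array, values in {0,1,2} or NaN

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("codes shape must be (n_samples, n_loci)")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("codes must be 0, 1, 2 or NaN")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.codes, index=self.sample_ids,
                          columns=self.locus_ids)
        df.to_csv(path, sep="\t", na_rep="NA",
                  float_format="%g", index_label="sample")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(np.diag(self.values), 0, equal_nan=True):
            raise ValueError("diagonal must be zero")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="sample")


def genetic_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing dosage distance with pairwise deletion of missing loci.

    Pairs with no shared non-missing locus get NaN and are flagged; samples
    that are entirely missing are flagged.
    """
    codes = matrix.codes
    n = codes.shape[0]
    if n < 2 or codes.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 locus")
    flagged = [
        sid for sid, row in zip(matrix.sample_ids, np.isnan(codes).all(axis=1))
        if row
    ]
    d = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(codes[i]) & ~np.isnan(codes[j])
            if not shared.any():
                d[i, j] = d[j, i] = np.nan
                undefined.append((matrix.sample_ids[i], matrix.sample_ids[j]))
                continue
            d[i, j] = d[j, i] = float(
                np.abs(codes[i, shared] - codes[j, shared]).mean() / 2.0
            )
    return DistanceMatrix(list(matrix.sample_ids), d,
                          undefined_pairs=undefined, flagged_samples=flagged)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    name: str | None = None
    height: float = 0.0
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class UltrametricTree:
    root: TreeNode
    sample_ids: list[str]

    def cophenetic(self) -> DistanceMatrix:
        """Tree-implied distances: 2 x height of each pair's LCA."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        n = len(self.sample_ids)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            child_leaves = [walk(c) for c in node.children]
            for a_set, b_set in (
                (child_leaves[x], child_leaves[y])
                for x in range(len(child_leaves))
                for y in range(x + 1, len(child_leaves))
            ):
                for a in a_set:
                    for b in b_set:
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * node.height
            return [l for grp in child_leaves for l in grp]

        walk(self.root)
        return DistanceMatrix(list(self.sample_ids), d)

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k clusters by splitting the highest nodes first."""
        if k < 1 or k > len(self.sample_ids):
            raise ValueError("k out of range")
        clusters: list[TreeNode] = [self.root]
        while len(clusters) < k:
            top = max(
                (c for c in clusters if not c.is_leaf),
                key=lambda c: (c.height, min(c.leaf_names())),
                default=None,
            )
            if top is None:
                break
            clusters.remove(top)
            clusters.extend(top.children)
        labels: dict[str, int] = {}
        for ci, node in enumerate(
            sorted(clusters, key=lambda c: min(c.leaf_names()))
        ):
            for name in node.leaf_names():
                labels[name] = ci
        return labels


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """Average-linkage agglomeration with cluster-size weighting.

    Merge height is half the merge distance.  Ties are broken by the
    lexicographically smallest pair of cluster labels (each cluster labelled
    by its smallest member id), making the tree deterministic.
    """
    n = len(dist.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    if np.isnan(dist.values).any():
        raise ValueError("undefined pairwise distances; cannot build tree")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=s) for i, s in enumerate(dist.sample_ids)
    }
    sizes = {i: 1 for i in range(n)}
    labels = {i: dist.sample_ids[i] for i in range(n)}
    d = {frozenset((i, j)): float(dist.values[i, j])
         for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                key = (
                    d[frozenset((i, j))],
                    tuple(sorted((labels[i], labels[j]))),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dmin, _), i, j = best
        if labels[j] < labels[i]:
            i, j = j, i
        merged = TreeNode(height=dmin / 2.0, children=(nodes[i], nodes[j]))
        for x in active:
            if x in (i, j):
                continue
            dx = (
                sizes[i] * d[frozenset((i, x))]
                + sizes[j] * d[frozenset((j, x))]
            ) / (sizes[i] + sizes[j])
            d[frozenset((next_id, x))] = dx
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    root = nodes[next(iter(active))]
    return UltrametricTree(root=root, sample_ids=list(dist.sample_ids))


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_newick(tree: UltrametricTree) -> str:
    """Serialize with branch lengths = parent height - child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(
                render(c, node.height) for c in node.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - node.height)}"

    return render(tree.root, None) + ";"


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    variance_proportions: np.ndarray

    def scores_table(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample", self.sample_ids)
        return df

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in
                              range(len(self.variance_proportions))],
                "variance_proportion": self.variance_proportions,
            }
        )


def pca(matrix: GenotypeMatrix, n_components: int = 3) -> PcaResult:
    """PCA of mean-imputed, centered dosages.

    Variance proportion of component i is its covariance eigenvalue divided
    by the total variance.  A constant (zero-variance) matrix is an error.
    """
    codes = matrix.codes.copy()
    n_samples, n_loci = codes.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    col_means = np.nanmean(np.where(np.isnan(codes), np.nan, codes), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_mask = np.isnan(codes)
    codes[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    centered = codes - codes.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("constant genotype matrix: variance undefined")
    n_components = min(n_components, n_samples - 1, n_loci)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(centered)
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        variance_proportions=model.explained_variance_ratio_.copy(),
    )
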