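"""Genome distance matrices and neighbor-joining trees with bootstraps.

Three distance flavors feed the same NJ machinery: binary distances over
pan-matrix columns (Jaccard by default, simple matching as an option),
core-genome sequence p-distances, and codon-usage distances (built in
:mod:`panprev.codon`).  NJ follows Saitou–Nei: iteratively join the pair
minimizing the Q-criterion (ties broken by lowest row/column index pair),
with negative branch lengths clamped to zero and the deficit moved to the
sibling branch.  Bootstrap supports resample characters (matrix rows or
alignment columns) with replacement and report the percentage of replicate
trees containing each internal bipartition of the original tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Callable, Optional

import numpy as np
import pandas as pd
from Bio import Align
from skbio import TreeNode

from .panmatrix import PanMatrix


@dataclass
class DistanceMatrix:
    """Symmetric genome × genome distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="genome_id")


def binary_distance_matrix(
    matrix: PanMatrix, metric: str = "jaccard"
) -> DistanceMatrix:
    """Pairwise distances between genome presence/absence columns.

    ``jaccard``: 1 − |intersection| / |union| of the two family sets;
    ``simple_matching``: fraction of families whose presence differs.
    """
    if matrix.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    vals = matrix.values()
    empty = np.where(vals.sum(axis=0) == 0)[0]
    if empty.size:
        raise ValueError(
            f"genome {matrix.genomes[empty[0]]!r} has no gene families"
        )
    n = matrix.n_genomes
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vals[:, i], vals[:, j]
            if metric == "jaccard":
                union = np.logical_or(a, b).sum()
                inter = np.logical_and(a, b).sum()
                d = 1.0 - inter / union
            elif metric == "simple_matching":
                d = np.mean(a != b)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(matrix.genomes), out)


_PROT_ALIGNER: Optional[Align.PairwiseAligner] = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        _PROT_ALIGNER = aligner
    return _PROT_ALIGNER


def _pair_mismatch_stats(a: str, b: str, aligned: bool) -> tuple[int, int]:
    """(mismatches, compared positions); gap columns excluded from both."""
    if aligned:
        if len(a) != len(b):
            raise ValueError("pre-aligned sequences must have equal lengths")
        cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    else:
        aln = _protein_aligner().align(a, b)[0]
        sa, sb = str(aln[0]), str(aln[1])
        cols = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    mism = sum(1 for x, y in cols if x != y)
    return mism, len(cols)


def sequence_distance_matrix(
    core_families: dict[str, dict[str, str]], aligned: bool = False
) -> DistanceMatrix:
    """Mean p-distance over core families, weighted by compared positions.

    ``core_families`` maps family id → {genome id → sequence}; every family
    must cover every genome.  With ``aligned=True`` sequences are taken as
    alignment rows (gap character ``-``) and compared column-wise, which
    makes the result the concatenated-alignment p-distance.
    """
    if not core_families:
        raise ValueError("no core families supplied")
    genomes = sorted({g for seqs in core_families.values() for g in seqs})
    for fid, seqs in core_families.items():
        for g in genomes:
            if g not in seqs:
                raise ValueError(f"family {fid!r} is missing genome {g!r}")
    n = len(genomes)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = comp = 0
            for seqs in core_families.values():
                m, c = _pair_mismatch_stats(seqs[genomes[i]], seqs[genomes[j]], aligned)
                mism += m
                comp += c
            out[i, j] = out[j, i] = mism / comp if comp else 0.0
    return DistanceMatrix(genomes, out)


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree as TreeNode.

    The returned (arbitrarily rooted) TreeNode has a trifurcating root for
    ≥ 3 taxa, mirroring the final three-way join of the algorithm.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dist.labels]

    if n == 2:
        root = TreeNode()
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.append(node)
        return root

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a_idx, a in enumerate(keep):
            for b_idx, b in enumerate(keep):
                new_d[a_idx, b_idx] = d[a, b]
            new_d[a_idx, m - 2] = new_d[m - 2, a_idx] = (
                d[a, i] + d[a, j] - d[i, j]
            ) / 2.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    # final three-way join: solve the three path equations
    root = TreeNode()
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = max(length, 0.0)
        root.append(node)
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _splits(tree: TreeNode) -> dict[int, frozenset[str]]:
    """Normalized internal bipartitions, keyed by id(node)."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[id(node)] = side
    return out


def bootstrap_support(
    source,
    tree_builder: Callable[[object], TreeNode],
    replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """Character-resampling bootstrap supports on the original tree.

    ``source`` is a PanMatrix (rows = characters) or a dict of equal-length
    aligned sequences (columns = characters); ``tree_builder`` maps a
    resampled source to a tree.  Supports (percent of replicate trees
    containing each internal bipartition) are written to the internal
    nodes' ``name``/``support`` of the tree built on the full source.  With
    fewer than 4 leaves supports are undefined and the tree is returned
    bare.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = tree_builder(source)
    labels = [t.name for t in tree.tips()]
    if len(labels) < 4:
        return tree
    rng = np.random.default_rng(seed)
    split_of_node = _splits(tree)
    counts = {key: 0 for key in split_of_node}
    sides = {key: side for key, side in split_of_node.items()}
    for _ in range(replicates):
        resampled = _resample(source, rng)
        rep_tree = tree_builder(resampled)
        rep_sides = set(_splits(rep_tree).values())
        for key, side in sides.items():
            if side in rep_sides:
                counts[key] += 1
    for node in tree.non_tips(include_self=False):
        if id(node) in counts:
            node.name = str(round(100.0 * counts[id(node)] / replicates))
    return tree


def _resample(source, rng: np.random.Generator):
    if isinstance(source, PanMatrix):
        n = len(source.families)
        idx = rng.integers(0, n, size=n)
        df = source.data.iloc[idx].copy()
        df.index = [f"r{i}" for i in range(n)]
        return PanMatrix(df, source.niches)
    if isinstance(source, dict):
        seqs = {k: str(v) for k, v in source.items()}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal lengths")
        L = lengths.pop()
        idx = rng.integers(0, L, size=L)
        return {k: "".join(s[i] for i in idx) for k, s in seqs.items()}
    raise TypeError(f"cannot bootstrap-resample a {type(source).__name__}")


def alignment_distance_builder(aligned: dict[str, str]) -> TreeNode:
    """NJ tree from a dict of pre-aligned marker sequences (one per genome)."""
    dm = sequence_distance_matrix({"marker": aligned}, aligned=True)
    return neighbor_joining(dm)


def root_at(tree: TreeNode, label: str) -> TreeNode:
    """Outgroup-rooted display form of an unrooted tree."""
    target = [t for t in tree.tips() if t.name == label]
    if not target:
        raise ValueError(f"label {label!r} not found in tree")
    return tree.root_at(target[0].parent)
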