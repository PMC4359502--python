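"""Functional-category frequency profiles, enrichment tests and clustering.

Annotations (COG single-letter categories, COG super-categories or KEGG
top-level classes) are inputs: a table mapping family id to a set of
category codes.  A family may carry several codes and then contributes one
count to each (percentages are computed over category assignments, so they
still sum to 100).  Unannotated families are counted separately and
excluded from percentages.

Enrichment of a category in a target family set against a disjoint
background set uses the two-sided Fisher exact test on the 2×2 table
[in-category vs not] × [target vs background]; a two-proportion z-test is
available as an option.  Genome (or set) profiles are hierarchically
clustered with average linkage on Euclidean distances between percentage
vectors; applying the same routine to the transposed matrix clusters the
category axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom, norm

AnnotationTable = dict[str, set[str]]

#: the 25 single-letter COG functional categories
COG_VOCABULARY: tuple[str, ...] = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a ``family_id<TAB>codes`` table (codes comma-separated)."""
    table: AnnotationTable = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family_id\t"):
                continue
            fid, _, codes = line.partition("\t")
            table[fid] = {c.strip() for c in codes.split(",") if c.strip()}
    return table


@dataclass
class FrequencyProfile:
    entity_id: str
    vocabulary: tuple[str, ...]
    counts: dict[str, int]
    percentages: dict[str, float]
    n_unannotated: int
    empty: bool = False  # warning flag for an empty family set

    def vector(self) -> np.ndarray:
        return np.array([self.percentages[c] for c in self.vocabulary])


def category_frequencies(
    families: set[str],
    annotation: AnnotationTable,
    vocabulary: Sequence[str],
    entity_id: str = "",
    single_code_only: bool = False,
) -> FrequencyProfile:
    """Category counts and percentages of a family set.

    Percentage = 100 × count / total category assignments within the set;
    multi-code families contribute once per code unless
    ``single_code_only`` restricts to families with exactly one code.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    vocab = tuple(vocabulary)
    counts = {c: 0 for c in vocab}
    n_unannotated = 0
    for fid in families:
        codes = annotation.get(fid, set()) & set(vocab)
        if not codes:
            n_unannotated += 1
            continue
        if single_code_only and len(codes) != 1:
            continue
        for code in codes:
            counts[code] += 1
    total = sum(counts.values())
    percentages = {
        c: (100.0 * counts[c] / total if total else 0.0) for c in vocab
    }
    return FrequencyProfile(
        entity_id=entity_id,
        vocabulary=vocab,
        counts=counts,
        percentages=percentages,
        n_unannotated=n_unannotated,
        empty=not families,
    )


def enrichment_test(
    category: str,
    target_set: set[str],
    background_set: set[str],
    annotation: AnnotationTable,
    method: str = "fisher",
) -> tuple[float, str]:
    """(p-value, direction) for over/under-representation of a category.

    Counts families (not assignments): a family is "in category" when the
    category appears among its codes.  Only annotated families enter the
    table.  Degenerate tables (category absent from both sets) return
    ``(1.0, 'none')``.
    """
    if target_set & background_set:
        raise ValueError("target and background sets must be disjoint")
    def split(fams: set[str]) -> tuple[int, int]:
        in_cat = not_cat = 0
        for fid in fams:
            codes = annotation.get(fid)
            if not codes:
                continue
            if category in codes:
                in_cat += 1
            else:
                not_cat += 1
        return in_cat, not_cat

    a, b = split(target_set)  # target: in-category, not
    c, d = split(background_set)
    if a + b == 0 or c + d == 0:
        raise ValueError("both sets need at least one annotated family")
    if a + c == 0:
        return 1.0, "none"
    p_target = a / (a + b)
    p_bg = c / (c + d)
    if p_target > p_bg:
        direction = "over"
    elif p_target < p_bg:
        direction = "under"
    else:
        direction = "none"
    if method == "fisher":
        p = fisher_two_sided(a, b, c, d)
    elif method == "ztest":
        pooled = (a + c) / (a + b + c + d)
        se = np.sqrt(pooled * (1 - pooled) * (1 / (a + b) + 1 / (c + d)))
        if se == 0:
            p = 1.0
        else:
            z = (p_target - p_bg) / se
            p = 2 * norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(p, 1.0)), direction


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one, with the conventional
    relative slack of 1e-7 for floating-point ties.
    """
    r1 = a + b
    n = a + b + c + d
    c1 = a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted q-values, same order as input."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    n = len(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        idx = order[rank_idx]
        val = min(prev, p[idx] * n / (rank_idx + 1))
        q[idx] = val
        prev = val
    return q.tolist()


@dataclass
class ProfileClustering:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    ordered_matrix: pd.DataFrame
    newick: str

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster assignment at k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.left, node.right
        bl = node.dist - left.dist
        br = node.dist - right.dist
        return f"({rec(left)}:{bl:.6g},{rec(right)}:{br:.6g})"

    return rec(tree) + ";"


def cluster_genomes_by_profile(
    profiles: Sequence[FrequencyProfile],
    method: str = "average",
    metric: str = "euclidean",
) -> ProfileClustering:
    """Hierarchical clustering of profiles; also usable on the transposed
    matrix for the category axis ("two-dimensional" clustering)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    vocab = profiles[0].vocabulary
    for p in profiles:
        if p.vocabulary != vocab:
            raise ValueError("profiles are over different vocabularies")
    labels = [p.entity_id for p in profiles]
    mat = np.vstack([p.vector() for p in profiles])
    link = hierarchy.linkage(mat, method=method, metric=metric)
    leaf_idx = hierarchy.leaves_list(link)
    leaf_order = [labels[i] for i in leaf_idx]
    df = pd.DataFrame(mat, index=labels, columns=list(vocab)).loc[leaf_order]
    return ProfileClustering(
        labels=labels,
        linkage=link,
        leaf_order=leaf_order,
        ordered_matrix=df,
        newick=_linkage_to_newick(link, labels),
    )


def transpose_profiles(
    profiles: Sequence[FrequencyProfile],
) -> list[FrequencyProfile]:
    """Category-axis profiles: one per category, across the input entities."""
    if not profiles:
        raise ValueError("no profiles supplied")
    vocab = profiles[0].vocabulary
    entities = tuple(p.entity_id for p in profiles)
    out = []
    for code in vocab:
        counts = {p.entity_id: p.counts[code] for p in profiles}
        pcts = {p.entity_id: p.percentages[code] for p in profiles}
        out.append(
            FrequencyProfile(
                entity_id=code,
                vocabulary=entities,
                counts=counts,
                percentages=pcts,
                n_unannotated=0,
            )
        )
    return out
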