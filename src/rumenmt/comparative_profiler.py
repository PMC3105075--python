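"""Comparative GH-family profiling: percentage matrix, Pearson distance, UPGMA.

Samples (metatranscriptomes, metagenomes or single genomes) are compared by
the percentage distribution of their glycoside hydrolase families: counts are
row-normalized to percents, pairwise Pearson correlation r is transformed to
the distance d = 1 - r (in [0, 2]), and samples are clustered by UPGMA
(unweighted pair group method with arithmetic mean), yielding an ultrametric
dendrogram written as newick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

GH_PREFIX = "GH"


@dataclass
class ProfileMatrix:
    """Samples x families count matrix with row-normalized percents."""

    sample_ids: list[str]
    family_ids: list[str]
    counts: np.ndarray  # (n_samples, n_families) non-negative ints
    percents: np.ndarray  # rows sum to 100, or 0 for flagged empty rows
    empty_rows: list[str] = field(default_factory=list)


def build_profile_matrix(
    per_sample_counts: Mapping[str, Mapping[str, int]],
    family_universe: Sequence[str],
) -> ProfileMatrix:
    """Assemble the two-dimensional family-frequency matrix.

    Families absent from a sample fill 0; families absent everywhere keep a
    zero column.  All-zero rows are flagged and excluded from clustering.
    """
    samples = list(per_sample_counts)
    families = list(family_universe)
    counts = np.zeros((len(samples), len(families)), dtype=int)
    fam_idx = {f: j for j, f in enumerate(families)}
    for i, s in enumerate(samples):
        for fam, n in per_sample_counts[s].items():
            if n < 0:
                raise ValueError(f"negative count for {s}/{fam}")
            if fam in fam_idx:
                counts[i, fam_idx[fam]] = n
    rowsums = counts.sum(axis=1)
    percents = np.zeros_like(counts, dtype=float)
    nonzero = rowsums > 0
    percents[nonzero] = 100.0 * counts[nonzero] / rowsums[nonzero, None]
    empty = [samples[i] for i in np.flatnonzero(~nonzero)]
    return ProfileMatrix(samples, families, counts, percents, empty)


def gh_only(family_universe: Iterable[str]) -> list[str]:
    """Restrict a family universe to glycoside hydrolase families."""
    return [f for f in family_universe if f.startswith(GH_PREFIX)]


def pearson_distance(matrix: ProfileMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise distance d = 1 - r between percent rows (r = Pearson).

    Flagged empty rows are excluded; a remaining row with zero variance is an
    error naming the sample.  The result is symmetric with zero diagonal and
    entries in [0, 2].
    """
    keep = [i for i, s in enumerate(matrix.sample_ids) if s not in matrix.empty_rows]
    if len(keep) < 2:
        raise ValueError("need at least two non-empty profiles")
    ids = [matrix.sample_ids[i] for i in keep]
    rows = matrix.percents[keep]
    for sid, row in zip(ids, rows):
        if np.ptp(row) == 0:
            raise ValueError(f"profile of sample {sid!r} has zero variance")
    r = np.corrcoef(rows)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return ids, d


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Node of an ultrametric merge tree; leaf iff ``children`` is empty.

    ``height`` follows the half-cophenetic convention: the merge creating a
    node at distance d sits at height d / 2, so the cophenetic distance
    between two leaves is twice the height of their lowest common ancestor.
    """

    members: tuple[str, ...]
    height: float = 0.0
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def name(self) -> str | None:
        return self.members[0] if self.is_leaf else None


def upgma(dist: np.ndarray, labels: Sequence[str]) -> DendrogramNode:
    """Cluster a distance matrix by UPGMA.

    Repeatedly merges the pair of clusters at minimal distance (ties broken
    by the lexicographically smallest pair of smallest member ids, for
    cross-platform determinism); the merged cluster's distance to the rest is
    the size-weighted arithmetic mean, and the merge height is d_min / 2.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least two leaves")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode((labels[i],)) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    d = {frozenset((i, j)): dist[i, j]
         for i, j in itertools.combinations(range(n), 2)}
    next_id = n
    while len(nodes) > 1:
        # minimal distance, then smallest (min-member, min-member) pair
        def key(pair):
            i, j = sorted(pair)
            mi = min(nodes[i].members)
            mj = min(nodes[j].members)
            return (d[pair], tuple(sorted((mi, mj))))

        best = min(d, key=key)
        dmin = d[best]
        i, j = sorted(best)
        merged = DendrogramNode(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            height=dmin / 2.0,
            children=(nodes[i], nodes[j]),
        )
        si, sj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dk = (si * d[frozenset((i, k))] + sj * d[frozenset((j, k))]) / (si + sj)
            d[frozenset((next_id, k))] = dk
        for pair in [p for p in d if i in p or j in p]:
            del d[pair]
        del nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        next_id += 1
    return nodes[next_id - 1]


def cophenetic_distances(root: DendrogramNode) -> dict[frozenset, float]:
    """Leaf-pair cophenetic distances (2 x the height of the joining node)."""
    out: dict[frozenset, float] = {}

    def visit(node: DendrogramNode) -> list[str]:
        if node.is_leaf:
            return [node.members[0]]
        leaf_sets = [visit(c) for c in node.children]
        for a_set, b_set in itertools.combinations(leaf_sets, 2):
            for a in a_set:
                for b in b_set:
                    out[frozenset((a, b))] = 2.0 * node.height
        return [l for s in leaf_sets for l in s]

    visit(root)
    return out


def to_newick(root: DendrogramNode, digits: int = 6) -> str:
    """Newick string with branch lengths (parent height - child height)."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        if node.is_leaf:
            body = node.members[0]
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        return f"{body}:{parent_height - node.height:.{digits}f}"

    if root.is_leaf:
        return f"{root.members[0]};"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# synthetic reference profiles
# ---------------------------------------------------------------------------


def default_reference_profiles() -> dict[str, dict[str, int]]:
    """Synthetic GH-count profiles of contrasting reference organisms.

    Stand-ins constructed for clustering demonstrations and tests (no real
    genome annotations are shipped): two cellulolytic-like profiles dominated
    by crystalline-cellulose families (GH5/6/9/45/48) and two
    oligosaccharide-like profiles dominated by GH1/GH13-type families.
    """
    return {
        "cellulolytic_A": {"GH5": 30, "GH6": 25, "GH9": 20, "GH45": 15,
                           "GH48": 20, "GH10": 8, "GH11": 10, "GH1": 4},
        "cellulolytic_B": {"GH5": 28, "GH6": 20, "GH9": 24, "GH45": 12,
                           "GH48": 16, "GH10": 10, "GH11": 8, "GH1": 6},
        "oligosaccharide_A": {"GH1": 40, "GH2": 30, "GH3": 35, "GH13": 25,
                              "GH5": 4, "GH10": 6, "GH43": 12},
        "oligosaccharide_B": {"GH1": 35, "GH2": 28, "GH3": 30, "GH13": 30,
                              "GH9": 3, "GH11": 5, "GH43": 10},
    }
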