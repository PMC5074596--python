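"""UPGMA tree construction, tree cutting, and the species-sharing tally.

Distances (e.g. from a protein multiple alignment) are consumed, not computed.
UPGMA repeatedly merges the closest pair of clusters, places the new node at
half the merge distance, and updates distances as size-weighted arithmetic
means; ties break on the lexicographically smallest pair of cluster labels, so
the tree is deterministic.  cut_tree partitions the leaves either below a
fixed height h or into a fixed number k of clusters (undoing the k-1 highest
merges).  species_tally reproduces a cluster-sharing summary across species:
singleton, one-species, two-, three-, and all-species categories with a
marginal table per species combination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("asymmetric distance matrix")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(x) for x in df.index], d=df.to_numpy())


@dataclass
class TreeNode:
    height: float
    label: str | None = None                 # leaf label
    children: list["TreeNode"] = field(default_factory=list)
    min_label: str = ""                      # smallest leaf label underneath

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [x for ch in self.children for x in ch.leaves()]

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self, parent_height: float | None = None) -> str:
        bl = "" if parent_height is None else f":{parent_height - self.height:.6g}"
        if self.is_leaf:
            return f"{self.label}{bl}"
        inner = ",".join(ch._newick_node(self.height) for ch in self.children)
        return f"({inner}){bl}"


@dataclass
class ClusterSummary:
    cluster_id: str
    members: list[str]
    species: tuple[str, ...]
    category: str   # singleton | one_species | two_species | three_species | all_species


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Deterministic UPGMA; merge heights are d/2 and leaves end up equidistant."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab, min_label=lab) for i, lab in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            d = dist[(i, j)]
            pair_labels = tuple(sorted((nodes[i].min_label, nodes[j].min_label)))
            key = (d, pair_labels)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d = dist[(i, j)]
        merged = TreeNode(
            height=d / 2,
            children=sorted([nodes[i], nodes[j]], key=lambda nd: nd.min_label),
            min_label=min(nodes[i].min_label, nodes[j].min_label),
        )
        si, sj = sizes[i], sizes[j]
        active -= {i, j}
        for k in active:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((next_id, k)))] = (si * dik + sj * djk) / (si + sj)
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


def _merge_nodes(root: TreeNode) -> list[TreeNode]:
    """Internal nodes sorted by height (ascending), tie-broken by min leaf label."""
    out = []

    def walk(nd: TreeNode) -> None:
        if not nd.is_leaf:
            out.append(nd)
            for ch in nd.children:
                walk(ch)

    walk(root)
    out.sort(key=lambda nd: (nd.height, nd.min_label))
    return out


def cut_tree(root: TreeNode, k: int | None = None, h: float | None = None) -> list[list[str]]:
    """Flat clusters: below height h, or exactly k clusters (k-1 highest merges undone)."""
    if (k is None) == (h is None):
        raise ValueError("give exactly one of k or h")
    leaves = root.leaves()
    if k is not None:
        if not (1 <= k <= len(leaves)):
            raise ValueError(f"k must be in [1, {len(leaves)}]")
        merges = _merge_nodes(root)          # ascending height
        kept = merges[: len(merges) - (k - 1)]
    else:
        kept = [nd for nd in _merge_nodes(root) if nd.height < h]

    parent: dict[str, str] = {lab: lab for lab in leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for nd in kept:
        ls = nd.leaves()
        for other in ls[1:]:
            ra, rb = find(ls[0]), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for lab in leaves:
        groups.setdefault(find(lab), []).append(lab)
    return [sorted(groups[r]) for r in sorted(groups)]


_CATEGORY_BY_NSPECIES = {1: "one_species", 2: "two_species", 3: "three_species"}


def species_tally(clusters: list[list[str]], species_of: dict[str, str]) -> tuple[list[ClusterSummary], pd.DataFrame]:
    """Categorize clusters by species sharing and tabulate the marginals.

    Returns the per-cluster summaries and a marginal table with one row per
    (category, species combination) and the count of clusters in it.
    """
    all_species = sorted(set(species_of.values()))
    summaries: list[ClusterSummary] = []
    for idx, members in enumerate(clusters):
        for m in members:
            if m not in species_of:
                raise KeyError(f"member {m!r} has no species mapping")
        sp = tuple(sorted({species_of[m] for m in members}))
        if len(members) == 1:
            cat = "singleton"
        elif len(sp) >= len(all_species):
            cat = "all_species"
        else:
            cat = _CATEGORY_BY_NSPECIES.get(len(sp), "all_species")
        summaries.append(ClusterSummary(f"cluster_{idx + 1}", sorted(members), sp, cat))

    rows: dict[tuple[str, str], int] = {}
    for s in summaries:
        combo = "+".join(s.species)
        rows[(s.category, combo)] = rows.get((s.category, combo), 0) + 1
    table = pd.DataFrame(
        [{"category": c, "species": combo, "clusters": n} for (c, combo), n in sorted(rows.items())]
    )
    return summaries, table
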