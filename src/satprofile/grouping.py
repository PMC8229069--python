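"""Profile grouping and schematic UPGMA trees.

Samples with identical alteration profiles form a group; profile dissimilarity
is the columnwise mean Jaccard distance between IUPAC base sets, and the
schematic tree is the UPGMA dendrogram of that distance — an ultrametric
summary of profile similarity, not a model-based phylogeny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .iupac import GAP, base_set
from .profiling import ProfileMatrix

_MISSING_CODES = {GAP, "N"}


def state_distance(s1: str, s2: str) -> float:
    """Jaccard distance between the base sets of two non-missing states.

    0 iff equal sets, 1 iff disjoint, else 1 - |intersection|/|union|.
    """
    b1, b2 = base_set(s1), base_set(s2)
    return 1.0 - len(b1 & b2) / len(b1 | b2)


def profile_distance(p1, p2, ids: tuple[str, str] | None = None) -> float:
    """Mean state distance over columns where both profiles assert a call."""
    if len(p1) != len(p2):
        raise ValueError("profiles span different column sets")
    shared = [
        (a, b)
        for a, b in zip(p1, p2)
        if a not in _MISSING_CODES and b not in _MISSING_CODES
    ]
    if not shared:
        label = f" ({ids[0]} vs {ids[1]})" if ids else ""
        raise ValueError(f"no shared non-missing columns{label}")
    return sum(state_distance(a, b) for a, b in shared) / len(shared)


@dataclass
class Group:
    members: list[str]
    representative_profile: tuple[str, ...]


@dataclass
class GroupPartition:
    """Disjoint groups of samples, in order of first-appearing member."""

    groups: list[Group]

    @property
    def sizes(self) -> list[int]:
        return [len(g.members) for g in self.groups]

    def group_of(self, sample_id: str) -> int:
        for k, g in enumerate(self.groups):
            if sample_id in g.members:
                return k
        raise KeyError(sample_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_groups": len(self.groups),
                "groups": [
                    {
                        "id": k + 1,
                        "members": g.members,
                        "representative_profile": list(g.representative_profile),
                    }
                    for k, g in enumerate(self.groups)
                ],
            },
            indent=2,
        )


def partition_profiles(matrix: ProfileMatrix, tolerance: float = 0.0) -> GroupPartition:
    """Partition samples by alteration profile.

    At tolerance 0 (default) groups are equivalence classes of exact profile
    equality.  A positive tolerance admits a sample into the first existing
    group whose every member lies within that mean distance (exploratory use).
    The reference row is not a sample and is never grouped.
    """
    groups: list[Group] = []
    for sid in matrix.sample_ids:
        prof = matrix.profile(sid)
        placed = False
        for g in groups:
            if tolerance == 0.0:
                ok = prof == g.representative_profile
            else:
                ok = all(
                    profile_distance(prof, matrix.profile(m), (sid, m)) <= tolerance
                    for m in g.members
                )
            if ok:
                g.members.append(sid)
                placed = True
                break
        if not placed:
            groups.append(Group(members=[sid], representative_profile=prof))
    return GroupPartition(groups=groups)


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric schematic tree; leaves have height 0."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for ch in self.children:
            out.extend(ch.leaf_labels())
        return out


@dataclass(frozen=True)
class SchematicTree:
    root: TreeNode
    labels: tuple[str, ...] = field(default=(), compare=False)

    def is_monophyletic(self, leaf_set) -> bool:
        """True when some clade's leaf set equals ``leaf_set`` exactly."""
        target = set(leaf_set)

        def walk(node: TreeNode) -> bool:
            here = set(node.leaf_labels())
            if here == target:
                return True
            if not target < here:
                return False
            return any(walk(ch) for ch in node.children)

        return walk(self.root)


def upgma(distances: np.ndarray, labels: list[str]) -> SchematicTree:
    """Average-linkage (UPGMA) agglomeration of a symmetric distance matrix.

    Node height is half the distance at which two clusters merge, so the tree
    is ultrametric.  Deterministic tie-break: among pairs at the minimal
    distance, merge the pair whose lexicographically smallest member label is
    smallest (then by the other pair member's smallest label).
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if n == 0:
        raise ValueError("no labels")
    if n == 1:
        leaf = TreeNode(height=0.0, label=labels[0])
        return SchematicTree(root=leaf, labels=tuple(labels))

    clusters: dict[int, TreeNode] = {
        k: TreeNode(height=0.0, label=lab) for k, lab in enumerate(labels)
    }
    sizes = {k: 1 for k in range(n)}
    smallest = {k: lab for k, lab in enumerate(labels)}  # lexicographically smallest member
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best = min(dist[key] for key in dist)
        tied = [key for key, v in dist.items() if v <= best + 1e-12]
        i, j = min(tied, key=lambda k: tuple(sorted((smallest[k[0]], smallest[k[1]]))))
        h = dist[(i, j)] / 2.0
        node = TreeNode(height=h, children=(clusters[i], clusters[j]))
        ni, nj = sizes[i], sizes[j]
        new_d = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_d[k] = (ni * dik + nj * djk) / (ni + nj)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = node
        sizes[next_id] = ni + nj
        smallest[next_id] = min(smallest[i], smallest[j])
        for k, v in new_d.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    (root,) = clusters.values()
    return SchematicTree(root=root, labels=tuple(labels))


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: SchematicTree) -> str:
    """Serialize with branch lengths (height differences); single leaf -> 'A:0.0;'."""
    root = tree.root

    def render(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if not node.children:
            return f"{_quote(node.label)}:{bl:.10g}"
        inner = ",".join(render(ch, node.height) for ch in node.children)
        return f"({inner}):{bl:.10g}"

    if not root.children:
        return f"{_quote(root.label)}:0.0;"
    inner = ",".join(render(ch, root.height) for ch in root.children)
    return f"({inner});"


def profile_distance_matrix(matrix: ProfileMatrix, include_reference: bool = False):
    """Pairwise profile distances over the matrix's samples.

    Returns ``(labels, D)``; with ``include_reference`` the reference profile is
    prepended as an extra row labelled by the reference id.
    """
    labels = list(matrix.sample_ids)
    profiles = [matrix.profile(s) for s in labels]
    if include_reference:
        labels = [matrix.reference_id] + labels
        profiles = [matrix.reference_profile()] + profiles
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = profile_distance(profiles[i], profiles[j], (labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    return labels, D
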