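"""p-distance matrices and neighbor-joining trees with bootstrap support.

Distances are proportions of differing sites among pairwise-comparable
positions: columns where either sequence has a gap ('-') or N are excluded
for that pair only (pairwise deletion), so all available sites are used.
Trees are standard Saitou-Nei neighbor joining with the Q-matrix criterion,
deterministic lexicographic tie-breaking and (by default) negative branch
lengths clamped to zero; branch lengths are base differences per site.
Bootstrap support for each internal bipartition is the percentage of
column-resampled replicates containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.name or ""
        parts = ",".join(
            f"{child._newick(with_support)}:{bl:.6g}" for child, bl in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({parts}){label}"

    def bipartitions(self) -> dict[frozenset, "TreeNode"]:
        """Internal-edge bipartitions: child-side leaf set -> child node.

        The root (trifurcation) itself defines no edge; trivial splits
        (single leaf or all-but-root-side) are excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _bl in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaf_names())
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[side] = child
                walk(child)

        walk(self)
        return out

    def path_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(n, d + bl) for n, d in walk(child)])
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for n1, d1 in groups[i]:
                        for n2, d2 in groups[j]:
                            key = (n1, n2) if n1 < n2 else (n2, n1)
                            dists[key] = d1 + d2
            return [x for g in groups for x in g]

        walk(self)
        return dists


def _seq_matrix(seqs: dict[str, str] | list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    ids = [i for i, _s in items]
    lengths = {len(s) for _i, s in items}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.frombuffer("".join(s.upper() for _i, s in items).encode(), dtype=np.uint8)
    return ids, mat.reshape(len(items), -1)


def p_distance(seqs: dict[str, str] | list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distances under pairwise deletion of gaps and Ns."""
    ids, mat = _seq_matrix(seqs)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            mism = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = mism / compared
    return DistanceMatrix(ids=ids, d=d)


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei NJ; deterministic, ties broken by lexicographic pair order.

    Returns the unrooted tree as a trifurcation at the final join.  On an
    additive matrix the tree's path distances reproduce the input exactly.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in D.ids]
    # active entries as (sort key, node, row); key keeps tie-breaks stable
    keys = list(D.ids)
    d = D.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a, b] for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                q = (m - 2) * d[a, b] - r[a] - r[b]
                pair_key = tuple(sorted((keys[a], keys[b])))
                cand = (q, pair_key)
                if best is None or cand < best[0:2]:
                    best = (q, pair_key, a, b)
        _q, _pk, a, b = best
        la = d[a, b] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a, b] - la
        parent = TreeNode(children=[(nodes[a], clamp(la)), (nodes[b], clamp(lb))])
        # reuse row a for the new node
        for c in active:
            if c not in (a, b):
                d[a, c] = d[c, a] = (d[a, c] + d[b, c] - d[a, b]) / 2
        nodes[a] = parent
        keys[a] = min(keys[a], keys[b])
        active.remove(b)
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    return TreeNode(
        children=[(nodes[a], clamp(la)), (nodes[b], clamp(lb)), (nodes[c], clamp(lc))]
    )


def bootstrap_support(
    seqs: dict[str, str] | list[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    clamp_negative: bool = True,
) -> TreeNode:
    """NJ tree with per-internal-edge bootstrap supports (percent).

    Columns are resampled with replacement; support is the percentage of
    replicates whose NJ tree contains the original internal bipartition.
    ``n_replicates=0`` returns the tree with supports absent.
    """
    ids, mat = _seq_matrix(seqs)
    if mat.shape[1] < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = neighbor_joining(p_distance(seqs), clamp_negative)
    biparts = tree.bipartitions()
    if n_replicates <= 0:
        return tree
    taxa = frozenset(ids)

    def canonical(side: frozenset) -> frozenset:
        # an unrooted split is the side/complement pair; pick one normal form
        other = taxa - side
        return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))

    rng = np.random.default_rng(seed)
    counts = {canonical(side): 0 for side in biparts}
    n_cols = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = [(i, row.tobytes().decode()) for i, row in zip(ids, mat[:, cols])]
        rep_tree = neighbor_joining(p_distance(resampled), clamp_negative)
        rep_splits = {canonical(side) for side in rep_tree.bipartitions()}
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for side, node in biparts.items():
        node.support = 100.0 * counts[canonical(side)] / n_replicates
    return tree
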