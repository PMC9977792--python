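"""Distance-based phylogeny of aligned protein domains.

p-distances (pairwise gap deletion), Saitou-Nei neighbor joining with
deterministic lowest-index tie-breaking, outgroup rooting, and the two-clade
membership readout. Negative NJ branch-length estimates are clamped to zero
with the deficit moved to the sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("diagonal not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("negative distances")


@dataclass
class TreeNode:
    """Rooted tree node; `length` is the edge above this node."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name] if self.name else []
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(_newick(c) for c in self.children)
        return f"({inner});"  # the root carries no branch length


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length:.6g}"


def p_distance_matrix(aligned: list[str], ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise p-distances: mismatches / columns where both rows have residues.

    Gapped columns are excluded pairwise; a pair with zero comparable columns
    raises an error naming the pair.
    """
    if len(aligned) < 3:
        raise ValidationError("need >= 3 sequences")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValidationError("aligned sequences differ in length")
    if ids is None:
        ids = [f"s{i + 1}" for i in range(len(aligned))]
    if len(ids) != len(aligned):
        raise ValidationError("ids/sequences length mismatch")
    n = len(aligned)
    seqs = [s.upper() for s in aligned]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                cols += 1
                if a != b:
                    diff += 1
            if cols == 0:
                raise ValidationError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            d[i, j] = d[j, i] = diff / cols
    return DistanceMatrix(ids=tuple(ids), d=d)


def poisson_correct(dm: DistanceMatrix) -> DistanceMatrix:
    """Poisson-corrected distances: -ln(1 - p). Requires all p < 1."""
    if (dm.d >= 1.0).any():
        raise ValidationError("p-distance of 1 cannot be Poisson corrected")
    return DistanceMatrix(ids=dm.ids, d=-np.log(1.0 - dm.d))


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # move any negative estimate onto the sibling edge, preserving the sum
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree represented with
    a trifurcating root. Ties in the Q-criterion go to the lowest index pair."""
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("need >= 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    D = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        D = np.pad(D, ((0, 1), (0, 1)))
        k_new = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[k_new, k] = D[k, k_new] = max(dk, 0.0)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]
    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def _edges(node: TreeNode, parent_id: int, graph: dict, names: dict, counter: list[int]) -> int:
    nid = counter[0]
    counter[0] += 1
    names[nid] = node.name
    graph.setdefault(nid, [])
    if parent_id >= 0:
        graph[parent_id].append((nid, node.length))
        graph[nid].append((parent_id, node.length))
    for c in node.children:
        _edges(c, nid, graph, names, counter)
    return nid


def root_with_outgroup(tree: TreeNode, outgroup_id: str) -> TreeNode:
    """Root on the outgroup's pendant edge (split half/half). Idempotent."""
    if len(tree.children) == 2:
        for idx, c in enumerate(tree.children):
            if c.is_leaf and c.name == outgroup_id:
                # already rooted here; just normalize child order
                if idx == 1:
                    tree.children.reverse()
                return tree
    graph: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}
    _edges(tree, -1, graph, names, [0])
    leaf = next((nid for nid, nm in names.items() if nm == outgroup_id and len(graph[nid]) == 1), None)
    if leaf is None:
        raise ValidationError(f"unknown outgroup leaf {outgroup_id!r}")
    (attach, edge_len), = graph[leaf]

    def build(nid: int, parent: int, length: float) -> TreeNode:
        kids = [build(c, nid, l) for c, l in graph[nid] if c != parent]
        node = TreeNode(name=names[nid], length=length, children=kids)
        # suppress degree-2 internal nodes created by re-rooting
        if len(kids) == 1 and names[nid] is None:
            only = kids[0]
            only.length += length
            return only
        return node

    root = TreeNode()
    out_node = TreeNode(name=outgroup_id, length=edge_len / 2)
    in_node = build(attach, leaf, edge_len / 2)
    root.children = [out_node, in_node]
    return root


def ingroup_clades(rooted: TreeNode) -> list[list[str]]:
    """Leaf-name lists of the ingroup bipartition under the root.

    The root's non-outgroup child splits the ingroup; each of its children's
    leaf sets is one clade (sorted for determinism).
    """
    if len(rooted.children) != 2:
        raise ValidationError("tree is not rooted with an outgroup")
    ingroup = rooted.children[1]
    if ingroup.is_leaf:
        return [[ingroup.name]]
    return [sorted(c.leaf_names()) for c in ingroup.children]
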