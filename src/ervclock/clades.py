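"""LTR indel fingerprinting, clade assignment, and distance trees.

Within an ERV family the paired LTRs of each provirus are nearly identical
in sequence, yet LTRs across proviruses separate into clades defined by
which indels — of what length, in what combination — they carry.  This
module enumerates the gap blocks of a master LTR alignment, scores each LTR
present/absent per block (its indel fingerprint), groups identical
fingerprints into clades (optionally merging near-identical ones by Jaccard
distance), and builds a neighbor-joining tree with midpoint rooting as a
visual companion; clade assignment itself is fingerprint-based, not
tree-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import GAP
from .consensus import AlignmentBlock


@dataclass
class LtrFingerprint:
    ltr_id: str
    vector: tuple             # presence of a gap per qualifying block
    clade: str | None = None
    unique_indels: list = field(default_factory=list)  # block indices


def gap_blocks(block: AlignmentBlock, min_indel_length: int = 3,
               ignore_terminal: bool = True) -> list[tuple[int, int]]:
    """Maximal runs of columns where at least one row is gapped,
    of length >= min_indel_length, left to right.

    Blocks touching the first or last alignment column are dropped by
    default: when LTRs come from a boundary detector, terminal overhangs
    reflect boundary-placement uncertainty rather than indel variation.
    """
    ncol = block.n_columns
    any_gap = [any(row[c] == GAP for row in block.rows)
               for c in range(ncol)]
    blocks = []
    start = None
    for c in range(ncol + 1):
        gapped = c < ncol and any_gap[c]
        if gapped and start is None:
            start = c
        elif not gapped and start is not None:
            if c - start >= min_indel_length:
                blocks.append((start, c))
            start = None
    if ignore_terminal:
        blocks = [(a, b) for a, b in blocks if a > 0 and b < ncol]
    return blocks


def fingerprint_indels(block: AlignmentBlock,
                       min_indel_length: int = 3) -> list[LtrFingerprint]:
    """Score every LTR present/absent over each qualifying gap block.

    An LTR "carries" a block when it is gapped over at least half of the
    block's columns.  Blocks where exactly one LTR differs from all others
    are flagged as that LTR's unique indels.
    """
    blocks = gap_blocks(block, min_indel_length)
    vectors = []
    for row in block.rows:
        bits = []
        for (a, b) in blocks:
            n_gap = sum(row[c] == GAP for c in range(a, b))
            bits.append(1 if n_gap * 2 >= (b - a) else 0)
        vectors.append(tuple(bits))
    fps = [LtrFingerprint(ltr_id=str(i), vector=v)
           for i, v in zip(block.ids, vectors)]
    for bi in range(len(blocks)):
        states = [v[bi] for v in vectors]
        ones = sum(states)
        if ones == 1 or ones == len(states) - 1:
            minority = 1 if ones == 1 else 0
            idx = states.index(minority)
            fps[idx].unique_indels.append(bi)
    return fps


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def cluster_fingerprints(fps: list[LtrFingerprint],
                         jaccard_threshold: float = 0.0) -> dict:
    """Group fingerprints into clades; returns ltr_id -> clade label.

    Identical indel vectors always share a clade; with a positive
    threshold, groups whose indel sets sit within the Jaccard distance are
    single-linkage merged.  Labels are deterministic, ordered by clade size
    (descending) then smallest member id: "clade_1", "clade_2", ...
    """
    if not fps:
        raise ValueError("no fingerprints")
    groups: dict[tuple, list] = {}
    for fp in fps:
        groups.setdefault(fp.vector, []).append(fp)
    keys = sorted(groups, key=lambda v: (len(v), v))
    parent = list(range(len(keys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if jaccard_threshold > 0:
        sets = [frozenset(i for i, b in enumerate(k) if b) for k in keys]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if _jaccard(sets[i], sets[j]) <= jaccard_threshold:
                    parent[find(j)] = find(i)
    merged: dict[int, list] = {}
    for i, key in enumerate(keys):
        merged.setdefault(find(i), []).extend(groups[key])
    clades = sorted(merged.values(),
                    key=lambda m: (-len(m), min(fp.ltr_id for fp in m)))
    out = {}
    for rank, members in enumerate(clades, start=1):
        label = f"clade_{rank}"
        for fp in members:
            fp.clade = label
            out[fp.ltr_id] = label
    return out


# ---------------------------------------------------------------------------
# neighbor joining + midpoint rooting

class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=None, length=0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6g}"


def nj_tree(dist: np.ndarray, ids: list) -> str:
    """Canonical neighbor joining with midpoint rooting; returns newick.

    Tie-breaking picks the lowest-index pair minimizing the Q criterion.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  Requires a symmetric matrix with zero diagonal and
    at least 3 taxa.
    """
    D = np.asarray(dist, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("matrix/ids size mismatch")
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    nodes = [_Node(name=str(t)) for t in ids]
    active = list(range(n))
    D = D.copy()
    while len(active) > 2:
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
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, redistributing to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        new = _Node(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = \
                0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]
    i, j = active
    nodes[i].length = nodes[j].length = 0.5 * D[i, j]
    root = _Node(children=[nodes[i], nodes[j]])
    root = _midpoint_root(root)
    return root.newick()


def _edges(node: _Node, parent=None, acc=None):
    if acc is None:
        acc = []
    for child in node.children:
        acc.append((node, child, child.length))
        _edges(child, node, acc)
    return acc


def _leaf_depths(node: _Node) -> list[tuple]:
    """(leaf, path length, path nodes) from ``node`` down."""
    if not node.children:
        return [(node, 0.0, [node])]
    out = []
    for child in node.children:
        for leaf, dist, path in _leaf_depths(child):
            out.append((leaf, dist + child.length, [node] + path))
    return out


def _midpoint_root(root: _Node) -> _Node:
    """Re-root the tree at the midpoint of the longest leaf-to-leaf path."""
    # collect distances between all leaf pairs through their common ancestor
    leaves = _leaf_depths(root)
    best = None
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            la, da, pa = leaves[a]
            lb, db, pb = leaves[b]
            shared = 0.0
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            # distance from root to common ancestor
            anc_depth = sum(n.length for n in pa[1:k])
            dist = (da - anc_depth) + (db - anc_depth)
            if best is None or dist > best[0]:
                best = (dist, pa, pb, da, db, anc_depth, k)
    total, pa, pb, da, db, anc_depth, k = best
    half = total / 2.0
    # walk from the deeper leaf's path towards the ancestor to find the edge
    # containing the midpoint
    deep_path, deep_d = (pa, da) if da - anc_depth >= db - anc_depth \
        else (pb, db)
    # cumulative distance from leaf back up
    walked = 0.0
    for idx in range(len(deep_path) - 1, 0, -1):
        child = deep_path[idx]
        if walked + child.length >= half - 1e-12:
            offset = half - walked     # distance from child up into edge
            return _reroot_on_edge(root, child, offset)
        walked += child.length
    return root


def _parent_map(node: _Node, parent=None, acc=None):
    if acc is None:
        acc = {}
    acc[id(node)] = parent
    for child in node.children:
        _parent_map(child, node, acc)
    return acc


def _reroot_on_edge(root: _Node, child: _Node, offset: float) -> _Node:
    """New root on the edge above ``child``, ``offset`` above the child."""
    parents = _parent_map(root)
    parent = parents[id(child)]
    if parent is None:
        return root
    new_root = _Node()
    parent.children.remove(child)
    upper = child.length - offset
    child.length = offset
    new_root.children.append(child)
    # invert the path from parent back to the old root
    prev, prev_len = new_root, upper
    node = parent
    while node is not None:
        up = parents[id(node)]
        length = node.length
        prev.children.append(node)
        node.length = prev_len
        if up is not None:
            up.children.remove(node)
        prev, prev_len = node, length
        node = up
    # the old root had 2 children; after inversion it retains one — splice it
    old_root_holder = prev
    if len(old_root_holder.children) == 1 and old_root_holder.name is None:
        only = old_root_holder.children[0]
        grand = parents[id(old_root_holder)]
        # old_root_holder is now a child somewhere in new tree; find holder
        holder_parents = _parent_map(new_root)
        hp = holder_parents[id(old_root_holder)]
        hp.children.remove(old_root_holder)
        only.length += old_root_holder.length
        hp.children.append(only)
        del grand
    return new_root
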