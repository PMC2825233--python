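"""Tree machinery: p-distances, neighbor joining, bootstrap, Fitch parsimony.

Trees are :class:`skbio.TreeNode` objects; bootstrap supports are attached
as ``node.support_value`` (percent of replicates containing the node's
bipartition) and survive rerooting through bipartition-keyed re-annotation,
since a support belongs to a bipartition of the leaf set, not to a node of
any particular rooting.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .similarity import ScoringParams
from .util import child_rng


def pairwise_distance(a: str, b: str, params: ScoringParams | None = None) -> float:
    """p-distance between two sequences after global alignment.

    Fraction of mismatching columns among columns where neither sequence is
    gapped; an alignment with zero ungapped columns is an error.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 0.0
    params = params or ScoringParams()
    aligner = params.make_aligner("global")
    alignment = next(iter(aligner.align(a, b)))
    ra, rb = str(alignment[0]), str(alignment[1])
    pairs = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("global alignment has no ungapped columns")
    return sum(x != y for x, y in pairs) / len(pairs)


def aligned_p_distances(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise p-distance matrix for pre-aligned, equal-length sequences."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    gap = ord("-")
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != gap) & (arr[j] != gap)
            nv = int(valid.sum())
            if nv == 0:
                raise ValueError(f"sequences {i} and {j} share no ungapped columns")
            D[i, j] = D[j, i] = float((arr[i][valid] != arr[j][valid]).sum()) / nv
    return D


def poisson_correct(D: np.ndarray) -> np.ndarray:
    """Poisson distance correction d = -ln(1 - p); p >= 1 is an error."""
    if (D >= 1).any():
        raise ValueError("p-distance >= 1 cannot be Poisson-corrected")
    return -np.log1p(-np.asarray(D, dtype=float))


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing the Q criterion, with ties broken
    by the lexicographically smallest (label, label) pair (each working
    node's label for tie-breaking is the smallest leaf label beneath it), so
    output is deterministic.  Negative branch-length estimates are clamped
    to 0.  Returns an unrooted tree stored with a degree-3 root.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("leaf labels must be unique")

    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # tie-break key: smallest leaf label in subtree
    d = D.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = clamp(li), clamp(lj)
        parent = TreeNode(children=[ni, nj])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    (a, b, c), dd = nodes, d
    a.length = clamp(0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2]))
    b.length = clamp(0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2]))
    c.length = clamp(0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1]))
    if clamped:
        warnings.warn("negative NJ branch-length estimate(s) clamped to 0")
    root = TreeNode(children=[a, b, c])
    for node in root.traverse():
        node.support_value = None
    return root


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def bipartition_keys(tree: TreeNode) -> dict[int, frozenset[str]]:
    """Canonical bipartition per internal (non-root, non-trivial) node.

    The key is the side of the split NOT containing the lexicographically
    smallest leaf label, so it is invariant to rooting.  Keyed by ``id(node)``.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    n = len(leaves)
    out: dict[int, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if not (2 <= len(below) <= n - 2):
            continue  # trivial split, present in every tree
        side = leaves - below if ref in below else below
        out[id(node)] = side
    return out


def annotate_supports(tree: TreeNode, support_map: Mapping[frozenset[str], int]) -> TreeNode:
    """Attach ``support_value`` to internal nodes from a bipartition->percent map."""
    keys = bipartition_keys(tree)
    for node in tree.traverse():
        node.support_value = None
    for node in tree.non_tips(include_self=False):
        sup = support_map.get(keys.get(id(node)))
        if sup is not None:
            node.support_value = int(sup)
    return tree


def bootstrap_support(
    alignment: Sequence[tuple[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "p",
) -> tuple[TreeNode, dict[frozenset[str], int]]:
    """NJ tree of an alignment with bootstrap supports on its internal edges.

    Columns are resampled with replacement per replicate; the support of an
    internal edge of the full-data tree is the percent of replicate trees
    containing the same bipartition (rounded to integer).  Returns the
    annotated tree and the bipartition->support map (for re-annotating any
    rerooted copy).  Identical seeds give identical supports.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    labels = [lab for lab, _ in alignment]
    seqs = [s for _, s in alignment]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires equal-length (aligned) sequences")
    L = lengths.pop()
    dist = {"p": aligned_p_distances, "poisson": lambda s: poisson_correct(aligned_p_distances(s))}[
        correction
    ]
    full = neighbor_joining(dist(seqs), labels)
    target = bipartition_keys(full)
    counts = {key: 0 for key in target.values()}
    rng = child_rng(seed)
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_seqs = ["".join(row) for row in arr[:, cols]]
        rep_tree = neighbor_joining(dist(rep_seqs), labels)
        for key in set(bipartition_keys(rep_tree).values()):
            if key in counts:
                counts[key] += 1
    support_map = {key: int(round(100.0 * c / n_replicates)) for key, c in counts.items()}
    annotate_supports(full, support_map)
    return full, support_map


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_ancestral(
    tree: TreeNode, leaf_states: Mapping[str, str]
) -> tuple[dict[int, frozenset[str]], int]:
    """Fitch bottom-up pass for a discrete character on a rooted tree.

    Returns (state sets keyed by ``id(node)``, parsimony score).  The state
    set of an internal node is the intersection of its children's sets when
    non-empty, else their union (one union event = one change counted);
    ambiguity is preserved, not resolved.  Every leaf must be annotated.
    """
    states: dict[int, frozenset[str]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_tip():
            if node.name not in leaf_states:
                raise ValueError(f"leaf {node.name!r} has no character state")
            states[id(node)] = frozenset([leaf_states[node.name]])
        else:
            acc: frozenset[str] | None = None
            for child in node.children:
                cs = states[id(child)]
                if acc is None:
                    acc = cs
                else:
                    inter = acc & cs
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cs
                        score += 1
            states[id(node)] = acc if acc is not None else frozenset()
    return states, score


def midpoint_root(tree: TreeNode, support_map: Mapping[frozenset[str], int] | None = None) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Supports are re-attached afterwards by bipartition lookup when a
    ``support_map`` is given (rerooting relocates internal nodes, so
    node-attached values cannot be trusted across it).
    """
    work = tree.copy()
    for node in work.traverse():
        if node.length is None and node.parent is not None:
            node.length = 0.0
    rooted = work.root_at_midpoint()
    if support_map is not None:
        annotate_supports(rooted, support_map)
    else:
        for node in rooted.traverse():
            node.support_value = getattr(node, "support_value", None)
    return rooted
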