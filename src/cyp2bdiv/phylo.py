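"""Distance-based tree construction and parsimony ancestral states.

Neighbor-joining on a (Poisson-corrected) amino-acid distance supplies the
clone tree that the UniFrac treatment comparison and the per-site
selection scan consume; Fitch parsimony provides deterministic
ancestral codon assignments for edge-level substitution counting.
Trees are :class:`dendropy.Tree` objects throughout, so newick I/O and
standard tree surgery come for free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .seqcore import CodonAlignment, mean_p_distance, p_distance_matrix


def neighbor_joining(d: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration.

    ``d`` must be symmetric with zero diagonal over >=3 labels.  The result
    is an unrooted tree stored with a provisional trifurcating root.
    Determinism is pinned: Q-criterion ties are broken by the smallest pair
    of cluster creation indices, and negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs >=3 taxa")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    tns = dendropy.TaxonNamespace([str(l) for l in labels])
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(str(label))
        nodes.append(node)
    order = list(range(n))  # creation index per active cluster
    D = d.copy()
    active = list(range(n))

    def _join(i_pos: int, j_pos: int, vi: float, vj: float) -> None:
        """Join active clusters at positions i_pos < j_pos into a new node."""
        nonlocal D, active, order
        # clamp negative estimates, deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        u = dendropy.Node()
        ci, cj = nodes[active[i_pos]], nodes[active[j_pos]]
        u.add_child(ci)
        u.add_child(cj)
        ci.edge.length = vi
        cj.edge.length = vj
        nodes.append(u)
        dij = D[i_pos, j_pos]
        du = 0.5 * (D[i_pos, :] + D[j_pos, :] - dij)
        keep = [k for k in range(len(active)) if k not in (i_pos, j_pos)]
        newD = np.empty((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        active = [active[k] for k in keep] + [len(nodes) - 1]
        order = [order[k] for k in keep] + [len(nodes) - 1]

    while len(active) > 3:
        r = len(active)
        rs = D.sum(axis=1)
        Q = (r - 2) * D - rs[:, None] - rs[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((order[i], order[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (rs[i] - rs[j]) / (2.0 * (r - 2))
        vj = D[i, j] - vi
        _join(i, j, vi, vj)

    # final trifurcation: closed-form terminal branches
    root = dendropy.Node()
    (a, b, c) = (nodes[active[0]], nodes[active[1]], nodes[active[2]])
    va = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    vb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    vc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(node)
        node.edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _find_leaf(tree: dendropy.Tree, leaf_id: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == leaf_id:
            return leaf
    raise KeyError(f"leaf {leaf_id!r} not in tree")


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root on the outgroup's terminal branch (bisected); returns a new tree."""
    rooted = tree.clone(depth=1)
    leaf = _find_leaf(rooted, outgroup_id)
    half = (leaf.edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(leaf.edge, length1=half, length2=half,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def root_at_midpoint(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint rooting; returns a new tree."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def poisson_correct(p: np.ndarray) -> np.ndarray:
    """Poisson-corrected distance -ln(1 - p) for amino-acid p-distances."""
    p = np.asarray(p, dtype=float)
    if (p >= 1.0).any():
        raise ValueError("p-distance of 1 cannot be Poisson corrected")
    return -np.log1p(-p)


def tree_from_alignment(
    aln: CodonAlignment,
    level: str = "aminoacid",
    correction: str = "poisson",
) -> dendropy.Tree:
    """NJ tree from the alignment's pairwise distances.

    ``correction`` is ``"poisson"`` (default, -ln(1-p)) or ``"none"``
    (raw p-distance).  Tied sequences (distance 0) are fine: NJ places
    them as zero-length cherries.
    """
    d = p_distance_matrix(aln, level=level)
    if correction == "poisson":
        d = poisson_correct(d)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return neighbor_joining(d, aln.ids)


@dataclass
class AncestralAssignment:
    """Per-column Fitch parsimony codon states for every node of a rooted
    tree, plus the minimal change count per column."""

    tree: dendropy.Tree
    states: list[dict[dendropy.Node, str]]  # one dict per 1-based column
    changes: np.ndarray  # minimal changes per column

    def column(self, index: int) -> dict[dendropy.Node, str]:
        return self.states[index - 1]


def fitch_ancestral(tree: dendropy.Tree, aln: CodonAlignment) -> AncestralAssignment:
    """Fitch parsimony ancestral codons, column by column.

    Bottom-up set intersections/unions give the minimal change count;
    the deterministic top-down pass assigns the parent's state when
    possible, otherwise the lexicographically smallest member of the
    node's state set.  Exact for binary trees (the rooted NJ trees used
    here); multifurcations are folded pairwise.
    """
    by_id = {m.id: m for m in aln.members}
    leaves = [l for l in tree.leaf_node_iter()]
    for leaf in leaves:
        if leaf.taxon.label not in by_id:
            raise ValueError(f"tree leaf {leaf.taxon.label!r} missing from alignment")
    postorder = list(tree.postorder_node_iter())
    columns: list[dict[dendropy.Node, str]] = []
    changes = np.zeros(aln.codon_count, dtype=int)
    for col in range(1, aln.codon_count + 1):
        k = (col - 1) * 3
        state_sets: dict[dendropy.Node, frozenset[str]] = {}
        n_changes = 0
        for node in postorder:
            if node.is_leaf():
                codon = by_id[node.taxon.label].nucleotides[k : k + 3]
                state_sets[node] = frozenset((codon,))
            else:
                acc: frozenset[str] | None = None
                for child in node.child_nodes():
                    cs = state_sets[child]
                    if acc is None:
                        acc = cs
                    else:
                        inter = acc & cs
                        if inter:
                            acc = inter
                        else:
                            acc = acc | cs
                            n_changes += 1
                state_sets[node] = acc
        assigned: dict[dendropy.Node, str] = {}
        for node in tree.preorder_node_iter():
            options = state_sets[node]
            if node.parent_node is None:
                assigned[node] = min(options)
            else:
                parent_state = assigned[node.parent_node]
                assigned[node] = (
                    parent_state if parent_state in options else min(options)
                )
        columns.append(assigned)
        changes[col - 1] = n_changes
    return AncestralAssignment(tree=tree, states=columns, changes=changes)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
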