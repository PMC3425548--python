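"""Unweighted UniFrac between treatment groups, with permutation tests.

The question: are clones from different population x diet treatments
distributed non-randomly across the clone tree?  Unweighted UniFrac
measures, for two groups of leaves, the fraction of spanned branch length
unique to one group.  Significance comes from permuting leaf labels
(group sizes preserved); the omnibus statistic is the mean of the pairwise
distances over all compared treatment pairs, and pairwise p-values carry a
Bonferroni correction for the number of pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqcore import TreatmentPartition


def _edge_structure(
    tree: dendropy.Tree,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Leaf labels, edge x leaf descendant matrix, and edge lengths.

    Edges are every branch with a parent (the seed node's null edge is
    excluded); missing branch lengths count as zero.
    """
    leaves = sorted(
        (l for l in tree.leaf_node_iter()), key=lambda l: l.taxon.label
    )
    index = {id(l): i for i, l in enumerate(leaves)}
    labels = [l.taxon.label for l in leaves]
    below: dict[int, np.ndarray] = {}
    rows, lengths = [], []
    for node in tree.postorder_node_iter():
        vec = np.zeros(len(leaves), dtype=bool)
        if node.is_leaf():
            vec[index[id(node)]] = True
        else:
            for child in node.child_nodes():
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent_node is not None:
            rows.append(vec)
            lengths.append(node.edge.length or 0.0)
    return labels, np.vstack(rows), np.asarray(lengths, dtype=float)


def _unifrac_from_counts(
    c_a: np.ndarray, c_b: np.ndarray, n_a: int, n_b: int, lengths: np.ndarray
) -> float:
    """Unweighted UniFrac from per-edge descendant counts of two groups.

    Equivalent to pruning the tree to the two groups' leaves and rooting at
    their MRCA: edges with no descendant in either group, and edges
    ancestral to every kept leaf, drop out; the rest are unique to one
    group or shared.
    """
    has_a = c_a > 0
    has_b = c_b > 0
    complete = (c_a == n_a) & (c_b == n_b)
    unique = (has_a ^ has_b)
    shared = has_a & has_b & ~complete
    u = lengths[unique].sum()
    s = lengths[shared].sum()
    total = u + s
    return float(u / total) if total > 0 else 0.0


def unifrac_from_sets(
    tree: dendropy.Tree, group_a: set[str], group_b: set[str]
) -> float:
    """Unweighted UniFrac between two explicit leaf-label sets."""
    labels, M, lengths = _edge_structure(tree)
    in_tree = set(labels)
    a = np.array([l in group_a for l in labels])
    b = np.array([l in group_b for l in labels])
    if not a.any() or not b.any():
        raise ValueError("both groups must be non-empty among tree leaves")
    c_a = M @ a
    c_b = M @ b
    return _unifrac_from_counts(c_a, c_b, int(a.sum()), int(b.sum()), lengths)


def unweighted_unifrac(
    tree: dendropy.Tree,
    partition: TreatmentPartition,
    group_a: str,
    group_b: str,
) -> float:
    """Unweighted UniFrac between two treatment groups of the partition.

    Leaves outside the two groups are effectively pruned.  Symmetric and
    in [0, 1]; 0 when every spanned branch leads to both groups, 1 when
    the two groups share no branch below their common ancestor.
    """
    set_a = set(partition.members_of(group_a))
    set_b = set(partition.members_of(group_b))
    return unifrac_from_sets(tree, set_a, set_b)


@dataclass
class UniFracResult:
    observed: float
    overall_p: float
    pairwise: pd.DataFrame  # group_a, group_b, distance, raw_p, corrected_p
    n_permutations: int
    seed: int
    skipped_pairs: list[tuple[str, str]]


def permutation_test(
    tree: dendropy.Tree,
    partition: TreatmentPartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> UniFracResult:
    """Label-permutation significance test of treatment structure.

    The observed omnibus statistic is the mean pairwise unweighted UniFrac
    over all group pairs (groups with <2 leaves are skipped with a warning
    and excluded from the Bonferroni count).  The null shuffles leaf
    labels with group sizes preserved; p-values use the add-one rule
    ``(1 + #{null >= obs}) / (1 + n_perm)`` and are therefore never zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels, M, lengths = _edge_structure(tree)
    partition.validate_against(labels)
    group_names = partition.labels()
    sizes = {g: sum(partition.groups[l] == g for l in labels)
             for g in group_names}
    usable, skipped = [], []
    for g in group_names:
        if sizes[g] >= 2:
            usable.append(g)
        else:
            warnings.warn(f"group {g!r} has <2 leaves; its pairs are skipped")
    pairs = list(itertools.combinations(usable, 2))
    for g in group_names:
        if g not in usable:
            skipped.extend((g, h) for h in group_names if h != g and g < h)
    if not pairs:
        raise ValueError("no group pair with >=2 leaves per group")

    gidx = {g: i for i, g in enumerate(group_names)}
    assign = np.array([gidx[partition.groups[l]] for l in labels])
    onehot = np.zeros((len(labels), len(group_names)))
    onehot[np.arange(len(labels)), assign] = 1.0
    n_per_group = onehot.sum(axis=0).astype(int)
    Mf = M.astype(float)

    def stats(perm_onehot: np.ndarray) -> np.ndarray:
        counts = Mf @ perm_onehot  # edges x groups
        out = np.empty(len(pairs))
        for k, (ga, gb) in enumerate(pairs):
            ia, ib = gidx[ga], gidx[gb]
            out[k] = _unifrac_from_counts(
                counts[:, ia], counts[:, ib],
                n_per_group[ia], n_per_group[ib], lengths,
            )
        return out

    observed_pairwise = stats(onehot)
    observed = float(observed_pairwise.mean())

    rng = np.random.default_rng(seed)
    ge_overall = 0
    ge_pairwise = np.zeros(len(pairs), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        null_pairwise = stats(onehot[perm])
        ge_overall += null_pairwise.mean() >= observed
        ge_pairwise += null_pairwise >= observed_pairwise
    overall_p = (1 + ge_overall) / (1 + n_perm)
    raw_p = (1 + ge_pairwise) / (1 + n_perm)
    corrected = np.minimum(1.0, raw_p * len(pairs))
    table = pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "distance": observed_pairwise,
            "raw_p": raw_p,
            "corrected_p": corrected,
        }
    )
    return UniFracResult(
        observed=observed,
        overall_p=float(overall_p),
        pairwise=table,
        n_permutations=n_perm,
        seed=seed,
        skipped_pairs=skipped,
    )
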