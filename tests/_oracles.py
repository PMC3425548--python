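"""Independent oracles used to cross-check the implementation.

Each function here recomputes a quantity by a different route than the
package (explicit enumeration, tree surgery, closed forms) so that tests
compare two independent derivations.
"""

from __future__ import annotations

import itertools
import math

import dendropy

from Bio.Seq import Seq


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_pathway_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by explicit enumeration,
    translating every intermediate codon with biopython."""
    stops = {"TAA", "TAG", "TGA"}
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            steps.append(translate_codon(nxt) == translate_codon(cur))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return float("nan"), float("nan")  # caller decides; no stop-free path
    sd = sum(sum(p) for p in paths) / len(paths)
    nd = sum(len(p) - sum(p) for p in paths) / len(paths)
    return sd, nd


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Potential (s, n) by direct enumeration of the nine mutations."""
    stops = {"TAA", "TAG", "TGA"}
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in stops and translate_codon(mut) == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def unifrac_prune_oracle(
    tree: dendropy.Tree, group_a: set[str], group_b: set[str]
) -> float:
    """Unweighted UniFrac by physical pruning with dendropy.

    The tree is pruned to the union of the two groups, edges above the MRCA
    of the kept leaves are discarded, and each remaining edge is classified
    by the group membership of the leaves below it.
    """
    keep = sorted(group_a | group_b)
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    mrca = pruned.mrca(taxon_labels=keep)
    unique = shared = 0.0
    for node in mrca.preorder_iter():
        if node is mrca:
            continue
        length = node.edge.length or 0.0
        below = {l.taxon.label for l in node.leaf_iter()}
        in_a = bool(below & group_a)
        in_b = bool(below & group_b)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    total = unique + shared
    return unique / total if total > 0 else 0.0


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric summation with exact
    integer arithmetic (conditional rule: sum of P(table) <= P(observed))."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        for x in range(lo, hi + 1)
    }
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


def welch_oracle(g1, g2) -> tuple[float, float]:
    """Welch t statistic and Satterthwaite df from the textbook formulas."""
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    v1 = sum((x - m1) ** 2 for x in g1) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in g2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def fitch_bruteforce_min(tree: dendropy.Tree, leaf_states: dict[str, str]) -> int:
    """Minimum substitution count over all internal-node labelings.

    Exhaustive search over assignments of observed leaf states to internal
    nodes (sufficient for the parsimony minimum).
    """
    states = sorted(set(leaf_states.values()))
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), combo))
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = leaf_states[leaf.taxon.label]
        changes = sum(
            assign[id(n)] != assign[id(n.parent_node)]
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best
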