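"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from cyp2bdiv.seqcore import CodingSequence, CodonAlignment, Diet, Population
from cyp2bdiv.synthfamily import FamilyModel, generate_family


def make_cds(
    nucleotides: str,
    id: str = "s1",
    animal: str = "a1",
    population: Population = Population.GREAT_BASIN,
    diet: Diet = Diet.JUNIPER,
) -> CodingSequence:
    return CodingSequence(
        id=id,
        animal_id=animal,
        population=population,
        diet=diet,
        nucleotides=nucleotides,
    )


def make_alignment(codon_rows: list[list[str]], ids: list[str] | None = None) -> CodonAlignment:
    """Alignment from explicit analysis codons (ATG + codons + TAA added)."""
    members = []
    for i, row in enumerate(codon_rows):
        members.append(
            make_cds(
                "ATG" + "".join(row) + "TAA",
                id=ids[i] if ids else f"s{i+1}",
            )
        )
    return CodonAlignment(members)


def random_rooted_tree(
    rng: np.random.Generator, n_leaves: int, labels: list[str] | None = None
) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        node.edge.length = float(rng.exponential(1.0))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.exponential(1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


#: Reduced-size family used where the full 491-codon default would be slow.
SMALL_MODEL_KWARGS = dict(
    codon_count=120,
    srs_positions=(10, 25, 40, 55, 70, 85, 100, 115),
    clones_per_animal=3,
    animals_per_treatment=2,
)


@pytest.fixture(scope="session")
def default_family():
    """Clones, truth table and loci from the default family model."""
    model = FamilyModel(seed=0)
    clones, truth, loci = generate_family(model)
    return model, clones, truth, loci
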