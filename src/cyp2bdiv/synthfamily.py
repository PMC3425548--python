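"""Synthetic clone-set generator with the structure the analysis assumes.

Emulates a liver cDNA cloning study of a recently duplicated P450
subfamily: a handful of divergent loci descend from a common ancestral ORF
under a codon model with locus-specific substrate-recognition-site (SRS)
dynamics; each animal in each population x diet treatment contributes a
set of cloned transcripts whose source locus is drawn from the treatment's
expression weights, blurred by within-locus allelic variation and
RT-PCR error.  A truth table records the provenance of every emitted
clone so downstream stages can be scored against the generating model.

All randomness flows from the single ``FamilyModel.seed``; identical
models produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._codon import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS
from .fingerprint import DEFAULT_SRS_POSITIONS
from .seqcore import (
    TREATMENTS,
    CodingSequence,
    Diet,
    Population,
    write_fasta,
)

#: Default per-treatment expression weights over the four loci.  Locus 1 is
#: expressed by every treatment (juniper-leaning); loci 2-4 are each
#: dominated by one treatment, and some treatment x locus combinations are
#: absent altogether, emulating treatment-biased variant usage in which the
#: major clades are dominated by single treatments.
DEFAULT_EXPRESSION_WEIGHTS: dict[str, tuple[float, ...]] = {
    "GB-juniper": (0.45, 0.50, 0.05, 0.00),
    "GB-creosote": (0.30, 0.00, 0.65, 0.05),
    "MJ-juniper": (0.75, 0.05, 0.00, 0.20),
    "MJ-creosote": (0.30, 0.00, 0.05, 0.65),
}


@dataclass(frozen=True)
class FamilyModel:
    """Parameters of the synthetic gene family.

    ``locus_divergence`` and ``allele_divergence`` are expected proposed
    single-nucleotide changes per nucleotide site (per locus lineage and
    per sampled clone, respectively); ``error_rate`` is the per-nucleotide
    RT/PCR substitution probability.  Nonsynonymous proposals between loci
    are accepted with probability min(1, omega); omega_srs applies at the
    designated SRS codons, omega_background elsewhere.
    """

    n_loci: int = 4
    codon_count: int = 491
    locus_divergence: float = 0.05
    allele_divergence: float = 0.0005
    omega_background: float = 0.5
    omega_srs: float = 2.0
    srs_positions: tuple[int, ...] = DEFAULT_SRS_POSITIONS
    expression_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_WEIGHTS)
    )
    clones_per_animal: int = 7
    animals_per_treatment: int = 3
    error_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.codon_count < 20:
            raise ValueError("codon_count must be >= 20")
        for name in ("locus_divergence", "allele_divergence", "error_rate",
                     "omega_background", "omega_srs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pos in self.srs_positions:
            if not 1 <= pos <= self.codon_count:
                raise ValueError(f"SRS position {pos} outside codon range")
        for treatment in TREATMENTS:
            if treatment not in self.expression_weights:
                raise ValueError(f"missing expression weights for {treatment}")
            w = np.asarray(self.expression_weights[treatment], dtype=float)
            if w.size != self.n_loci or (w < 0).any():
                raise ValueError(f"bad weight vector for {treatment}")
            if w.sum() <= 0:
                raise ValueError(f"degenerate (all-zero) weights for {treatment}")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights for {treatment} must sum to 1")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["srs_positions"] = list(self.srs_positions)
        d["expression_weights"] = {
            k: list(v) for k, v in self.expression_weights.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


class Proposal(NamedTuple):
    """One logged mutation proposal during locus evolution."""

    codon_index: int  # 1-based
    at_srs: bool
    nonsynonymous: bool
    accepted: bool


_DUMMY = dict(animal_id="-", population=Population.GREAT_BASIN, diet=Diet.JUNIPER)


def simulate_ancestor(codon_count: int, seed: int) -> CodingSequence:
    """Random ancestral ORF of ``codon_count`` residues (initial Met
    included) plus a terminal stop: ATG, ``codon_count - 1`` uniform random
    sense codons, then TAA.  Deterministic per seed."""
    if codon_count < 20:
        raise ValueError("codon_count must be >= 20")
    rng = np.random.default_rng([int(seed), 0])
    body = rng.choice(len(SENSE_CODONS), size=codon_count - 1)
    nt = "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"
    return CodingSequence(id=f"ancestor-{seed}", nucleotides=nt, **_DUMMY)


def _mutable_range(nt_len: int) -> tuple[int, int]:
    # start codon and terminal stop are immutable: positions 3 .. nt_len-4
    return 3, nt_len - 3


def _propose(nt: list[str], rng: np.random.Generator) -> tuple[int, str, str]:
    """Draw a substitution that does not create a stop codon; returns
    (nt position, old codon, new codon).  Stop-creating draws are redrawn."""
    lo, hi = _mutable_range(len(nt))
    while True:
        pos = int(rng.integers(lo, hi))
        old_nt = nt[pos]
        new_nt = NUCLEOTIDES[int(rng.integers(4))]
        if new_nt == old_nt:
            new_nt = NUCLEOTIDES[(NUCLEOTIDES.index(old_nt) + 1 +
                                  int(rng.integers(3))) % 4]
        cstart = pos - pos % 3
        old_codon = "".join(nt[cstart : cstart + 3])
        new_codon = (old_codon[: pos % 3] + new_nt + old_codon[pos % 3 + 1 :])
        if new_codon not in STOP_CODONS:
            return pos, old_codon, new_codon


def evolve_locus(
    ancestor: CodingSequence,
    model: FamilyModel,
    locus_index: int,
    with_log: bool = False,
):
    """Evolve one locus from the ancestor under the codon model.

    The number of proposals is Poisson with mean
    ``locus_divergence x mutable nucleotide sites``; each proposal is a
    uniform single-nucleotide change (stop-creating draws redrawn),
    accepted with probability 1 if synonymous, else min(1, omega) with the
    SRS/background omega chosen by codon position.
    """
    rng = np.random.default_rng([int(model.seed), 1, int(locus_index)])
    nt = list(ancestor.nucleotides)
    lo, hi = _mutable_range(len(nt))
    n_prop = int(rng.poisson(model.locus_divergence * (hi - lo)))
    srs = set(model.srs_positions)
    log: list[Proposal] = []
    for _ in range(n_prop):
        pos, old_codon, new_codon = _propose(nt, rng)
        codon_index = pos // 3 + 1
        at_srs = codon_index in srs
        nonsyn = CODON_TO_AA[old_codon] != CODON_TO_AA[new_codon]
        if nonsyn:
            omega = model.omega_srs if at_srs else model.omega_background
            accepted = bool(rng.random() < min(1.0, omega))
        else:
            accepted = True
        if accepted:
            nt[pos] = new_codon[pos % 3]
        log.append(Proposal(codon_index, at_srs, nonsyn, accepted))
    out = CodingSequence(id=f"locus{locus_index}", nucleotides="".join(nt),
                         **_DUMMY)
    return (out, log) if with_log else out


def _substitutions(nt: list[str], rate: float,
                   rng: np.random.Generator) -> list[int]:
    """Apply sense-codon-preserving substitutions at the given per-site
    rate; returns the 0-based positions changed."""
    lo, hi = _mutable_range(len(nt))
    n = int(rng.poisson(rate * (hi - lo)))
    changed = []
    for _ in range(n):
        pos, _, new_codon = _propose(nt, rng)
        nt[pos] = new_codon[pos % 3]
        changed.append(pos)
    return changed


_TREATMENT_META = {
    "GB-juniper": (Population.GREAT_BASIN, Diet.JUNIPER),
    "GB-creosote": (Population.GREAT_BASIN, Diet.CREOSOTE),
    "MJ-juniper": (Population.MOJAVE, Diet.JUNIPER),
    "MJ-creosote": (Population.MOJAVE, Diet.CREOSOTE),
}


def sample_clones(
    loci: Sequence[CodingSequence], model: FamilyModel
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Sample treatment-labelled clones from the evolved loci.

    For each animal in each treatment, ``clones_per_animal`` clones are
    drawn; the source locus of every clone is an independent multinomial
    draw from the treatment's expression weights.  Allelic variation and
    RT-PCR error are layered on as sense-codon-preserving substitutions.
    Returns the clones plus a truth table (one row per clone).
    """
    if len(loci) != model.n_loci:
        raise ValueError("loci list does not match model.n_loci")
    rng = np.random.default_rng([int(model.seed), 2])
    clones: list[CodingSequence] = []
    rows = []
    counter = 0
    for treatment in TREATMENTS:
        pop, diet = _TREATMENT_META[treatment]
        weights = np.asarray(model.expression_weights[treatment], dtype=float)
        for a in range(1, model.animals_per_treatment + 1):
            animal = f"{pop.value}{diet.value[0]}{a}"
            for _ in range(model.clones_per_animal):
                counter += 1
                locus = int(rng.choice(model.n_loci, p=weights))
                nt = list(loci[locus].nucleotides)
                allele_pos = _substitutions(nt, model.allele_divergence, rng)
                error_pos = _substitutions(nt, model.error_rate, rng)
                clone_id = f"c{counter:03d}"
                clones.append(
                    CodingSequence(
                        id=clone_id,
                        animal_id=animal,
                        population=pop,
                        diet=diet,
                        nucleotides="".join(nt),
                    )
                )
                rows.append(
                    {
                        "clone_id": clone_id,
                        "animal_id": animal,
                        "treatment": treatment,
                        "locus": locus + 1,
                        "allele_positions": ";".join(map(str, allele_pos)),
                        "error_positions": ";".join(map(str, error_pos)),
                    }
                )
    return clones, pd.DataFrame(rows)


def generate_family(
    model: FamilyModel,
) -> tuple[list[CodingSequence], pd.DataFrame, list[CodingSequence]]:
    """Ancestor -> loci -> clones in one call; returns
    (clones, truth table, loci)."""
    ancestor = simulate_ancestor(model.codon_count, model.seed)
    loci = [evolve_locus(ancestor, model, i) for i in range(1, model.n_loci + 1)]
    clones, truth = sample_clones(loci, model)
    return clones, truth, loci


def write_outputs(
    clones: Sequence[CodingSequence],
    truth: pd.DataFrame,
    model: FamilyModel,
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "clones.fasta",
        "truth": outdir / "truth.tsv",
        "model": outdir / "family_model.json",
    }
    write_fasta(clones, paths["fasta"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["model"].write_text(model.to_json() + "\n")
    return paths
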