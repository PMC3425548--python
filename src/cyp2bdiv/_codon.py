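"""Shared genetic-code machinery for codon-level analyses.

Builds, once at import, the standard-code lookup tables used by the
Nei–Gojobori style counting in :mod:`cyp2bdiv.selection` and by the
codon-aware mutation proposals in :mod:`cyp2bdiv.synthfamily`:

* potential synonymous/nonsynonymous site counts per sense codon
  (``s`` = number of synonymous single-nucleotide changes divided by 3,
  ``n = 3 - s``; changes that would create a stop codon are never
  synonymous and count toward ``n``),
* observed synonymous/nonsynonymous differences for every sense-codon
  pair, averaged with equal weight over all minimal mutational pathways
  that do not pass through a stop codon.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

START_CODON = "ATG"


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def single_nt_neighbors(codon: str) -> list[str]:
    """All nine codons reachable by one nucleotide change."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


@lru_cache(maxsize=None)
def potential_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous potential sites ``(s, n)`` of a sense codon.

    At each of the three positions the fraction of the three possible
    single-nucleotide changes that are synonymous contributes to ``s``;
    ``n = 3 - s``.  Changes producing a stop codon are nonsynonymous by
    construction (a stop is not an amino acid).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no potential-site counts")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for mutant in single_nt_neighbors(codon):
        if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
            s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous differences ``(sd, nd)`` between
    two sense codons, averaged with equal weight over minimal mutational
    pathways.

    Pathways whose intermediate codons are stops are excluded; if every
    pathway is excluded (possible only for 2-3 step paths between rare
    codon pairs) the average falls back to all pathways.
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("pathway counts defined for sense codons only")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    everything: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                # step through a stop: still tally for the fallback average
                nd += 1
            elif CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        everything.append((sd, nd))
        if ok:
            valid.append((sd, nd))
    paths = valid if valid else everything
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    k = len(SENSE_CODONS)
    sd = np.zeros((k, k))
    nd = np.zeros((k, k))
    s_pot = np.zeros(k)
    n_pot = np.zeros(k)
    for i, ci in enumerate(SENSE_CODONS):
        s_pot[i], n_pot[i] = potential_sites(ci)
        for j in range(i + 1, k):
            a, b = pathway_counts(ci, SENSE_CODONS[j])
            sd[i, j] = sd[j, i] = a
            nd[i, j] = nd[j, i] = b
    return sd, nd, s_pot, n_pot


_TABLES: tuple[np.ndarray, ...] | None = None


def tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lazily built ``(SD, ND, S_POT, N_POT)`` arrays indexed by sense-codon
    index (see :data:`CODON_INDEX`)."""
    global _TABLES
    if _TABLES is None:
        _TABLES = _build_tables()
    return _TABLES


def encode_codons(nucleotides: str) -> np.ndarray:
    """Sense-codon index array for a stop-terminated ORF, stop excluded."""
    body = nucleotides[:-3]
    idx = np.empty(len(body) // 3, dtype=np.int16)
    for k in range(0, len(body), 3):
        idx[k // 3] = CODON_INDEX[body[k : k + 3]]
    return idx
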