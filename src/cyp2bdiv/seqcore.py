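"""Core domain types and I/O for cloned coding sequences.

The unit of analysis is a full-length open reading frame (ORF) cloned from
liver cDNA of a desert woodrat that went through a population x diet
feeding trial.  Every sequence therefore carries treatment metadata:
source population (Great Basin or Mojave) and experimental diet (juniper
or creosote).  FASTA headers encode this as ``id|animal|population|diet``
with configurable delimiter, e.g. ``c01|A12|GB|juniper``.

Records whose sequence is not a complete uninterrupted ORF (start codon
through a single terminal stop, no internal stops, no ambiguity codes) are
excluded and reported, mirroring how incomplete clones are discarded
before analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import percent_identity_with_gaps as _pid
from ._codon import CODON_TO_AA, START_CODON, STOP_CODONS


class SeqFormatError(ValueError):
    """Malformed FASTA input."""


class MetadataError(ValueError):
    """FASTA header that cannot be parsed into treatment metadata."""


class InvalidOrfError(ValueError):
    """Sequence violating the complete-ORF invariants."""


class Population(enum.Enum):
    GREAT_BASIN = "GB"
    MOJAVE = "MJ"


class Diet(enum.Enum):
    JUNIPER = "juniper"
    CREOSOTE = "creosote"


#: The four population x diet treatment groups of the feeding trial.
TREATMENTS: tuple[str, ...] = (
    "GB-juniper",
    "GB-creosote",
    "MJ-juniper",
    "MJ-creosote",
)


def treatment_label(population: Population, diet: Diet) -> str:
    return f"{population.value}-{diet.value}"


def _orf_problem(nt: str) -> str | None:
    """Reason the nucleotide string is not a valid complete ORF, or None."""
    if len(nt) % 3 != 0:
        return "length not divisible by 3"
    if len(nt) < 6:
        return "shorter than start + stop"
    if any(c not in "ACGT" for c in nt):
        return "non-ACGT symbol (ambiguity codes are rejected)"
    if not nt.startswith(START_CODON):
        return "does not begin with ATG"
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons[-1] not in STOP_CODONS:
        return "does not end with a stop codon"
    internal = [i + 1 for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
    if internal:
        return f"internal stop codon at codon {internal[0]}"
    return None


@dataclass(frozen=True)
class CodingSequence:
    """One cloned ORF with its treatment metadata."""

    id: str
    animal_id: str
    population: Population
    diet: Diet
    nucleotides: str

    def __post_init__(self) -> None:
        problem = _orf_problem(self.nucleotides)
        if problem:
            raise InvalidOrfError(f"{self.id}: {problem}")

    @property
    def treatment(self) -> str:
        return treatment_label(self.population, self.diet)

    @property
    def codon_count(self) -> int:
        """Number of analysed codons (terminal stop excluded)."""
        return len(self.nucleotides) // 3 - 1


@dataclass(frozen=True)
class ProteinSequence:
    """Translated ORF, terminal stop dropped."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if "*" in self.residues:
            raise InvalidOrfError(f"{self.id}: stop symbol in protein sequence")


def translate(seq: CodingSequence) -> ProteinSequence:
    """Translate under the standard genetic code, dropping the terminal stop."""
    aa = str(Seq(seq.nucleotides).translate())
    if "*" in aa[:-1] or not aa.endswith("*"):
        raise InvalidOrfError(f"{seq.id}: not a clean stop-terminated ORF")
    return ProteinSequence(id=seq.id, residues=aa[:-1])


class CodonAlignment:
    """Equal-length, frame-preserving set of coding sequences.

    Clones are full-length ORFs amplified with common primers, so they are
    positionally homologous without an explicit alignment step.  Codon
    columns are 1-based and exclude the terminal stop.
    """

    def __init__(self, members: Sequence[CodingSequence]):
        members = list(members)
        if not members:
            raise ValueError("alignment needs at least one member")
        length = len(members[0].nucleotides)
        for m in members:
            if len(m.nucleotides) != length:
                raise ValueError(
                    f"member {m.id} length {len(m.nucleotides)} != {length}"
                )
        ids = [m.id for m in members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        self.members: list[CodingSequence] = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def codon_count(self) -> int:
        return self.members[0].codon_count

    def proteins(self) -> list[ProteinSequence]:
        return [translate(m) for m in self.members]

    def codon_column(self, index: int) -> list[str]:
        """Codon states of the 1-based analysis column ``index``."""
        if not 1 <= index <= self.codon_count:
            raise IndexError(f"codon column {index} out of range")
        k = (index - 1) * 3
        return [m.nucleotides[k : k + 3] for m in self.members]

    def nucleotide_matrix(self) -> np.ndarray:
        """(members x analysed nucleotide sites) byte matrix, stop excluded."""
        rows = [
            np.frombuffer(m.nucleotides[:-3].encode(), dtype=np.uint8)
            for m in self.members
        ]
        return np.vstack(rows)

    def aminoacid_matrix(self) -> np.ndarray:
        rows = [
            np.frombuffer(translate(m).residues.encode(), dtype=np.uint8)
            for m in self.members
        ]
        return np.vstack(rows)


@dataclass
class TreatmentPartition:
    """Mapping sequence id -> treatment label."""

    groups: Mapping[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def members_of(self, label: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == label]

    def validate_against(self, leaf_ids: Iterable[str]) -> None:
        leaves = set(leaf_ids)
        missing = leaves - set(self.groups)
        if missing:
            raise ValueError(f"leaves without treatment label: {sorted(missing)}")
        if len(self.labels()) < 2:
            raise ValueError("need >=2 non-empty groups for a between-group test")

    @classmethod
    def from_sequences(cls, seqs: Iterable[CodingSequence]) -> "TreatmentPartition":
        return cls(groups={s.id: s.treatment for s in seqs})


@dataclass
class ReadReport:
    """Outcome of FASTA ingestion: accepted ORFs plus exclusion records."""

    sequences: list[CodingSequence]
    excluded: list[tuple[str, str]] = field(default_factory=list)


_POPULATION_CODES = {p.value: p for p in Population}
_DIET_CODES = {d.value: d for d in Diet}


def parse_header(header: str, delimiter: str = "|") -> tuple[str, str, Population, Diet]:
    parts = header.split(delimiter)
    if len(parts) != 4:
        raise MetadataError(
            f"header {header!r} does not parse as id{delimiter}animal"
            f"{delimiter}population{delimiter}diet"
        )
    seq_id, animal, pop, diet = parts
    if pop not in _POPULATION_CODES:
        raise MetadataError(f"header {header!r}: unknown population code {pop!r}")
    if diet not in _DIET_CODES:
        raise MetadataError(f"header {header!r}: unknown diet {diet!r}")
    return seq_id, animal, _POPULATION_CODES[pop], _DIET_CODES[diet]


def read_fasta(path: str | Path, delimiter: str = "|") -> ReadReport:
    """Read treatment-annotated ORFs from FASTA.

    Invalid ORFs are excluded and reported in the returned
    :class:`ReadReport`; unparseable headers raise :class:`MetadataError`.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython error surface
        raise SeqFormatError(f"{path}: {exc}") from exc
    if not records:
        raise SeqFormatError(f"{path}: no FASTA records found")
    report = ReadReport(sequences=[])
    for rec in records:
        seq_id, animal, pop, diet = parse_header(rec.id, delimiter)
        try:
            cs = CodingSequence(
                id=seq_id,
                animal_id=animal,
                population=pop,
                diet=diet,
                nucleotides=str(rec.seq).upper(),
            )
        except InvalidOrfError as exc:
            report.excluded.append((rec.id, str(exc)))
            continue
        report.sequences.append(cs)
    return report


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path,
                delimiter: str = "|") -> None:
    records = [
        SeqRecord(
            Seq(s.nucleotides),
            id=delimiter.join(
                [s.id, s.animal_id, s.population.value, s.diet.value]
            ),
            description="",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def percent_identity_with_gaps(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment identity of two proteins, gap columns counted.

    Match +1, mismatch 0, linear gap -1; among co-optimal alignments the one
    with fewest gap columns defines the identity.  Symmetric, in [0, 1],
    equal to 1 iff the sequences are identical.
    """
    return _pid(a.residues, b.residues)


def p_distance_matrix(aln: CodonAlignment, level: str = "nucleotide") -> np.ndarray:
    """Pairwise p-distance matrix (proportion of differing sites).

    ``level`` is ``"nucleotide"`` or ``"aminoacid"``; the terminal stop codon
    is excluded from the compared sites at both levels.
    """
    if len(aln) < 2:
        raise ValueError("p-distance needs >=2 members")
    if level == "nucleotide":
        mat = aln.nucleotide_matrix()
    elif level == "aminoacid":
        mat = aln.aminoacid_matrix()
    else:
        raise ValueError(f"unknown level {level!r}")
    diff = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return diff


def mean_p_distance(d: np.ndarray) -> float:
    """Mean of the off-diagonal upper triangle of a distance matrix."""
    iu = np.triu_indices(d.shape[0], k=1)
    return float(d[iu].mean())
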