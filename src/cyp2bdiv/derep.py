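"""Dereplication: greedy centroid grouping of protein variants.

Cloned transcripts from a recently duplicated gene family mix true locus
divergence with allelic variation and reverse-transcription/PCR error.
Grouping amino-acid sequences at a similarity threshold (default >95%
identity-with-gaps) collapses the low-level noise so the divergent variants
stand out, the same role OTU dereplication plays for amplicon data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqcore import ProteinSequence, percent_identity_with_gaps


@dataclass
class VariantGroup:
    representative_id: str
    member_ids: list[str]
    threshold: float

    def __len__(self) -> int:
        return len(self.member_ids)


def dereplicate(
    seqs: Sequence[ProteinSequence],
    threshold: float = 0.95,
    presort: bool = False,
) -> list[VariantGroup]:
    """Greedy centroid clustering at a similarity threshold.

    Sequences are processed in input order; each joins the first existing
    group whose representative identity is strictly greater than
    ``threshold``, otherwise it founds a new group.  The outcome can depend
    on input order (as with any greedy centroid scheme); ``presort=True``
    pins a canonical order (decreasing length, then id) for
    order-independent results.
    """
    if not seqs:
        raise ValueError("dereplicate needs at least one sequence")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = list(seqs)
    if presort:
        ordered.sort(key=lambda s: (-len(s.residues), s.id))
    reps: list[ProteinSequence] = []
    groups: list[VariantGroup] = []
    for s in ordered:
        placed = False
        for rep, grp in zip(reps, groups):
            if percent_identity_with_gaps(s, rep) > threshold:
                grp.member_ids.append(s.id)
                placed = True
                break
        if not placed:
            reps.append(s)
            groups.append(
                VariantGroup(representative_id=s.id, member_ids=[s.id],
                             threshold=threshold)
            )
    return groups


def count_unique(seqs: Sequence, level: str = "nucleotide") -> int:
    """Exact-string deduplication count at nucleotide or amino-acid level."""
    if level == "nucleotide":
        return len({s.nucleotides for s in seqs})
    if level == "aminoacid":
        strings = set()
        for s in seqs:
            strings.add(s.residues if isinstance(s, ProteinSequence)
                        else _aa_string(s))
        return len(strings)
    raise ValueError(f"unknown level {level!r}")


def _aa_string(seq) -> str:
    from .seqcore import translate

    return translate(seq).residues


def groups_table(groups: Sequence[VariantGroup],
                 proteins: Sequence[ProteinSequence]) -> pd.DataFrame:
    """Long-format group table with identity of each member to its
    representative."""
    by_id = {p.id: p for p in proteins}
    rows = []
    for gi, grp in enumerate(groups, start=1):
        rep = by_id[grp.representative_id]
        for member in grp.member_ids:
            rows.append(
                {
                    "group_id": gi,
                    "representative": grp.representative_id,
                    "member": member,
                    "identity_to_representative": percent_identity_with_gaps(
                        by_id[member], rep
                    ),
                }
            )
    return pd.DataFrame(rows)


def write_groups_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)
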