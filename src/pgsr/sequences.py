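"""Nucleotide sequence container and basic operations.

Sequences are plain uppercase strings over the alphabet {A, C, G, T, N}.
Anything that is not A/C/G/T is treated as ambiguous ("N") by downstream
k-mer counting; the container keeps the original symbol so round-trips are
faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence.

    Parameters
    ----------
    id : str
        Label, unique within any collection the sequence belongs to.
    residues : str
        Sequence string; stored uppercase.
    """

    id: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, id_suffix: str = "_rc") -> "NucleotideSequence":
        return NucleotideSequence(self.id + id_suffix,
                                  self.residues.translate(_COMPLEMENT)[::-1])


def reverse_complement(residues: str) -> str:
    """Reverse complement of a raw residue string (IUPAC-aware)."""
    return residues.upper().translate(_COMPLEMENT)[::-1]


def check_unique_ids(seqs) -> None:
    seen = set()
    for s in seqs:
        if s.id in seen:
            raise ValueError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)
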