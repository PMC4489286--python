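"""Core sequence containers shared by every analysis stage.

All coordinates are 0-based half-open and strand is +1/-1; conversion to the
1-based inclusive convention of GenBank/EMBL happens only inside
:mod:`bgcmine.genome_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: canonical amino-acid ordering used by every profile/emission table
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NUCLEOTIDES = set("ACGTN")


class BgcmineError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class Feature:
    """A located annotation on a sequence record.

    ``parts`` is a list of ``(start, end)`` pairs, 0-based half-open, stored
    in translation order (ascending on the + strand).  ``strand`` is +1 or -1.
    """

    kind: str
    parts: list[tuple[int, int]]
    strand: int = 1
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for start, end in self.parts:
            if not start < end:
                raise ValueError(
                    f"feature part ({start}, {end}) violates start < end"
                )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)


@dataclass
class SequenceRecord:
    """One replicon/contig (or one protein entry for protein FASTA input)."""

    id: str
    description: str = ""
    seq: str = ""
    topology: str = "linear"  # or "circular"
    features: list[Feature] = field(default_factory=list)
    #: protein FASTA input skips gene calling; each record is one gene
    is_protein: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class Gene:
    """A protein-coding gene with its translation."""

    gene_id: str
    record_id: str
    parts: list[tuple[int, int]]
    strand: int
    translation: str

    def __post_init__(self) -> None:
        if len(self.translation) < 1:
            raise ValueError(f"gene {self.gene_id}: empty translation")
        if "*" in self.translation:
            raise ValueError(
                f"gene {self.gene_id}: internal stop in translation"
            )

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)


@dataclass
class DomainHit:
    """A profile-model match on a protein.

    ``alignment`` maps 1-based consensus columns of the profile to 0-based
    residue indices of the protein, or to :data:`GAP` for deleted columns.
    Columns outside the aligned span are absent from the map.
    """

    gene_id: str
    profile: str
    env_start: int
    env_end: int
    bitscore: float
    alignment: dict[int, Optional[int]] = field(default_factory=dict)

    def overlaps(self, other: "DomainHit") -> bool:
        return self.env_start < other.env_end and other.env_start < self.env_end


#: sentinel stored in DomainHit.alignment for deleted consensus columns
GAP = None
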