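"""Aligned sequence I/O (FASTA).

Sequences are stored uppercase over the alphabet {A, C, G, T, -, N};
all members of an alignment must have equal length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, ReferentialError

__all__ = ["Alignment", "read_fasta", "write_fasta"]

_ALPHABET = set("ACGT-N")


@dataclass(frozen=True)
class Alignment(Mapping[str, str]):
    """Ordered, validated set of equal-length aligned sequences."""

    ids: tuple[str, ...]
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ReferentialError("alignment ids and sequences disagree")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, seq in self.seqs.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlphabetError(
                    f"sequence {sid!r}: illegal character(s) {sorted(bad)}"
                )

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "Alignment":
        ids = tuple(p[0] for p in pairs)
        if len(set(ids)) != len(ids):
            raise ReferentialError("duplicate sequence ids in alignment")
        return cls(ids=ids, seqs={sid: seq.upper() for sid, seq in pairs})

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def __getitem__(self, key: str) -> str:
        return self.seqs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; lowercase input is normalised."""
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment.from_pairs(pairs)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(alignment[sid]), id=sid, description="") for sid in alignment.ids
    ]
    SeqIO.write(records, str(path), "fasta")
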