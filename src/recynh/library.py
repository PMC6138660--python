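"""Screening-library I/O and 3'-end reference construction.

A pooled rec-YnH screen reads each mate of a pair from a constant plasmid
part into the 3' end of a fused ORF, so the reference an insert is mapped
against is the reverse complement of the last ``window`` (default 100)
nucleotides of each library coding sequence: position 0 of the reference
corresponds to the ORF's 3'-terminal base, and a correctly structured read
aligns at (or within a few bases of) that position.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Role",
    "LibraryEntry",
    "ThreePrimeReference",
    "reverse_complement",
    "load_library",
    "build_reference",
    "write_manifest",
]

_DNA_ALPHABET = frozenset("ACGTN")
# N is its own complement: no base is invented for ambiguous positions.
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Role(str, enum.Enum):
    """What a library member is fused to in the screen."""

    BAIT = "bait"  # DNA-binding-domain fusion, read 1
    PREY = "prey"  # activation-domain fusion, read 2
    RNA_BAIT = "rna_bait"  # MS2 stem-loop RNA fusion (three-hybrid), read 1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryEntry:
    """One bait/prey ORF or RNA motif of a screening library."""

    id: str
    display_name: str
    sequence: str
    role: Role

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("library entry id must be non-empty")
        if not self.sequence:
            raise ValueError(f"library entry {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"library entry {self.id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class ThreePrimeReference:
    """Reverse complement of the last ``window`` nt of one library sequence.

    ``ref_seq[0]`` is the complement of the ORF's 3'-terminal base, so a read
    entering the ORF from the constant primer aligns starting at offset 0.
    """

    target_id: str
    ref_seq: str
    window: int

    @property
    def ref_len(self) -> int:
        return len(self.ref_seq)


def load_library(fasta_path: str | Path, role: Role) -> list[LibraryEntry]:
    """Load a FASTA library, uppercasing sequences and applying ``role``.

    The entry id is the FASTA header token before the first whitespace; the
    full header is kept as the display name. Duplicate ids and non-ACGTN
    characters are hard errors naming the offending record.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    role = Role(role)
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate library id {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        entries.append(
            LibraryEntry(
                id=record.id,
                display_name=record.description or record.id,
                sequence=seq,
                role=role,
            )
        )
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return entries


def build_reference(
    entries: Sequence[LibraryEntry], window: int = 100
) -> list[ThreePrimeReference]:
    """Build per-entry 3'-end references (reverse complement of the final
    ``min(window, len)`` bases). Sequences shorter than the window simply
    yield shorter references."""
    if window < 1:
        raise ValueError("window must be >= 1")
    refs = []
    for entry in entries:
        tail = entry.sequence[-window:]
        refs.append(
            ThreePrimeReference(
                target_id=entry.id,
                ref_seq=reverse_complement(tail),
                window=window,
            )
        )
    return refs


def write_manifest(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write an id/role/length TSV manifest (for logging)."""
    with open(path, "w") as handle:
        handle.write("id\trole\tlength\n")
        for entry in entries:
            handle.write(f"{entry.id}\t{entry.role.value}\t{len(entry.sequence)}\n")
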