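"""Paired-end read processing: adapter filters, 3'-end mapping, pair counts.

Read structure. Both mates of a usable pair start with a constant primer
sequence (ending in the attB2 site for protein fusions) and continue into the
3' end of a fused ORF. Read 1 identifies the bait (or, in three-hybrid mode,
the RNA motif), read 2 the prey. A pair contributes one count to N(bait,
prey) only when both mates pass every filter:

1. adapter: the mode's constant sequence must match the read prefix with at
   most ``max_adapter_mismatches`` substitutions, and the remaining insert
   must be at least ``min_trimmed_len`` (15) nt;
2. mapping: the insert must align to exactly one 3'-end reference with
   E-value <= 1e-8 (best hit by E-value, ties on score across targets are
   discarded as ambiguous);
3. structure: the alignment must be forward-oriented and start within
   ``max_offset`` (10) nt of the ORF's 3' terminus (reference position 0).

Alignment scoring. Inserts are aligned locally against every candidate
reference sharing at least one 7-mer seed, with short-query parameters
(match +1, mismatch -3, gap open 5, gap extend 2). The expectation value is
the Karlin-Altschul estimate E = K * m * n * exp(-lambda * S) with the
standard ungapped constants for the +1/-3 scheme (lambda ~= 1.374,
K ~= 0.711) applied to the gapped score, m the insert length and n the total
reference length. This is a monotone surrogate for a full gapped-statistics
E-value: it preserves the behaviour of the 1e-8 cut-off for the exact or
near-exact matches this read structure produces. Note that under these
statistics a bare 15 nt exact match scores above 1e-8 for any realistic
reference set -- the 15 nt minimum is a trimming filter, not a mapping
guarantee; :func:`min_exact_match_length` reports the shortest perfect match
that can pass for a given reference size.
"""

from __future__ import annotations

import gzip
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import LibraryEntry, ThreePrimeReference, reverse_complement
from .matrix import CountMatrix

__all__ = [
    "AdapterSpec",
    "MappingHit",
    "MappingStats",
    "ReferenceIndex",
    "trim_adapter",
    "align_to_reference",
    "filter_hit",
    "match_rna_exact",
    "expected_rna_read1",
    "count_pairs",
    "min_exact_match_length",
    "R1_Y2H",
    "R2_Y2H",
    "R1_Y3H",
]

# Constant read-start sequences (two-hybrid R1/R2 end in the common attB2
# site; the three-hybrid read 1 starts in the MS2-side cloning flank).
R1_Y2H = "CGCTGCAGGTCGACGGATCTTAGTTACTTACCACTTTGTACAAGAAAGCTGGGT"
R2_Y2H = "GCAGCTCGAGCTCGATGGATCTTAGTTACTTACCACTTTGTACAAGAAAGCTGGGT"
R1_Y3H = "GCAGGCATGCAAGCTGCC"

# RNA motifs are cloned between constant flanks
# 5'-gaactagtggatccc-<motif>-ccgggcagcttgcatgcctg-3'; read 1 enters the insert
# in reverse complement through the 3' flank, whose last 17 nt sit inside the
# read-1 adapter. The first bases after the adapter are therefore the reverse
# complement of the leftover flank ("CCG"), then of the motif itself.
RNA_FLANK_5 = "GAACTAGTGGATCCC"
RNA_FLANK_3_REMAINDER = "CCG"

# Karlin-Altschul constants for the ungapped +1/-3 nucleotide scheme.
KA_LAMBDA = 1.374
KA_K = 0.711

DEFAULT_EVALUE_CUTOFF = 1e-8
DEFAULT_MAX_OFFSET = 10
SEED_WORD_SIZE = 7


@dataclass(frozen=True)
class AdapterSpec:
    """Constant-prefix filter parameters for one screening mode."""

    mode: str  # "Y2H" or "Y3H"
    read1_adapter: str
    read2_adapter: str
    min_trimmed_len: int = 15
    max_adapter_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("Y2H", "Y3H"):
            raise ValueError("mode must be 'Y2H' or 'Y3H'")

    @classmethod
    def y2h(cls, **kwargs) -> "AdapterSpec":
        return cls(mode="Y2H", read1_adapter=R1_Y2H, read2_adapter=R2_Y2H, **kwargs)

    @classmethod
    def y3h(cls, **kwargs) -> "AdapterSpec":
        return cls(mode="Y3H", read1_adapter=R1_Y3H, read2_adapter=R2_Y2H, **kwargs)


@dataclass(frozen=True)
class MappingHit:
    """Best local alignment of a trimmed insert to a 3'-end reference."""

    target_id: str
    score: int
    e_value: float
    ref_start_offset: int  # distance from reference position 0 (ORF 3' end)
    orientation: str  # "forward" or "reverse"


@dataclass
class MappingStats:
    """Per-file tallies at each filter of :func:`count_pairs`."""

    total_pairs: int = 0
    adapter_pass_pairs: int = 0
    read1_mapped: int = 0
    read2_mapped: int = 0
    usable_pairs: int = 0

    @property
    def usable_fraction(self) -> float:
        return self.usable_pairs / self.total_pairs if self.total_pairs else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for key in (
                "total_pairs",
                "adapter_pass_pairs",
                "read1_mapped",
                "read2_mapped",
                "usable_pairs",
            ):
                handle.write(f"{key}\t{getattr(self, key)}\n")
            handle.write(f"usable_fraction\t{self.usable_fraction:.6f}\n")


def min_exact_match_length(
    total_ref_len: int, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> int:
    """Shortest perfect match whose Karlin-Altschul E-value clears the cut-off.

    Solves K * k * n * exp(-lambda * k) <= cutoff for the smallest integer k.
    """
    k = 1
    while KA_K * k * total_ref_len * math.exp(-KA_LAMBDA * k) > evalue_cutoff:
        k += 1
        if k > 10_000:  # pragma: no cover - cutoff/λ misuse guard
            raise ValueError("no match length satisfies the E-value cut-off")
    return k


def trim_adapter(
    read_seq: str, adapter: str, min_len: int = 15, max_mm: int = 2
) -> str | None:
    """Return the insert after a prefix-anchored adapter match, or None.

    The adapter must match the start of the read with at most ``max_mm``
    substitutions (no indels); rejected reads (no match, or insert shorter
    than ``min_len``) return None -- a normal, tallied outcome.
    """
    if not read_seq:
        raise ValueError("empty read")
    if len(read_seq) < len(adapter):
        return None
    mismatches = sum(
        1 for a, b in zip(adapter, read_seq) if a != b
    )
    if mismatches > max_mm:
        return None
    insert = read_seq[len(adapter):]
    if len(insert) < min_len:
        return None
    return insert


class ReferenceIndex:
    """Seeded local aligner over a set of 3'-end references.

    A 7-mer exact seed restricts the candidate references; candidates are
    aligned in both orientations with the short-query scoring scheme and
    ranked by Karlin-Altschul E-value.
    """

    def __init__(
        self,
        refs: Sequence[ThreePrimeReference],
        evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
        word_size: int = SEED_WORD_SIZE,
    ) -> None:
        if not refs:
            raise ValueError("empty reference set")
        self.refs = list(refs)
        self.evalue_cutoff = evalue_cutoff
        self.word_size = word_size
        self.total_ref_len = sum(r.ref_len for r in refs)
        self._kmer_index: dict[str, set[int]] = defaultdict(set)
        for i, ref in enumerate(self.refs):
            seq = ref.ref_seq
            for j in range(len(seq) - word_size + 1):
                self._kmer_index[seq[j : j + word_size]].add(i)
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=1,
            mismatch_score=-3,
            open_gap_score=-5,
            extend_gap_score=-2,
        )

    def _candidates(self, seq: str) -> set[int]:
        found: set[int] = set()
        for j in range(len(seq) - self.word_size + 1):
            hits = self._kmer_index.get(seq[j : j + self.word_size])
            if hits:
                found |= hits
        return found

    def best_hit(self, trimmed: str) -> MappingHit | None:
        """Best-E-value hit for an insert, or None (no hit / ambiguous)."""
        queries = (("forward", trimmed), ("reverse", reverse_complement(trimmed)))
        best: MappingHit | None = None
        ambiguous = False
        for orientation, query in queries:
            for i in self._candidates(query):
                ref = self.refs[i]
                alignments = self._aligner.align(ref.ref_seq, query)
                if not alignments:
                    continue
                aln = alignments[0]
                score = int(aln.score)
                if score <= 0:
                    continue
                e_value = (
                    KA_K
                    * len(trimmed)
                    * self.total_ref_len
                    * math.exp(-KA_LAMBDA * score)
                )
                hit = MappingHit(
                    target_id=ref.target_id,
                    score=score,
                    e_value=e_value,
                    ref_start_offset=int(aln.aligned[0][0][0]),
                    orientation=orientation,
                )
                if best is None or hit.score > best.score:
                    best, ambiguous = hit, False
                elif hit.score == best.score and hit.target_id != best.target_id:
                    ambiguous = True
        if best is None or ambiguous:
            return None
        if best.e_value > self.evalue_cutoff:
            return None
        return best


def align_to_reference(
    trimmed: str,
    refs: Sequence[ThreePrimeReference],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> MappingHit | None:
    """One-shot form of :meth:`ReferenceIndex.best_hit` (builds the index)."""
    return ReferenceIndex(refs, evalue_cutoff=evalue_cutoff).best_hit(trimmed)


def filter_hit(hit: MappingHit, max_offset: int = DEFAULT_MAX_OFFSET) -> bool:
    """Keep only forward hits starting within ``max_offset`` nt of the 3' end."""
    return hit.orientation == "forward" and hit.ref_start_offset <= max_offset


def expected_rna_read1(entry: LibraryEntry) -> str:
    """Expected post-adapter read-1 sequence for a cloned RNA motif.

    Read 1 proceeds in reverse complement through the leftover 3' cloning
    flank, the motif, and finally the 5' flank.
    """
    insert = RNA_FLANK_5 + entry.sequence + RNA_FLANK_3_REMAINDER
    return reverse_complement(insert)


def match_rna_exact(
    trimmed: str, rna_entries: Sequence[LibraryEntry]
) -> str | None:
    """Exact, prefix-anchored match of a read-1 insert to an RNA motif.

    Some target RNAs are short, so only exact matches are accepted: the
    trimmed read must equal a prefix of exactly one motif's expected read-1
    sequence. No match or an ambiguous match returns None.
    """
    matched: str | None = None
    for entry in rna_entries:
        if expected_rna_read1(entry).startswith(trimmed):
            if matched is not None:
                return None  # ambiguous between motifs sharing a prefix
            matched = entry.id
    return matched


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_pairs(fastq_r1: str | Path, fastq_r2: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(fastq_r1) as h1, _open_text(fastq_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (title1, seq1, _q1), (title2, seq2, _q2) in zip(it1, it2, strict=True):
            id1 = title1.split()[0].removesuffix("/1")
            id2 = title2.split()[0].removesuffix("/2")
            if id1 != id2:
                raise ValueError(
                    f"desynchronised FASTQ mates: {id1!r} vs {id2!r}"
                )
            yield id1, seq1.upper(), seq2.upper()


def count_pairs(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    spec: AdapterSpec,
    bait_refs: Sequence[ThreePrimeReference] | None = None,
    prey_refs: Sequence[ThreePrimeReference] | None = None,
    rna_entries: Sequence[LibraryEntry] | None = None,
    condition: str | None = None,
    max_offset: int = DEFAULT_MAX_OFFSET,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> tuple[CountMatrix, MappingStats]:
    """Map synchronised paired FASTQ files to a usable-read count matrix.

    Read 1 is resolved against the bait references (Y2H) or RNA motifs
    (Y3H, exact matching); read 2 against the prey references. A pair
    increments N(bait, prey) only when both mates pass adapter, mapping and
    3'-structure filters; every input pair is assigned exactly one fate and
    tallied in the returned :class:`MappingStats`.
    """
    if prey_refs is None:
        raise ValueError("prey references are required")
    if spec.mode == "Y3H":
        if rna_entries is None:
            raise ValueError("Y3H mode requires the RNA motif library")
        bait_ids = [e.id for e in rna_entries]
        bait_index = None
    else:
        if bait_refs is None:
            raise ValueError("Y2H mode requires bait references")
        bait_ids = [r.target_id for r in bait_refs]
        bait_index = ReferenceIndex(bait_refs, evalue_cutoff=evalue_cutoff)
    prey_index = ReferenceIndex(prey_refs, evalue_cutoff=evalue_cutoff)
    prey_ids = [r.target_id for r in prey_refs]

    bait_pos = {b: i for i, b in enumerate(bait_ids)}
    prey_pos = {p: i for i, p in enumerate(prey_ids)}
    counts = np.zeros((len(bait_ids), len(prey_ids)), dtype=np.int64)
    stats = MappingStats()

    for _pair_id, seq1, seq2 in _read_pairs(fastq_r1, fastq_r2):
        stats.total_pairs += 1
        insert1 = trim_adapter(
            seq1, spec.read1_adapter, spec.min_trimmed_len, spec.max_adapter_mismatches
        )
        insert2 = trim_adapter(
            seq2, spec.read2_adapter, spec.min_trimmed_len, spec.max_adapter_mismatches
        )
        if insert1 is None or insert2 is None:
            continue
        stats.adapter_pass_pairs += 1

        if spec.mode == "Y3H":
            bait = match_rna_exact(insert1, rna_entries)  # type: ignore[arg-type]
        else:
            hit1 = bait_index.best_hit(insert1)  # type: ignore[union-attr]
            bait = (
                hit1.target_id if hit1 is not None and filter_hit(hit1, max_offset) else None
            )
        if bait is not None:
            stats.read1_mapped += 1

        hit2 = prey_index.best_hit(insert2)
        prey = hit2.target_id if hit2 is not None and filter_hit(hit2, max_offset) else None
        if prey is not None:
            stats.read2_mapped += 1

        if bait is not None and prey is not None:
            stats.usable_pairs += 1
            counts[bait_pos[bait], prey_pos[prey]] += 1

    matrix = CountMatrix(
        baits=bait_ids, preys=prey_ids, values=counts, condition=condition
    )
    return matrix, stats
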