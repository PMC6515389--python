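"""Domain types for SAM records, CIGAR strings and reference access.

This module is the coordinate-convention boundary for the whole package:
everything downstream works in 0-based half-open coordinates, and the
conversion to/from SAM's 1-based inclusive convention happens only here,
inside the pysam-backed I/O helpers.

Conventions enforced on ingest:

* secondary (0x100) and supplementary (0x800) records are discarded — the
  pipeline realigns clipped parts itself rather than consuming the
  aligner's split-alignment records;
* hard clips carry no sequence and are ignored for splitting; a record
  whose only clip is ``H`` behaves as a full-length mapped read;
* reference bases are uppercased on load, and ``N`` never matches any
  base during comparisons downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .errors import CigarError, ReferenceLookupError

__all__ = [
    "CigarOp",
    "ReferenceGenome",
    "AlignedSegmentView",
    "parse_cigar",
    "cigar_to_string",
    "soft_clip_profile",
    "reverse_complement",
    "iter_primary",
    "read_pairs",
]

#: CIGAR operations that consume query bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MDN=X")

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: an op code and a positive length."""

    op: str
    length: int


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string into an ordered op list.

    ``"*"`` (the unmapped convention) yields an empty list. A malformed
    token raises :class:`CigarError` naming the offending span.
    """
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for match in _CIGAR_TOKEN.finditer(text):
        if match.start() != pos:
            raise CigarError(f"malformed CIGAR near {text[pos:match.start()]!r} in {text!r}")
        length = int(match.group(1))
        if length < 1:
            raise CigarError(f"non-positive length in CIGAR token {match.group(0)!r}")
        ops.append(CigarOp(match.group(2), length))
        pos = match.end()
    if pos != len(text) or not ops:
        raise CigarError(f"malformed CIGAR near {text[pos:]!r} in {text!r}")
    return ops


def cigar_to_string(cigar: Iterable[CigarOp]) -> str:
    ops = list(cigar)
    if not ops:
        return "*"
    return "".join(f"{c.length}{c.op}" for c in ops)


def query_length(cigar: Iterable[CigarOp]) -> int:
    """Number of query bases consumed (M, I, S, =, X)."""
    return sum(c.length for c in cigar if c.op in QUERY_OPS)


def reference_span(cigar: Iterable[CigarOp]) -> int:
    """Number of reference bases consumed (M, D, N, =, X)."""
    return sum(c.length for c in cigar if c.op in REF_OPS)


def soft_clip_profile(cigar: list[CigarOp]) -> tuple[int, int, int]:
    """Return ``(leading_clip_len, trailing_clip_len, aligned_query_len)``.

    Leading/trailing are the soft-clip lengths at the respective read ends
    (0 if absent); the aligned query length sums M, I, =, X. Hard clips at
    the ends are transparent. An ``S`` in an interior position raises
    :class:`CigarError` — such records cannot be split into two pieces.
    """
    if not cigar:
        raise CigarError("empty CIGAR has no clip profile")
    core = [c for c in cigar if c.op != "H"]
    leading = trailing = 0
    if core and core[0].op == "S":
        leading = core[0].length
        core = core[1:]
    if core and core[-1].op == "S":
        trailing = core[-1].length
        core = core[:-1]
    if any(c.op == "S" for c in core):
        raise CigarError(f"interior soft clip in {cigar_to_string(cigar)}")
    aligned = sum(c.length for c in core if c.op in ("M", "I", "=", "X"))
    return leading, trailing, aligned


@dataclass
class ReferenceGenome:
    """Whole-loaded reference: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        if not seqs:
            raise ReferenceLookupError(f"no sequences found in {path}")
        return cls(seqs)

    def fetch_oriented(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Reference slice on ``[start, end)`` in the given orientation.

        Positions outside ``[0, L)`` are padded with ``N`` so the returned
        string always has length ``end - start``; strand ``'-'`` returns
        the reverse complement of the (padded) forward slice.
        """
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise ReferenceLookupError(f"unknown chromosome {chrom!r}") from None
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        length = len(seq)
        left_pad = max(0, min(end, 0) - start)
        right_pad = max(0, end - max(start, length))
        lo, hi = max(start, 0), min(end, length)
        core = seq[lo:hi] if lo < hi else ""
        out = "N" * left_pad + core + "N" * right_pad
        if strand == "-":
            out = reverse_complement(out)
        return out


@dataclass
class AlignedSegmentView:
    """The pipeline's view of one primary SAM record.

    Coordinates are 0-based half-open; ``sequence`` is the DNA string in
    read orientation exactly as stored in SAM (i.e. already
    reverse-complemented by the aligner for minus-strand records).
    """

    read_id: str
    mate_index: int
    sequence: str
    is_mapped: bool
    is_proper_pair: bool
    is_primary: bool
    strand: str
    mate_strand: str | None
    chrom: str | None
    ref_start: int
    ref_end: int
    cigar: list[CigarOp] = field(default_factory=list)
    quality: str | None = None

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedSegmentView":
        mapped = not rec.is_unmapped
        mate_strand: str | None = None
        if rec.is_paired and not rec.mate_is_unmapped:
            mate_strand = "-" if rec.mate_is_reverse else "+"
        cigar = parse_cigar(rec.cigarstring) if (mapped and rec.cigarstring) else []
        qual = None
        if rec.query_qualities is not None:
            qual = pysam.qualities_to_qualitystring(rec.query_qualities)
        return cls(
            read_id=rec.query_name,
            mate_index=2 if rec.is_read2 else 1,
            sequence=(rec.query_sequence or "").upper(),
            is_mapped=mapped,
            is_proper_pair=rec.is_proper_pair,
            is_primary=not (rec.is_secondary or rec.is_supplementary),
            strand="-" if (mapped and rec.is_reverse) else "+",
            mate_strand=mate_strand,
            chrom=rec.reference_name if mapped else None,
            ref_start=rec.reference_start if mapped else -1,
            ref_end=rec.reference_end if mapped else -1,
            cigar=cigar,
            quality=qual,
        )


def iter_primary(path: str) -> Iterator[AlignedSegmentView]:
    """Yield primary records from a SAM/BAM file, in file order.

    Secondary and supplementary alignments are dropped on ingest.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            yield AlignedSegmentView.from_pysam(rec)


def read_pairs(path: str) -> Iterator[tuple[AlignedSegmentView, AlignedSegmentView]]:
    """Group a name-sorted SAM into (mate1, mate2) primary pairs.

    Grouping is by read name (a dict keyed by name, so stray non-adjacent
    mates still pair up); singletons are silently dropped — desk-scale
    inputs are expected to be complete pairs.
    """
    pending: dict[str, AlignedSegmentView] = {}
    for rec in iter_primary(path):
        other = pending.pop(rec.read_id, None)
        if other is None:
            pending[rec.read_id] = rec
            continue
        r1, r2 = (other, rec) if other.mate_index == 1 else (rec, other)
        yield r1, r2
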