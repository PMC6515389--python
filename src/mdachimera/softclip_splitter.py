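"""Soft-clip splitting and pseudo paired-end reconstruction.

A terminally soft-clipped read is cut exactly at the clip boundary into a
*former* and a *following* subsection (read orientation, 0-based
half-open), and the two pieces are re-emitted as a pseudo read pair for
realignment. Clipped pieces that are too short to place uniquely are
filtered first: the per-chromosome minimum length is

    min_len(L) = floor(log4 L) + 1

(the number of bases needed for a sequence to be expected at most once in
a chromosome of L bp), with an absolute hard floor of 8 bp. A read whose
shorter subsection falls under max(hard_floor, min_len) is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import CigarError, PairingError
from .sam_model import AlignedSegmentView, soft_clip_profile

__all__ = [
    "SplitParams",
    "SubsectionPair",
    "min_softclip_length",
    "split_read",
    "has_qualifying_clip",
    "reconstruct_pairs",
    "encode_split_name",
    "parse_split_name",
]

#: separator used in pseudo-pair read names; must not occur in read ids.
_NAME_SEP = "|cm|"


@dataclass(frozen=True)
class SplitParams:
    """Length gates for splitting.

    hard_floor
        Absolute minimum subsection length in bp (default 8); subsections
        shorter than this multi-align with high probability regardless of
        chromosome size.
    both_ends_policy
        What to do with reads soft-clipped at both ends: ``"longer"``
        splits at the longer clip (the shorter clip's bases stay attached
        to the aligned part; ties go to the trailing clip), ``"skip"``
        drops the read.
    """

    hard_floor: int = 8
    both_ends_policy: str = "longer"

    def __post_init__(self) -> None:
        if self.hard_floor < 1:
            raise ValueError("hard_floor must be >= 1")
        if self.both_ends_policy not in ("longer", "skip"):
            raise ValueError(f"unknown both-ends policy {self.both_ends_policy!r}")


@dataclass
class SubsectionPair:
    """The two pieces of a split soft-clipped read.

    ``former`` precedes ``following`` in read orientation;
    ``former_end == following_start`` and the two sequences concatenate
    back to the origin read byte-for-byte. ``anchor`` records which piece
    was the originally aligned portion and where it mapped.
    """

    origin_read_id: str
    origin_mate: int
    origin_sequence: str
    former: str
    former_start: int
    former_end: int
    following: str
    following_start: int
    following_end: int
    anchor: str  # "former" or "following"
    anchor_chrom: str
    anchor_ref_start: int
    anchor_strand: str
    origin_quality: str | None = None

    def __post_init__(self) -> None:
        assert self.former_end == self.following_start
        assert self.former + self.following == self.origin_sequence

    @property
    def split_pos(self) -> int:
        return self.former_end


def min_softclip_length(chromosome_length: int) -> int:
    """Minimum allowed soft-clipped subsection length for a chromosome.

    floor(log4 L) + 1, computed exactly in integer arithmetic
    (floor(log4 L) == floor(log2 L) // 2, and floor(log2 L) is
    ``L.bit_length() - 1``).
    """
    if chromosome_length < 1:
        raise ValueError(f"chromosome length must be >= 1, got {chromosome_length}")
    return (chromosome_length.bit_length() - 1) // 2 + 1


def split_read(
    record: AlignedSegmentView,
    chrom_lengths: Mapping[str, int],
    params: SplitParams = SplitParams(),
) -> SubsectionPair | None:
    """Split a terminally soft-clipped record at the clip boundary.

    Returns ``None`` when the record has no terminal soft clip or when
    the shorter subsection falls below ``max(hard_floor, min_len)`` for
    the record's chromosome. Interior soft clips raise
    :class:`~mdachimera.errors.CigarError`.
    """
    if not (record.is_mapped and record.is_primary and record.sequence):
        raise ValueError("split_read requires a mapped primary record with sequence")
    leading, trailing, _ = soft_clip_profile(record.cigar)
    if leading == 0 and trailing == 0:
        return None
    if leading > 0 and trailing > 0:
        if params.both_ends_policy == "skip":
            return None
        # "longer": keep the single larger clip; ties go to the trailing clip
        if leading > trailing:
            trailing = 0
        else:
            leading = 0

    seq = record.sequence
    if leading > 0:
        boundary = leading
        anchor = "following"
    else:
        boundary = len(seq) - trailing
        anchor = "former"
    lengths = (boundary, len(seq) - boundary)

    floor = max(params.hard_floor, min_softclip_length(chrom_lengths[record.chrom]))
    if min(lengths) < floor:
        return None

    return SubsectionPair(
        origin_read_id=record.read_id,
        origin_mate=record.mate_index,
        origin_sequence=seq,
        former=seq[:boundary],
        former_start=0,
        former_end=boundary,
        following=seq[boundary:],
        following_start=boundary,
        following_end=len(seq),
        anchor=anchor,
        anchor_chrom=record.chrom,
        anchor_ref_start=record.ref_start,
        anchor_strand=record.strand,
        origin_quality=record.quality,
    )


def has_qualifying_clip(
    record: AlignedSegmentView,
    chrom_lengths: Mapping[str, int],
    params: SplitParams = SplitParams(),
) -> bool:
    """True when the record would yield a subsection pair under ``params``."""
    if not (record.is_mapped and record.is_primary and record.sequence):
        return False
    try:
        return split_read(record, chrom_lengths, params) is not None
    except CigarError:
        return False


def encode_split_name(pair: SubsectionPair) -> str:
    """Derived pseudo-pair name: origin id, mate, split position, lengths.

    Reversible by :func:`parse_split_name`; the separator is forbidden in
    origin read ids so collisions are impossible by construction.
    """
    rid = f"{pair.origin_read_id}/{pair.origin_mate}"
    if _NAME_SEP in rid:
        raise PairingError(f"read id {rid!r} contains reserved separator {_NAME_SEP!r}")
    return (
        f"{rid}{_NAME_SEP}{pair.split_pos}:"
        f"{len(pair.former)}:{len(pair.following)}"
    )


def parse_split_name(name: str) -> tuple[str, int, int, int, int]:
    """Inverse of :func:`encode_split_name`.

    Returns ``(origin_read_id, mate_index, split_pos, len_former,
    len_following)``.
    """
    try:
        rid, payload = name.rsplit(_NAME_SEP, 1)
        base, mate = rid.rsplit("/", 1)
        pos, l1, l2 = payload.split(":")
        return base, int(mate), int(pos), int(l1), int(l2)
    except ValueError:
        raise PairingError(f"unparseable pseudo-pair name {name!r}") from None


def reconstruct_pairs(
    splits: Iterable[SubsectionPair],
) -> Iterator[tuple[tuple[str, str, str], tuple[str, str, str]]]:
    """Pseudo paired-end records for realignment, one pair per split.

    Yields ``((name, seq, qual), (name, seq, qual))`` with mate 1 the
    former subsection and mate 2 the following subsection, order
    preserved. Quality strings are the origin read's corresponding
    slices (all-``I`` placeholders when the origin had none).
    """
    seen: set[str] = set()
    for pair in splits:
        name = encode_split_name(pair)
        assert name not in seen, f"pseudo-pair name collision: {name}"
        seen.add(name)
        qual = pair.origin_quality or "I" * len(pair.origin_sequence)
        yield (
            (name, pair.former, qual[: pair.former_end]),
            (name, pair.following, qual[pair.following_start:]),
        )
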