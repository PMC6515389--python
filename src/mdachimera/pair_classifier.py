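"""Stage A: pre-filter raw reads and partition aligned pairs.

Read pairs containing an ``N`` base are dropped before alignment; aligned
pairs are then partitioned into exactly one category each. Pairs whose two
mates map to the same strand of the same chromosome are insertion
chimeras — the template switch happened inside the unsequenced insert, so
the second mate fails to flip orientation. Soft-clipped reads that pass
the splitter's length gates go on to the split/realign stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import zip_longest
from typing import Iterable, Mapping

from .errors import PairingError
from .sam_model import AlignedSegmentView
from .softclip_splitter import SplitParams, has_qualifying_clip

__all__ = ["PairCategory", "PairDisposition", "prefilter_reads", "classify_pair"]


class PairCategory(Enum):
    PROPER_PAIR_REMOVED = "PROPER_PAIR_REMOVED"
    UNMAPPED_REMOVED = "UNMAPPED_REMOVED"
    INSERTION_CHIMERA = "INSERTION_CHIMERA"
    SOFTCLIP_CANDIDATE = "SOFTCLIP_CANDIDATE"
    OTHER_DISCORDANT = "OTHER_DISCORDANT"


@dataclass
class PairDisposition:
    category: PairCategory
    r1: AlignedSegmentView
    r2: AlignedSegmentView


_SENTINEL = object()


def prefilter_reads(
    mate1: Iterable[str], mate2: Iterable[str]
) -> tuple[list[tuple[str, str]], int]:
    """Drop raw read pairs in which either mate contains an ``N`` base.

    Takes the two mate sequence streams; returns the surviving pairs
    (unchanged, order preserved) and the dropped-pair count. Streams of
    unequal cardinality raise :class:`PairingError`.
    """
    kept: list[tuple[str, str]] = []
    dropped = 0
    for s1, s2 in zip_longest(mate1, mate2, fillvalue=_SENTINEL):
        if s1 is _SENTINEL or s2 is _SENTINEL:
            raise PairingError("mate streams have different cardinality")
        if "N" in s1.upper() or "N" in s2.upper():
            dropped += 1
        else:
            kept.append((s1, s2))
    return kept, dropped


def classify_pair(
    r1: AlignedSegmentView,
    r2: AlignedSegmentView,
    chrom_lengths: Mapping[str, int],
    split_params: SplitParams = SplitParams(),
    max_insertion_distance: int | None = None,
) -> PairDisposition:
    """Assign exactly one category to a primary read pair.

    Precedence: unmapped mate -> UNMAPPED_REMOVED; both mates on the same
    strand of the same chromosome -> INSERTION_CHIMERA (insertion
    classification wins even when soft clips are present, keeping the
    rate denominator clean); a qualifying terminal soft clip on either
    mate -> SOFTCLIP_CANDIDATE (also when the pair is flagged proper);
    proper pair -> PROPER_PAIR_REMOVED; anything else, including
    inter-chromosomal same-strand pairs -> OTHER_DISCORDANT.

    ``max_insertion_distance`` optionally caps the start-to-start
    distance for insertion calls (default: unlimited).
    """
    if r1.read_id != r2.read_id:
        raise PairingError(f"mate read ids differ: {r1.read_id!r} vs {r2.read_id!r}")

    if not (r1.is_mapped and r2.is_mapped):
        return PairDisposition(PairCategory.UNMAPPED_REMOVED, r1, r2)

    if r1.chrom == r2.chrom and r1.strand == r2.strand:
        dist = abs(r1.ref_start - r2.ref_start)
        if max_insertion_distance is None or dist <= max_insertion_distance:
            return PairDisposition(PairCategory.INSERTION_CHIMERA, r1, r2)

    if has_qualifying_clip(r1, chrom_lengths, split_params) or has_qualifying_clip(
        r2, chrom_lengths, split_params
    ):
        return PairDisposition(PairCategory.SOFTCLIP_CANDIDATE, r1, r2)

    if r1.is_proper_pair and r2.is_proper_pair:
        return PairDisposition(PairCategory.PROPER_PAIR_REMOVED, r1, r2)

    return PairDisposition(PairCategory.OTHER_DISCORDANT, r1, r2)
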