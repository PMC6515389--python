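"""Stage C: the two-sided cyclical junction-overlap search and validity gates.

A split read whose two subsections both realign is a potential single-end
chimera: DIRECT when the subsections sit on the same strand, INVERTED when
on opposite strands. The template switch that created the chimera was
mediated by a short shared sequence (microhomology), so a genuine chimera
carries an *overlap*: the end of the former subsection also occurs in the
reference immediately before the junction of the following subsection (or,
mirrored, the head of the following subsection occurs right after the
former's junction).

The search takes a fixed comparison window (31 nt) on each side:

* tail side — the last 31 nt of the former subsection (N-padded in front
  if shorter) against the 31 reference bases immediately preceding the
  following subsection's first aligned base, read in the following
  subsection's orientation;
* head side — the first 31 nt of the following subsection against the 31
  reference bases immediately after the former subsection's last aligned
  base, in the former's orientation.

Each side is scanned cyclically, shortening the candidate overlap by one
base per loop from 30 bp down to the 3 bp minimum, and accepts the first
(longest) length with at most one mismatch, provided the mismatch is not
at the first base of the overlap. N never matches anything. When both
sides yield an overlap the longer wins (ties: tail).

A candidate becomes a valid chimera only if both subsections are at least
30 bp, the two hits sit on the same chromosome 25–5000 bp apart, and an
overlap of at least 3 bp was found.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .realigner import SubsectionHit
from .sam_model import ReferenceGenome
from .softclip_splitter import SubsectionPair

__all__ = [
    "OverlapParams",
    "Orientation",
    "Overlap",
    "CandidateChimera",
    "ChimeraCall",
    "genomic_distance",
    "search_overlap_tail",
    "search_overlap_head",
    "resolve_overlap",
    "build_candidate",
    "validate_candidate",
]


@dataclass(frozen=True)
class OverlapParams:
    """Tunable thresholds of the overlap search and validity gates.

    window
        Comparison window in nt (default 31): how much of the subsection
        end / reference context is cut for the cyclical scan.
    max_overlap / min_overlap
        Accepted overlap lengths, default 30 and 3 bp ("longer than two
        bases"); the window is one base wider than max_overlap so the
        31st base can support the mismatch-position rule.
    max_mismatches
        Mismatches tolerated inside an overlap (default 1); never at the
        overlap's first base.
    min_subsection
        Minimum subsection length for a valid chimera (default 30 bp).
    distance_min / distance_max
        Allowed genomic distance between the subsections, default
        25–5000 bp.
    distance_mode
        ``"start"`` (default): absolute difference of the two hits'
        reference start coordinates; ``"gap"``: bases between the nearer
        ends (0 when the hits touch or overlap).
    """

    window: int = 31
    max_overlap: int = 30
    min_overlap: int = 3
    max_mismatches: int = 1
    min_subsection: int = 30
    distance_min: int = 25
    distance_max: int = 5000
    distance_mode: str = "start"

    def __post_init__(self) -> None:
        if not (1 <= self.min_overlap <= self.max_overlap <= self.window):
            raise ValueError("need 1 <= min_overlap <= max_overlap <= window")
        if self.distance_min > self.distance_max:
            raise ValueError("distance_min > distance_max")
        if self.distance_mode not in ("start", "gap"):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")


class Orientation(Enum):
    DIRECT = "DIRECT"
    INVERTED = "INVERTED"


@dataclass(frozen=True)
class Overlap:
    sequence: str
    length: int
    side: str  # "tail" or "head"


@dataclass
class CandidateChimera:
    origin: SubsectionPair
    former_hit: SubsectionHit
    following_hit: SubsectionHit
    orientation: Orientation
    genomic_distance: int | None
    overlap: Overlap | None = None


@dataclass
class ChimeraCall:
    """A validated chimera, ready for the output table."""

    read_id: str
    mate_index: int
    type: str  # DIRECT, INVERTED (or INSERTION from stage A)
    chrom: str
    former_start: int
    former_end: int
    former_strand: str
    following_start: int
    following_end: int
    following_strand: str
    distance: int
    overlap_len: int
    overlap_seq: str
    overlap_side: str


def genomic_distance(
    former_hit: SubsectionHit,
    following_hit: SubsectionHit,
    mode: str = "start",
) -> int | None:
    """Physical genome distance between the two hits, or None across chromosomes."""
    if former_hit.chrom != following_hit.chrom:
        return None
    if mode == "start":
        return abs(former_hit.ref_start - following_hit.ref_start)
    lo = min(former_hit.ref_end, following_hit.ref_end)
    hi = max(former_hit.ref_start, following_hit.ref_start)
    return max(0, hi - lo)


def _bases_match(a: str, b: str) -> bool:
    # N never matches, not even another N
    return a == b and a != "N"


def _scan(read_window: str, ref_window: str, p: OverlapParams, side: str) -> Overlap | None:
    """Shared cyclical scan; windows are aligned so the junction-proximal
    ends coincide (tail: suffixes compared; head: prefixes compared)."""
    w = p.window
    for k in range(p.max_overlap, p.min_overlap - 1, -1):
        if side == "tail":
            t, e = read_window[w - k :], ref_window[w - k :]
        else:
            t, e = read_window[:k], ref_window[:k]
        if not _bases_match(t[0], e[0]):
            continue  # a mismatch at the overlap's first base is prohibited
        mismatches = sum(1 for x, y in zip(t[1:], e[1:]) if not _bases_match(x, y))
        if mismatches <= p.max_mismatches:
            return Overlap(t, k, side)
    return None


def search_overlap_tail(
    former_seq: str,
    following_hit: SubsectionHit,
    ref: ReferenceGenome,
    p: OverlapParams = OverlapParams(),
) -> Overlap | None:
    """Overlap assumed at the end of the former subsection.

    The last ``window`` nt of the former subsection (N-padded in front if
    shorter) are cyclically compared with the ``window`` reference bases
    immediately preceding the following subsection's first aligned base,
    in the following subsection's reading orientation: positions
    ``[start-window, start)`` forward for a '+' hit, ``(end, end+window]``
    reverse-complemented for a '-' hit. Out-of-range context is N-padded.
    Returns the accepted overlap as read sequence, or None.
    """
    w = p.window
    read_window = former_seq[-w:].rjust(w, "N")
    if following_hit.strand == "+":
        ref_window = ref.fetch_oriented(
            following_hit.chrom, following_hit.ref_start - w, following_hit.ref_start, "+"
        )
    else:
        ref_window = ref.fetch_oriented(
            following_hit.chrom, following_hit.ref_end, following_hit.ref_end + w, "-"
        )
    return _scan(read_window, ref_window, p, "tail")


def search_overlap_head(
    following_seq: str,
    former_hit: SubsectionHit,
    ref: ReferenceGenome,
    p: OverlapParams = OverlapParams(),
) -> Overlap | None:
    """Mirror search: overlap assumed at the head of the following subsection.

    The first ``window`` nt of the following subsection (N-padded at the
    back if shorter) against the ``window`` reference bases immediately
    after the former subsection's last aligned base in the former's
    orientation: ``(end, end+window]`` forward for '+', ``[start-window,
    start)`` reverse-complemented for '-'.
    """
    w = p.window
    read_window = following_seq[:w].ljust(w, "N")
    if former_hit.strand == "+":
        ref_window = ref.fetch_oriented(
            former_hit.chrom, former_hit.ref_end, former_hit.ref_end + w, "+"
        )
    else:
        ref_window = ref.fetch_oriented(
            former_hit.chrom, former_hit.ref_start - w, former_hit.ref_start, "-"
        )
    return _scan(read_window, ref_window, p, "head")


def resolve_overlap(tail: Overlap | None, head: Overlap | None) -> Overlap | None:
    """Pick the final overlap: the longer of the two; ties go to tail."""
    if tail is None:
        return head
    if head is None:
        return tail
    return head if head.length > tail.length else tail


def build_candidate(
    origin: SubsectionPair,
    former_hit: SubsectionHit,
    following_hit: SubsectionHit,
    ref: ReferenceGenome,
    p: OverlapParams = OverlapParams(),
) -> CandidateChimera:
    """Assemble a candidate: orientation, distance, and both-sided search."""
    orientation = (
        Orientation.DIRECT
        if former_hit.strand == following_hit.strand
        else Orientation.INVERTED
    )
    dist = genomic_distance(former_hit, following_hit, p.distance_mode)
    cand = CandidateChimera(origin, former_hit, following_hit, orientation, dist)
    if former_hit.chrom == following_hit.chrom:
        tail = search_overlap_tail(origin.former, following_hit, ref, p)
        head = search_overlap_head(origin.following, former_hit, ref, p)
        cand.overlap = resolve_overlap(tail, head)
    return cand


def validate_candidate(
    c: CandidateChimera, p: OverlapParams = OverlapParams()
) -> tuple[ChimeraCall | None, str | None]:
    """Apply the validity gates; returns (call, None) or (None, reason).

    Rejection reasons are reported with fixed precedence:
    ``subsection`` < ``distance`` < ``overlap``.
    """
    if min(len(c.origin.former), len(c.origin.following)) < p.min_subsection:
        return None, "subsection"
    if c.genomic_distance is None or not (
        p.distance_min <= c.genomic_distance <= p.distance_max
    ):
        return None, "distance"
    if c.overlap is None or c.overlap.length < p.min_overlap:
        return None, "overlap"
    call = ChimeraCall(
        read_id=c.origin.origin_read_id,
        mate_index=c.origin.origin_mate,
        type=c.orientation.value,
        chrom=c.former_hit.chrom,
        former_start=c.former_hit.ref_start,
        former_end=c.former_hit.ref_end,
        former_strand=c.former_hit.strand,
        following_start=c.following_hit.ref_start,
        following_end=c.following_hit.ref_end,
        following_strand=c.following_hit.strand,
        distance=c.genomic_distance,
        overlap_len=c.overlap.length,
        overlap_seq=c.overlap.sequence,
        overlap_side=c.overlap.side,
    )
    return call, None
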