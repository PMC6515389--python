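"""Stage B part 2: place reconstructed subsections back on the reference.

Two routes are provided. The built-in aligner is a deterministic
exact-match scanner over both strands of every chromosome: exactly one
occurrence gives a unique hit, zero gives none, and multi-mapped queries
are marked and discarded downstream rather than placed at random (random
multi-hit placement is a known source of count discrepancies). The
external adapter shells out to any paired-end aligner via a command
template and consumes its SAM; mismatch/indel-tolerant realignment only
arrives through that route.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConfigurationError, JoinError, RealignmentError
from .sam_model import ReferenceGenome, iter_primary, reverse_complement
from .softclip_splitter import SubsectionPair, encode_split_name, parse_split_name, reconstruct_pairs

__all__ = [
    "AlignOutcome",
    "SubsectionHit",
    "naive_align",
    "external_align",
    "collate_hits",
    "realign_naive",
]


class AlignOutcome(Enum):
    UNIQUE = "unique"
    UNMAPPED = "unmapped"
    MULTI = "multi"


@dataclass(frozen=True)
class SubsectionHit:
    """A subsection's placement on the reference (0-based half-open)."""

    role: str  # "former" or "following"
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    unique: bool = True


def _occurrences(hay: str, needle: str) -> Iterator[int]:
    pos = hay.find(needle)
    while pos != -1:
        yield pos
        pos = hay.find(needle, pos + 1)


def naive_align(
    query: str, ref: ReferenceGenome, role: str = "former", max_hits: int = 2
) -> tuple[AlignOutcome, SubsectionHit | None]:
    """Exhaustive exact-match search over both strands of every chromosome.

    ``N`` never matches, so a query containing ``N`` is unmapped. A query
    equal to its own reverse complement found at one locus counts as two
    (strand-ambiguous) hits and is therefore multi-mapped. Scanning stops
    once ``max_hits`` occurrences are seen.
    """
    if not ref.sequences:
        raise ConfigurationError("empty reference")
    if not query:
        raise ValueError("empty query")
    query = query.upper()
    if "N" in query:
        return AlignOutcome.UNMAPPED, None

    hits: list[SubsectionHit] = []
    rc = reverse_complement(query)
    for chrom in ref.sequences:  # insertion order: deterministic
        seq = ref.sequences[chrom]
        for strand, needle in (("+", query), ("-", rc)):
            for pos in _occurrences(seq, needle):
                hits.append(
                    SubsectionHit(role, chrom, pos, pos + len(query), strand)
                )
                if len(hits) >= max_hits:
                    return AlignOutcome.MULTI, None
    if not hits:
        return AlignOutcome.UNMAPPED, None
    return AlignOutcome.UNIQUE, hits[0]


def realign_naive(
    splits: Sequence[SubsectionPair], ref: ReferenceGenome
) -> tuple[list[tuple[SubsectionPair, SubsectionHit, SubsectionHit]], int]:
    """Align both subsections of each split with the built-in aligner.

    Splits with an unmapped or multi-mapped subsection are dropped;
    returns the surviving ``(split, former_hit, following_hit)`` triples
    in input order and the dropped count.
    """
    triples = []
    dropped = 0
    for pair in splits:
        o1, h1 = naive_align(pair.former, ref, role="former")
        o2, h2 = naive_align(pair.following, ref, role="following")
        if o1 is AlignOutcome.UNIQUE and o2 is AlignOutcome.UNIQUE:
            triples.append((pair, h1, h2))
        else:
            dropped += 1
    return triples, dropped


def external_align(
    splits: Sequence[SubsectionPair],
    ref_path: str | Path,
    command_template: str,
    workdir: str | Path | None = None,
) -> str:
    """Run an external paired-end aligner on the reconstructed pseudo pairs.

    ``command_template`` must contain the placeholders ``{ref}``,
    ``{fq1}``, ``{fq2}`` and ``{out}`` (output SAM path); it is executed
    through the shell, e.g.::

        bash -c 'bwa aln {ref} {fq1} > 1.sai && ...' > {out}

    Nonzero exit or unreadable output raises :class:`RealignmentError`
    with the captured diagnostics. Returns the output SAM path.
    """
    for placeholder in ("{ref}", "{fq1}", "{fq2}", "{out}"):
        if placeholder not in command_template:
            raise ConfigurationError(
                f"aligner command template lacks placeholder {placeholder}"
            )
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="mdachim_"))
    workdir.mkdir(parents=True, exist_ok=True)
    fq1, fq2 = workdir / "subsections_1.fq", workdir / "subsections_2.fq"
    out_sam = workdir / "realigned.sam"
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for (n1, s1, q1), (n2, s2, q2) in reconstruct_pairs(splits):
            f1.write(f"@{n1}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{n2}\n{s2}\n+\n{q2}\n")
    cmd = command_template.format(
        ref=shlex.quote(str(ref_path)),
        fq1=shlex.quote(str(fq1)),
        fq2=shlex.quote(str(fq2)),
        out=shlex.quote(str(out_sam)),
    )
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RealignmentError(
            f"aligner exited {proc.returncode}: {cmd}\nstderr:\n{proc.stderr[-2000:]}"
        )
    if not out_sam.is_file() or out_sam.stat().st_size == 0:
        raise RealignmentError(f"aligner produced no output at {out_sam}")
    return str(out_sam)


def collate_hits(
    sam_path: str,
    splits: Iterable[SubsectionPair],
) -> tuple[list[tuple[SubsectionPair, SubsectionHit, SubsectionHit]], int]:
    """Join realigned subsection records back to their origin splits.

    Primary records are matched by the reconstruct_pairs name scheme;
    mate 1 is the former subsection and mate 2 the following. Origins
    with an unmapped (or absent) subsection are dropped and counted.
    Unparseable names raise :class:`JoinError` citing the name.
    """
    index: dict[str, SubsectionPair] = {}
    order: list[str] = []
    for pair in splits:
        name = encode_split_name(pair)
        index[name] = pair
        order.append(name)

    found: dict[str, dict[str, SubsectionHit]] = {}
    for rec in iter_primary(sam_path):
        try:
            parse_split_name(rec.read_id)
        except Exception:
            raise JoinError(f"realigned record name {rec.read_id!r} does not parse") from None
        if rec.read_id not in index:
            raise JoinError(f"realigned record {rec.read_id!r} has no origin split")
        if not rec.is_mapped:
            continue
        role = "former" if rec.mate_index == 1 else "following"
        found.setdefault(rec.read_id, {})[role] = SubsectionHit(
            role, rec.chrom, rec.ref_start, rec.ref_end, rec.strand
        )

    triples = []
    dropped = 0
    for name in order:
        hits = found.get(name, {})
        if "former" in hits and "following" in hits:
            triples.append((index[name], hits["former"], hits["following"]))
        else:
            dropped += 1
    return triples, dropped
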