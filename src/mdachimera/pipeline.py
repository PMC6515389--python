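"""End-to-end chimera detection, summary statistics and filter-list output.

``detect`` wires the stages together: pair classification, soft-clip
splitting, realignment (built-in exact aligner or an external command),
overlap search and validation. It writes a fixed-column chimera TSV, a
read-id filter list (for downstream removal of chimeric pairs before SV
calling, e.g. with Picard FilterSamReads) and a JSON report. The pipeline
is deterministic: identical inputs and parameters give byte-identical
outputs.

The chimeric rate is pair-level: a read pair counts once toward the
numerator if it is an insertion chimera or if either mate yields at least
one valid single-end chimera, divided by the total number of read pairs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ChimeraError
from .overlap_engine import ChimeraCall, OverlapParams, build_candidate, validate_candidate
from .pair_classifier import PairCategory, classify_pair
from .realigner import collate_hits, external_align, realign_naive
from .sam_model import ReferenceGenome, read_pairs
from .softclip_splitter import SplitParams, split_read

__all__ = [
    "ChimeraReport",
    "DetectResult",
    "TSV_COLUMNS",
    "detect",
    "chimeric_rate",
    "inverted_share",
    "emit_filter_list",
    "stats_from_tsv",
]

log = logging.getLogger("mdachimera")

TSV_COLUMNS = [
    "read_id",
    "type",
    "chrom",
    "former_start",
    "former_end",
    "former_strand",
    "following_start",
    "following_end",
    "following_strand",
    "distance",
    "overlap_len",
    "overlap_seq",
    "overlap_side",
]


@dataclass
class ChimeraReport:
    """Per-run counts and the pair-level chimeric rate."""

    direct: int = 0
    inverted: int = 0
    insertion: int = 0
    total_pairs: int = 0
    chimeric_pairs: int = 0
    chimeric_rate: float = 0.0
    inverted_share_pct: float | None = None
    stage_counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class DetectResult:
    tsv_path: str
    filter_path: str
    report_path: str
    report: ChimeraReport
    calls: list[ChimeraCall]


def chimeric_rate(chimeric_pair_count: int, total_pairs: int) -> float:
    """Chimeric read pairs divided by total read pairs (0 when empty)."""
    if chimeric_pair_count < 0 or total_pairs < 0:
        raise ValueError("counts must be non-negative")
    if total_pairs < chimeric_pair_count:
        raise ValueError("chimeric pair count exceeds total pairs")
    return chimeric_pair_count / total_pairs if total_pairs else 0.0


def inverted_share(direct: int, inverted: int) -> float | None:
    """Inverted chimeras as a percentage of single-end chimeras.

    Returns None (absent) when there are no single-end chimeras at all.
    """
    if direct < 0 or inverted < 0:
        raise ValueError("counts must be non-negative")
    total = direct + inverted
    if total == 0:
        return None
    return 100.0 * inverted / total


def _insertion_call(r1, r2) -> ChimeraCall:
    return ChimeraCall(
        read_id=r1.read_id,
        mate_index=0,
        type="INSERTION",
        chrom=r1.chrom,
        former_start=r1.ref_start,
        former_end=r1.ref_end,
        former_strand=r1.strand,
        following_start=r2.ref_start,
        following_end=r2.ref_end,
        following_strand=r2.strand,
        distance=abs(r1.ref_start - r2.ref_start),
        overlap_len=0,
        overlap_seq=".",
        overlap_side=".",
    )


def detect(
    sam_path: str,
    ref_path: str,
    out_prefix: str,
    overlap_params: OverlapParams = OverlapParams(),
    split_params: SplitParams = SplitParams(),
    max_insertion_distance: int | None = None,
    aligner_cmd: str | None = None,
) -> DetectResult:
    """Run the full pipeline on a name-grouped SAM against a FASTA reference.

    With ``aligner_cmd`` unset the built-in exact-match aligner places the
    subsections; otherwise the command template is invoked on the
    reconstructed pseudo pairs. Outputs ``<prefix>.chimeras.tsv``,
    ``<prefix>.filter.txt`` and ``<prefix>.report.json``; partial outputs
    are removed on failure.
    """
    out_prefix = str(out_prefix)
    tsv_path = out_prefix + ".chimeras.tsv"
    filter_path = out_prefix + ".filter.txt"
    report_path = out_prefix + ".report.json"
    try:
        return _detect(
            sam_path, ref_path, tsv_path, filter_path, report_path,
            overlap_params, split_params, max_insertion_distance, aligner_cmd,
        )
    except Exception:
        for path in (tsv_path, filter_path, report_path):
            Path(path).unlink(missing_ok=True)
        raise


def _detect(
    sam_path, ref_path, tsv_path, filter_path, report_path,
    p: OverlapParams, sp: SplitParams, max_ins_dist, aligner_cmd,
) -> DetectResult:
    ref = ReferenceGenome.from_fasta(ref_path)
    lengths = ref.lengths

    category_counts = {c.name: 0 for c in PairCategory}
    insertion_calls: list[ChimeraCall] = []
    splits = []
    total_pairs = 0

    for r1, r2 in read_pairs(sam_path):
        total_pairs += 1
        disp = classify_pair(r1, r2, lengths, sp, max_ins_dist)
        category_counts[disp.category.name] += 1
        if disp.category is PairCategory.INSERTION_CHIMERA:
            insertion_calls.append(_insertion_call(r1, r2))
        elif disp.category is PairCategory.SOFTCLIP_CANDIDATE:
            for mate in (r1, r2):
                try:
                    pair = split_read(mate, lengths, sp) if mate.is_mapped else None
                except ChimeraError:
                    pair = None
                if pair is not None:
                    splits.append(pair)

    if total_pairs == 0:
        log.warning("empty SAM input: rate reported as 0")

    if aligner_cmd is None:
        triples, dropped = realign_naive(splits, ref)
    else:
        sam_out = external_align(splits, ref_path, aligner_cmd)
        triples, dropped = collate_hits(sam_out, splits)

    single_end_calls: list[ChimeraCall] = []
    rejections = {"subsection": 0, "distance": 0, "overlap": 0}
    for pair, former_hit, following_hit in triples:
        cand = build_candidate(pair, former_hit, following_hit, ref, p)
        call, reason = validate_candidate(cand, p)
        if call is not None:
            single_end_calls.append(call)
        else:
            rejections[reason] += 1

    calls = single_end_calls + insertion_calls
    direct = sum(1 for c in single_end_calls if c.type == "DIRECT")
    inverted = sum(1 for c in single_end_calls if c.type == "INVERTED")
    insertion = len(insertion_calls)
    single_end_pair_ids = {c.read_id for c in single_end_calls}
    chimeric_pairs = len(single_end_pair_ids) + insertion

    report = ChimeraReport(
        direct=direct,
        inverted=inverted,
        insertion=insertion,
        total_pairs=total_pairs,
        chimeric_pairs=chimeric_pairs,
        chimeric_rate=chimeric_rate(chimeric_pairs, total_pairs),
        inverted_share_pct=inverted_share(direct, inverted),
        stage_counts={
            "pair_categories": category_counts,
            "splits": len(splits),
            "realign_dropped": dropped,
            "realigned": len(triples),
            "rejections": rejections,
        },
        params={
            "overlap": asdict(p),
            "split": asdict(sp),
            "max_insertion_distance": max_ins_dist,
            "aligner": aligner_cmd or "naive",
        },
        inputs={"sam": str(sam_path), "ref": str(ref_path)},
    )

    _write_tsv(tsv_path, calls)
    emit_filter_list(tsv_path, filter_path)
    Path(report_path).write_text(report.to_json() + "\n")
    for stage, n in report.stage_counts.items():
        log.info("%s: %s", stage, n)
    return DetectResult(tsv_path, filter_path, report_path, report, calls)


def _row_id(call: ChimeraCall) -> str:
    # single-end calls carry the mate suffix; insertion rows are pair-level
    if call.type == "INSERTION":
        return call.read_id
    return f"{call.read_id}/{call.mate_index}"


def _write_tsv(path: str, calls: list[ChimeraCall]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    _row_id(c), c.type, c.chrom,
                    c.former_start, c.former_end, c.former_strand,
                    c.following_start, c.following_end, c.following_strand,
                    c.distance, c.overlap_len, c.overlap_seq, c.overlap_side,
                ]
            )


def _iter_tsv(path: str):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            if row.get("type") is None or None in row or row["type"] == "":
                raise ChimeraError(f"{path}: malformed row at line {lineno}")
            yield row


def _pair_id(read_id: str) -> str:
    base, sep, mate = read_id.rpartition("/")
    if sep and mate in ("1", "2"):
        return base
    return read_id


def emit_filter_list(tsv_path: str, out_path: str) -> str:
    """Unique, sorted pair-level read ids of all chimeras in the table.

    Insertion rows carry the pair id directly; single-end rows drop the
    mate suffix, so both mates of every chimeric pair are covered by one
    line, ready for read-name-based filtering.
    """
    ids = {_pair_id(row["read_id"]) for row in _iter_tsv(tsv_path)}
    with open(out_path, "w") as fh:
        for rid in sorted(ids):
            fh.write(rid + "\n")
    return out_path


def stats_from_tsv(tsv_path: str) -> dict[str, int]:
    """Recompute per-type call counts and distinct chimeric pairs from a table."""
    counts = {"DIRECT": 0, "INVERTED": 0, "INSERTION": 0}
    pairs = set()
    for row in _iter_tsv(tsv_path):
        counts[row["type"]] += 1
        pairs.add(_pair_id(row["read_id"]))
    counts["chimeric_pairs"] = len(pairs)
    return counts
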