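"""Small factories shared by the unit tests."""

from mdachimera import AlignedSegmentView, parse_cigar


def make_view(
    read_id="r1",
    mate=1,
    seq="ACGT" * 25 + "A",
    mapped=True,
    proper=False,
    strand="+",
    mate_strand="-",
    chrom="sim1",
    start=1000,
    cigar=None,
):
    cigar = cigar if cigar is not None else f"{len(seq)}M"
    ops = parse_cigar(cigar) if mapped else []
    span = sum(c.length for c in ops if c.op in "MDN=X")
    return AlignedSegmentView(
        read_id=read_id,
        mate_index=mate,
        sequence=seq,
        is_mapped=mapped,
        is_proper_pair=proper,
        is_primary=True,
        strand=strand if mapped else "+",
        mate_strand=mate_strand,
        chrom=chrom if mapped else None,
        ref_start=start if mapped else -1,
        ref_end=start + span if mapped else -1,
        cigar=ops,
    )
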