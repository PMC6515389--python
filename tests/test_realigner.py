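import numpy as np
import pysam
import pytest

from mdachimera import (
    AlignOutcome,
    ReferenceGenome,
    collate_hits,
    external_align,
    naive_align,
    realign_naive,
    reverse_complement,
    split_read,
)
from mdachimera.errors import ConfigurationError, JoinError, RealignmentError
from mdachimera.softclip_splitter import encode_split_name

from helpers import make_view
from oracles import oracle_scan_occurrences


def _random_ref(rng, n=400):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_unique_forward_hit():
    ref = ReferenceGenome({"c": "TTTTTTGATTACATTTTTT"})
    outcome, hit = naive_align("GATTACA", ref)
    assert outcome is AlignOutcome.UNIQUE
    assert (hit.chrom, hit.ref_start, hit.ref_end, hit.strand) == ("c", 6, 13, "+")


def test_unique_reverse_hit():
    ref = ReferenceGenome({"c": "TTTTTT" + reverse_complement("GATTACA") + "TTTTTT"})
    outcome, hit = naive_align("GATTACA", ref)
    assert outcome is AlignOutcome.UNIQUE
    assert (hit.ref_start, hit.strand) == (6, "-")


def test_duplicated_query_is_multi_mapped():
    ref = ReferenceGenome({"c": "AAGATTACAGGGGGGGGGGGATTACAAA"})
    outcome, hit = naive_align("GATTACA", ref)
    assert outcome is AlignOutcome.MULTI
    assert hit is None


def test_absent_and_n_queries_are_unmapped():
    ref = ReferenceGenome({"c": "ACGTACGTACGT"})
    assert naive_align("GGGGGG", ref)[0] is AlignOutcome.UNMAPPED
    assert naive_align("ACGNAC", ref)[0] is AlignOutcome.UNMAPPED


def test_empty_reference_is_configuration_error():
    with pytest.raises(ConfigurationError):
        naive_align("ACGT", ReferenceGenome({}))


def test_naive_align_matches_literal_scan_oracle():
    """Hit/none/multi verdicts agree with a per-position both-strand scan."""
    rng = np.random.default_rng(7)
    for _ in range(60):
        seq = _random_ref(rng, 300)
        ref = ReferenceGenome({"c": seq})
        if rng.random() < 0.7:  # mostly queries drawn from the reference
            start = int(rng.integers(0, 290))
            q = seq[start : start + int(rng.integers(6, 12))]
            if rng.random() < 0.5:
                q = reverse_complement(q)
        else:
            q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 9))))
        occurrences = oracle_scan_occurrences(seq, q)
        outcome, hit = naive_align(q, ref)
        if len(occurrences) == 0:
            assert outcome is AlignOutcome.UNMAPPED
        elif len(occurrences) == 1:
            assert outcome is AlignOutcome.UNIQUE
            assert (hit.ref_start, hit.strand) == occurrences[0]
        else:
            assert outcome is AlignOutcome.MULTI


def _two_splits():
    chrom_lengths = {"c": 200_000}
    rec1 = make_view(read_id="u", seq="ACGT" * 25 + "A", cigar="60M41S", chrom="c")
    rec2 = make_view(read_id="v", seq="TGCA" * 25 + "T", cigar="41S60M", chrom="c")
    return [split_read(rec1, chrom_lengths), split_read(rec2, chrom_lengths)]


def _write_realigned_sam(path, rows):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 200_000}]}
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for name, mate, mapped, pos in rows:
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.flag = 0x1 | (0x40 if mate == 1 else 0x80) | (0 if mapped else 0x4)
            rec.query_sequence = "ACGTACGTAC"
            if mapped:
                rec.reference_id = 0
                rec.reference_start = pos
                rec.cigarstring = "10M"
            out.write(rec)


def test_collate_hits_joins_and_drops(tmp_path):
    splits = _two_splits()
    names = [encode_split_name(s) for s in splits]
    sam = tmp_path / "realigned.sam"
    # first origin fully mapped, second has an unmapped former subsection
    _write_realigned_sam(
        sam,
        [(names[0], 1, True, 100), (names[0], 2, True, 500),
         (names[1], 1, False, 0), (names[1], 2, True, 900)],
    )
    triples, dropped = collate_hits(str(sam), splits)
    assert dropped == 1
    [(pair, former, following)] = triples
    assert pair.origin_read_id == "u"
    assert (former.ref_start, following.ref_start) == (100, 500)
    assert (former.role, following.role) == ("former", "following")


def test_collate_hits_rejects_foreign_names(tmp_path):
    sam = tmp_path / "bad.sam"
    _write_realigned_sam(sam, [("not-a-split-name", 1, True, 5)])
    with pytest.raises(JoinError):
        collate_hits(str(sam), _two_splits())


def test_external_align_stub_round_trip(tmp_path):
    """The adapter contract: template runs, output SAM joins back to origins."""
    splits = _two_splits()
    names = [encode_split_name(s) for s in splits]
    prepared = tmp_path / "prepared.sam"
    _write_realigned_sam(
        prepared,
        [(names[0], 1, True, 11), (names[0], 2, True, 22),
         (names[1], 1, True, 33), (names[1], 2, True, 44)],
    )
    ref = tmp_path / "ref.fa"
    ref.write_text(">c\nACGT\n")
    template = "cat " + str(prepared) + " > {out} && true {ref} {fq1} {fq2}"
    out_sam = external_align(splits, ref, template, workdir=tmp_path / "wd")
    triples, dropped = collate_hits(out_sam, splits)
    assert dropped == 0
    assert [t[1].ref_start for t in triples] == [11, 33]


def test_external_align_missing_placeholder():
    with pytest.raises(ConfigurationError):
        external_align([], "ref.fa", "aligner {ref} {fq1} {fq2}")


def test_external_align_failing_command(tmp_path):
    with pytest.raises(RealignmentError):
        external_align(
            _two_splits(), tmp_path / "r.fa",
            "/nonexistent-binary {ref} {fq1} {fq2} {out}",
            workdir=tmp_path / "wd",
        )


def test_realign_naive_drops_ambiguous_subsections():
    rng = np.random.default_rng(11)
    seq = _random_ref(rng, 2000)
    chrom_lengths = {"c": len(seq)}
    # embed one split read: former at 100, following at 700
    former, following = seq[100:160], seq[700:741]
    rec = make_view(read_id="ok", seq=former + following, cigar="60M41S",
                    chrom="c", start=100)
    good = split_read(rec, chrom_lengths)
    # a split whose former subsection occurs twice
    dup = seq[300:340]
    seq2 = seq[:1500] + dup + seq[1540:]
    ref = ReferenceGenome({"c": seq2})
    rec2 = make_view(read_id="amb", seq=dup + following, cigar="40M41S",
                     chrom="c", start=300)
    bad = split_read(rec2, chrom_lengths)
    triples, dropped = realign_naive([good, bad], ref)
    assert dropped == 1
    assert [t[0].origin_read_id for t in triples] == ["ok"]
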