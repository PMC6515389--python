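import numpy as np
import pytest

from mdachimera import (
    Overlap,
    OverlapParams,
    ReferenceGenome,
    genomic_distance,
    resolve_overlap,
    search_overlap_head,
    search_overlap_tail,
    validate_candidate,
)
from mdachimera.overlap_engine import CandidateChimera, Orientation
from mdachimera.realigner import SubsectionHit
from mdachimera.softclip_splitter import SubsectionPair

from oracles import oracle_head, oracle_tail, rc

P = OverlapParams()


def hit(role="former", start=1000, end=1060, strand="+", chrom="c"):
    return SubsectionHit(role, chrom, start, end, strand)


def test_genomic_distance():
    assert genomic_distance(hit(start=1000), hit(start=1025, end=1066)) == 25
    assert genomic_distance(hit(start=1000), hit(start=1000)) == 0
    assert genomic_distance(hit(chrom="a"), hit(chrom="b")) is None


def test_genomic_distance_gap_mode():
    former = hit(start=1000, end=1060)
    following = hit(start=1100, end=1141)
    assert genomic_distance(former, following, mode="gap") == 40
    assert genomic_distance(former, hit(start=1030, end=1071), mode="gap") == 0


def _planted_tail_ref(rng, omer, follow_start, n=600):
    seq = list(rng.choice(list("ACGT"), size=n))
    seq[follow_start - len(omer) : follow_start] = list(omer)
    return "".join(seq)


def test_tail_overlap_found_at_planted_length():
    rng = np.random.default_rng(3)
    omer = "GATTACA"
    former = "".join(rng.choice(list("ACGT"), size=53)) + omer
    seq = _planted_tail_ref(rng, omer, follow_start=300)
    ref = ReferenceGenome({"c": seq})
    follow = hit("following", 300, 341, "+")
    found = search_overlap_tail(former, follow, ref, P)
    expected = oracle_tail(former, follow, seq)
    assert found is not None and found.length == expected
    assert found.length >= len(omer)
    assert found.sequence == former[-found.length :]
    assert found.side == "tail"


def test_tail_overlap_on_minus_strand_following():
    rng = np.random.default_rng(4)
    omer = "TTGCAAC"
    former = "".join(rng.choice(list("ACGT"), size=50)) + omer
    seq = list(rng.choice(list("ACGT"), size=600))
    # following maps '-' at [300, 341); its upstream context in read
    # orientation is [341, 341+w) reverse-complemented
    seq[341 : 341 + len(omer)] = list(rc(omer))
    seq = "".join(seq)
    ref = ReferenceGenome({"c": seq})
    follow = hit("following", 300, 341, "-")
    found = search_overlap_tail(former, follow, ref, P)
    assert found is not None
    assert found.length == oracle_tail(former, follow, seq)
    assert found.length >= len(omer)


def test_two_base_agreement_is_not_an_overlap():
    # agreement of exactly 2 bases at the junction: below the 3 bp minimum
    former = "A" * 29 + "CA"
    seq = "T" * 269 + "G" * 29 + "CA" + "T" * 300
    ref = ReferenceGenome({"c": seq})
    follow = hit("following", 300, 341, "+")
    assert search_overlap_tail(former, follow, ref, P) is None
    assert oracle_tail(former, follow, seq) is None


def test_mismatch_at_overlap_start_rejects_that_length():
    """A 10-base agreement whose first base mismatches is rejected; the
    9-base suffix (mismatch now gone) is accepted."""
    w = P.window
    former = "A" * 21 + "GATTACAGGT"  # last 10 bases
    context = "CATTACAGGT"  # first base differs: G vs C
    seq = "T" * (300 - w) + ("T" * (w - 10) + context) + "G" * 300
    # make sure nothing longer matches by accident: former's earlier bases
    # are A, context bases before the 10-mer are T
    ref = ReferenceGenome({"c": seq})
    follow = hit("following", 300, 341, "+")
    found = search_overlap_tail(former, follow, ref, P)
    assert found is not None
    assert found.length == 9
    assert found.sequence == "ATTACAGGT"
    assert oracle_tail(former, follow, seq) == 9


def test_head_overlap_found_and_matches_oracle():
    rng = np.random.default_rng(6)
    omer = "TTGCA"
    following = omer + "".join(rng.choice(list("ACGT"), size=36))
    seq = list(rng.choice(list("ACGT"), size=600))
    seq[160 : 160 + len(omer)] = list(omer)  # right after former's end
    seq = "".join(seq)
    ref = ReferenceGenome({"c": seq})
    former = hit("former", 100, 160, "+")
    found = search_overlap_head(following, former, ref, P)
    assert found is not None
    assert found.length == oracle_head(following, former, seq)
    assert found.length >= len(omer)
    assert found.side == "head"


def test_head_overlap_with_minus_strand_former():
    rng = np.random.default_rng(8)
    omer = "CCGTAGA"
    following = omer + "".join(rng.choice(list("ACGT"), size=34))
    seq = list(rng.choice(list("ACGT"), size=600))
    # former maps '-' at [100, 160); the context after its last read base
    # is [100-w, 100) reverse-complemented, so the omer sits at [100-o, 100)
    seq[100 - len(omer) : 100] = list(rc(omer))
    seq = "".join(seq)
    ref = ReferenceGenome({"c": seq})
    former = hit("former", 100, 160, "-")
    found = search_overlap_head(following, former, ref, P)
    assert found is not None
    assert found.length == oracle_head(following, former, seq)
    assert found.length >= len(omer)


def test_resolve_overlap_prefers_longer_then_tail():
    t5 = Overlap("AAAAA", 5, "tail")
    h9 = Overlap("AAAAAAAAA", 9, "head")
    t6, h6 = Overlap("A" * 6, 6, "tail"), Overlap("C" * 6, 6, "head")
    assert resolve_overlap(t5, None) is t5
    assert resolve_overlap(None, h9) is h9
    assert resolve_overlap(t5, h9) is h9
    assert resolve_overlap(t6, h6) is t6  # documented tie-break


def _candidate(l1=64, l2=37, distance=300, overlap_len=7, same_chrom=True,
               orientation=Orientation.DIRECT):
    seq = "".join("ACGT"[i % 4] for i in range(l1 + l2))
    pair = SubsectionPair(
        origin_read_id="r", origin_mate=1, origin_sequence=seq,
        former=seq[:l1], former_start=0, former_end=l1,
        following=seq[l1:], following_start=l1, following_end=l1 + l2,
        anchor="former", anchor_chrom="c", anchor_ref_start=1000, anchor_strand="+",
    )
    fh = SubsectionHit("former", "c", 1000, 1000 + l1, "+")
    chrom2 = "c" if same_chrom else "d"
    strand2 = "+" if orientation is Orientation.DIRECT else "-"
    lh = SubsectionHit("following", chrom2, 1000 + distance, 1000 + distance + l2, strand2)
    dist = distance if same_chrom else None
    ov = Overlap("GATTACA"[:overlap_len], overlap_len, "tail") if overlap_len else None
    return CandidateChimera(pair, fh, lh, orientation, dist, ov)


def test_valid_candidate_becomes_call():
    call, reason = validate_candidate(_candidate(), P)
    assert reason is None
    assert call.type == "DIRECT"
    assert (call.distance, call.overlap_len) == (300, 7)


def test_inverted_orientation_propagates():
    call, _ = validate_candidate(_candidate(orientation=Orientation.INVERTED), P)
    assert call.type == "INVERTED"
    assert call.former_strand != call.following_strand


@pytest.mark.parametrize(
    "kwargs,reason",
    [
        (dict(l1=29, l2=72), "subsection"),
        (dict(distance=24), "distance"),
        (dict(distance=5001), "distance"),
        (dict(same_chrom=False), "distance"),
        (dict(overlap_len=0), "overlap"),
        # precedence: subsection is reported before distance and overlap
        (dict(l1=29, l2=72, distance=24, overlap_len=0), "subsection"),
        (dict(distance=24, overlap_len=0), "distance"),
    ],
)
def test_rejection_reasons_and_precedence(kwargs, reason):
    call, got = validate_candidate(_candidate(**kwargs), P)
    assert call is None
    assert got == reason


@pytest.mark.parametrize(
    "kwargs",
    [dict(distance=25), dict(distance=5000), dict(overlap_len=3),
     dict(l1=30, l2=71), dict(l1=71, l2=30)],
)
def test_boundary_values_are_valid(kwargs):
    call, reason = validate_candidate(_candidate(**kwargs), P)
    assert reason is None and call is not None


def test_relaxing_gates_never_loses_calls():
    """Monotonicity: smaller min_overlap or a wider distance window can
    only add valid calls on a fixed candidate set."""
    rng = np.random.default_rng(9)
    cands = [
        _candidate(
            l1=int(rng.integers(20, 70)),
            l2=int(rng.integers(20, 70)),
            distance=int(rng.integers(0, 6000)),
            overlap_len=int(rng.integers(0, 12)),
        )
        for _ in range(200)
    ]
    def n_valid(p):
        return sum(validate_candidate(c, p)[0] is not None for c in cands)

    base = OverlapParams()
    assert n_valid(OverlapParams(min_overlap=2)) >= n_valid(base)
    assert n_valid(OverlapParams(distance_min=10, distance_max=6000)) >= n_valid(base)


def test_search_matches_bruteforce_oracle_on_random_triples():
    """Randomized cross-check of both search sides against the oracle."""
    rng = np.random.default_rng(10)
    for _ in range(300):
        n = int(rng.integers(120, 1000))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        ref = ReferenceGenome({"c": seq})
        former_seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 80))))
        following_seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 80))))
        strand_f = "+" if rng.integers(2) else "-"
        strand_l = "+" if rng.integers(2) else "-"
        s1 = int(rng.integers(0, n))
        s2 = int(rng.integers(0, n))
        former_hit = SubsectionHit("former", "c", s1, s1 + len(former_seq), strand_f)
        follow_hit = SubsectionHit("following", "c", s2, s2 + len(following_seq), strand_l)

        tail = search_overlap_tail(former_seq, follow_hit, ref, P)
        head = search_overlap_head(following_seq, former_hit, ref, P)
        assert (tail.length if tail else None) == oracle_tail(former_seq, follow_hit, seq)
        assert (head.length if head else None) == oracle_head(following_seq, former_hit, seq)
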