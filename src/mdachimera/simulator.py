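"""Ground-truth simulator: planted MDA chimeras on a synthetic reference.

The generator emulates the template-switch mechanism that produces
chimeras during phi29 multiple displacement amplification: a displaced
3'-end re-anneals at a short shared sequence (the junction *overlap*) on
a nearby template and elongation continues there, concatenating two
nearby genomic segments into one read. Three classes are planted:

* DIRECT — single-end chimera, both segments on the same strand;
* INVERTED — single-end chimera, segments on opposite strands;
* INSERTION — the switch happened in the unsequenced insert, so the two
  mates of a pair map to the same strand.

Planting proceeds in two phases. First the junction geometry is chosen
and the overlap is written into the reference: the o-mer ending the first
segment's read-oriented slice is copied immediately upstream (in read
orientation) of the second segment's start, so the read stays an exact
concatenation of two slices of the *final* reference and the tail-side
overlap search must find exactly that o-mer. An interval registry keeps
loci and junction windows of different plants at least ``2 * window``
apart (bounded retry, then error). Second, after all edits, every read —
chimeric, insertion, normal — is materialized as a slice of the final
reference, and a truth-derived SAM is produced (each single-end chimeric
read emitted soft-clipped at its first locus) so the whole pipeline can
be exercised with no aligner at all.

Reads are error-free by default; a uniform substitution rate is available
to exercise the one-mismatch tolerance of the overlap search. Defaults
(101 bp reads, 25–5000 bp junction distances, 3–30 bp overlaps, >=30 bp
subsections) mirror the regime the detector targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, SimulationError
from .sam_model import ReferenceGenome, reverse_complement

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "simulate", "make_reference"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 42
    ref_length: int = 200_000
    read_length: int = 101
    insert_mean: float = 300.0
    insert_sd: float = 25.0
    n_normal: int = 700
    n_direct: int = 100
    n_inverted: int = 100
    n_insertion: int = 100
    distance_range: tuple[int, int] = (25, 5000)
    overlap_range: tuple[int, int] = (3, 30)
    subsection_min: int = 30
    error_rate: float = 0.0
    chrom: str = "sim1"
    window: int = 31

    def __post_init__(self) -> None:
        if self.ref_length < 10 * self.read_length:
            raise ConfigurationError(
                f"reference length {self.ref_length} < 10x read length"
            )
        if 2 * self.subsection_min > self.read_length:
            raise ConfigurationError("subsection_min too large for read length")


@dataclass
class SimTruth:
    """Planted ground truth for one read (single-end classes) or pair."""

    read_id: str
    cls: str  # NORMAL, DIRECT, INVERTED, INSERTION
    breakpoint: int | None  # split position in read orientation
    locus1: tuple[str, int, int, str]
    locus2: tuple[str, int, int, str] | None
    overlap_len: int
    overlap_seq: str
    distance: int | None


@dataclass
class _SamRec:
    name: str
    flag: int
    pos: int
    cigar: str
    seq: str
    mate_pos: int


@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: ReferenceGenome
    records: list[tuple[_SamRec, _SamRec]]
    truths: list[SimTruth]

    def emit(self, prefix: str | Path) -> dict[str, str]:
        """Write FASTA, paired FASTQ, truth TSV and the truth-derived SAM.

        Returns a dict of output paths keyed by kind.
        """
        prefix = str(prefix)
        paths = {
            "fasta": prefix + ".ref.fa",
            "fq1": prefix + ".reads_1.fq",
            "fq2": prefix + ".reads_2.fq",
            "truth": prefix + ".truth.tsv",
            "sam": prefix + ".truth.sam",
        }
        chrom = self.config.chrom
        seq = self.reference.sequences[chrom]
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

        with open(paths["fq1"], "w") as f1, open(paths["fq2"], "w") as f2:
            for r1, r2 in self.records:
                for rec, fh in ((r1, f1), (r2, f2)):
                    read = rec.seq
                    if rec.flag & FLAG_REVERSE:
                        read = reverse_complement(read)
                    fh.write(f"@{rec.name}\n{read}\n+\n{'I' * len(read)}\n")

        with open(paths["truth"], "w") as fh:
            fh.write(
                "read_id\tclass\tbreakpoint\tchrom1\tstart1\tend1\tstrand1"
                "\tchrom2\tstart2\tend2\tstrand2\toverlap_len\toverlap_seq\tdistance\n"
            )
            for t in self.truths:
                l2 = t.locus2 or (".", ".", ".", ".")
                fh.write(
                    f"{t.read_id}\t{t.cls}\t{t.breakpoint if t.breakpoint is not None else '.'}"
                    f"\t{t.locus1[0]}\t{t.locus1[1]}\t{t.locus1[2]}\t{t.locus1[3]}"
                    f"\t{l2[0]}\t{l2[1]}\t{l2[2]}\t{l2[3]}"
                    f"\t{t.overlap_len}\t{t.overlap_seq or '.'}"
                    f"\t{t.distance if t.distance is not None else '.'}\n"
                )

        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"SN": chrom, "LN": len(seq)}]}
        )
        with pysam.AlignmentFile(paths["sam"], "w", header=header) as out:
            for r1, r2 in self.records:
                for rec in (r1, r2):
                    a = pysam.AlignedSegment(header)
                    a.query_name = rec.name
                    a.flag = rec.flag
                    a.reference_id = 0
                    a.reference_start = rec.pos
                    a.mapping_quality = 60
                    a.cigarstring = rec.cigar
                    a.query_sequence = rec.seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
                    a.next_reference_id = 0
                    a.next_reference_start = rec.mate_pos
                    out.write(a)
        return paths


def make_reference(config: SimConfig, rng: np.random.Generator | None = None) -> ReferenceGenome:
    """Uniform random A/C/G/T sequence; deterministic for a seed."""
    rng = rng or np.random.default_rng(config.seed)
    arr = rng.choice(_BASES, size=config.ref_length)
    return ReferenceGenome({config.chrom: arr.tobytes().decode("ascii")})


class _Registry:
    """Occupied reference intervals, kept ``pad`` bp apart."""

    def __init__(self, pad: int) -> None:
        self.pad = pad
        self.intervals: list[tuple[int, int]] = []

    def clear_of_others(self, *candidates: tuple[int, int]) -> bool:
        for lo, hi in candidates:
            for a, b in self.intervals:
                if lo < b + self.pad and a - self.pad < hi:
                    return False
        return True

    def reserve(self, *intervals: tuple[int, int]) -> None:
        self.intervals.extend(intervals)


def _disjoint(*intervals: tuple[int, int]) -> bool:
    ivs = sorted(intervals)
    return all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))


@dataclass
class _Plant:
    cls: str
    a: int
    l1: int
    b: int
    l2: int
    strand1: str
    strand2: str
    o: int
    d: int
    mate2_pos: int


def _plan_single_end(
    cls: str, cfg: SimConfig, rng: np.random.Generator, registry: _Registry
) -> _Plant:
    """Choose junction geometry for one planted chimera (bounded retry)."""
    rl, L = cfg.read_length, cfg.ref_length
    for _ in range(500):
        l1 = int(rng.integers(cfg.subsection_min, rl - cfg.subsection_min + 1))
        l2 = rl - l1
        o_hi = min(cfg.overlap_range[1], l1 - 1)
        o = int(rng.integers(cfg.overlap_range[0], o_hi + 1))
        d = int(rng.integers(cfg.distance_range[0], cfg.distance_range[1] + 1))
        strand1 = "+" if rng.integers(2) else "-"
        strand2 = strand1 if cls == "DIRECT" else ("-" if strand1 == "+" else "+")
        a = int(rng.integers(cfg.window, L - cfg.window - rl))
        b = a + d if rng.integers(2) else a - d
        isize = int(np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd), rl + 20, None))
        mate2_pos = a + isize - rl if strand1 == "+" else a + l1 - isize

        locus1 = (a, a + l1)
        locus2 = (b, b + l2)
        edit = (b - o, b) if strand2 == "+" else (b + l2, b + l2 + o)
        regions = (locus1, locus2, edit)
        if min(r[0] for r in regions) < 0 or max(r[1] for r in regions) > L:
            continue
        if mate2_pos < 0 or mate2_pos + rl > L:
            continue
        if not _disjoint(*regions):
            continue
        if not registry.clear_of_others(*regions):
            continue
        registry.reserve(*regions)
        return _Plant(cls, a, l1, b, l2, strand1, strand2, o, d, mate2_pos)
    raise SimulationError(f"could not place a {cls} chimera after 500 attempts")


def _apply_edit(ref: bytearray, plant: _Plant) -> None:
    """Copy the junction o-mer into the reference upstream of locus 2."""
    a, l1, b, l2, o = plant.a, plant.l1, plant.b, plant.l2, plant.o
    if plant.strand1 == "+":
        omer = ref[a + l1 - o : a + l1].decode()
    else:
        omer = reverse_complement(ref[a : a + o].decode())
    if plant.strand2 == "+":
        ref[b - o : b] = omer.encode()
    else:
        ref[b + l2 : b + l2 + o] = reverse_complement(omer).encode()


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = bytearray(seq.encode())
    for i in range(len(arr)):
        if rng.random() < rate:
            choices = [b for b in b"ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
    return arr.decode()


def simulate(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate reference, reads, truth and the truth-derived alignments."""
    rng = np.random.default_rng(config.seed)
    ref_bytes = bytearray(
        rng.choice(_BASES, size=config.ref_length).tobytes()
    )
    rl, chrom, L = config.read_length, config.chrom, config.ref_length
    registry = _Registry(pad=2 * config.window)

    # phase 1: geometry and reference edits
    plants: list[_Plant] = []
    for cls, n in (("DIRECT", config.n_direct), ("INVERTED", config.n_inverted)):
        for _ in range(n):
            plant = _plan_single_end(cls, config, rng, registry)
            _apply_edit(ref_bytes, plant)
            plants.append(plant)

    # phase 2: materialize reads from the final reference
    ref = ReferenceGenome({chrom: ref_bytes.decode()})
    records: list[tuple[_SamRec, _SamRec]] = []
    truths: list[SimTruth] = []

    def slice_oriented(start: int, end: int, strand: str) -> str:
        return ref.fetch_oriented(chrom, start, end, strand)

    counters = {"DIRECT": 0, "INVERTED": 0}
    for plant in plants:
        cls = plant.cls
        counters[cls] += 1
        rid = f"sim:{cls.lower()}:{counters[cls]:05d}"
        s1 = slice_oriented(plant.a, plant.a + plant.l1, plant.strand1)
        s2 = slice_oriented(plant.b, plant.b + plant.l2, plant.strand2)
        read = _add_errors(s1 + s2, config.error_rate, rng)
        if plant.strand1 == "+":
            stored, cigar = read, f"{plant.l1}M{plant.l2}S"
            flag1 = FLAG_PAIRED | FLAG_PROPER | FLAG_READ1 | FLAG_MATE_REVERSE
            flag2 = FLAG_PAIRED | FLAG_PROPER | FLAG_READ2 | FLAG_REVERSE
        else:
            stored, cigar = reverse_complement(read), f"{plant.l2}S{plant.l1}M"
            flag1 = FLAG_PAIRED | FLAG_PROPER | FLAG_READ1 | FLAG_REVERSE
            flag2 = FLAG_PAIRED | FLAG_PROPER | FLAG_READ2 | FLAG_MATE_REVERSE
        mate2_seq = ref.sequences[chrom][plant.mate2_pos : plant.mate2_pos + rl]
        r1 = _SamRec(rid, flag1, plant.a, cigar, stored, plant.mate2_pos)
        r2 = _SamRec(rid, flag2, plant.mate2_pos, f"{rl}M", mate2_seq, plant.a)
        records.append((r1, r2))
        omer = s1[-plant.o :]
        truths.append(
            SimTruth(
                rid, cls, plant.l1,
                (chrom, plant.a, plant.a + plant.l1, plant.strand1),
                (chrom, plant.b, plant.b + plant.l2, plant.strand2),
                plant.o, omer, plant.d,
            )
        )

    for i in range(config.n_insertion):
        rid = f"sim:insertion:{i + 1:05d}"
        strand = "+" if rng.integers(2) else "-"
        dd = int(rng.integers(rl + 25, rl + 2001))
        p1 = int(rng.integers(0, L - dd - rl))
        p2 = p1 + dd
        base = FLAG_PAIRED
        rev = FLAG_REVERSE | FLAG_MATE_REVERSE if strand == "-" else 0
        r1 = _SamRec(
            rid, base | FLAG_READ1 | rev, p1, f"{rl}M",
            ref.sequences[chrom][p1 : p1 + rl], p2,
        )
        r2 = _SamRec(
            rid, base | FLAG_READ2 | rev, p2, f"{rl}M",
            ref.sequences[chrom][p2 : p2 + rl], p1,
        )
        records.append((r1, r2))
        truths.append(
            SimTruth(
                rid, "INSERTION", None,
                (chrom, p1, p1 + rl, strand), (chrom, p2, p2 + rl, strand),
                0, "", dd,
            )
        )

    for i in range(config.n_normal):
        rid = f"sim:normal:{i + 1:05d}"
        isize = int(np.clip(rng.normal(config.insert_mean, config.insert_sd), 2 * rl + 10, None))
        p = int(rng.integers(0, L - isize))
        fwd_first = bool(rng.integers(2))
        fwd = _SamRec(
            rid,
            FLAG_PAIRED | FLAG_PROPER | FLAG_MATE_REVERSE
            | (FLAG_READ1 if fwd_first else FLAG_READ2),
            p, f"{rl}M", ref.sequences[chrom][p : p + rl], p + isize - rl,
        )
        rev = _SamRec(
            rid,
            FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE
            | (FLAG_READ2 if fwd_first else FLAG_READ1),
            p + isize - rl, f"{rl}M",
            ref.sequences[chrom][p + isize - rl : p + isize], p,
        )
        records.append((fwd, rev) if fwd_first else (rev, fwd))
        truths.append(
            SimTruth(rid, "NORMAL", None, (chrom, p, p + isize, "+"), None, 0, "", None)
        )

    return SimulatedDataset(config, ref, records, truths)
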