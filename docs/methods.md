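# Methods

## Model

Chimeric reads in MDA data arise from template switching: during
strand-displacement synthesis a displaced 3′ end re-anneals at a short
sequence shared with a nearby template (the junction *overlap*, a
microhomology of a few to a few tens of bases) and elongation continues
there. The product concatenates two genomic segments that are close on the
chromosome but not contiguous. Depending on which strand the 3′ end lands
on, the two segments end up on the same strand (direct chimera) or
opposite strands (inverted chimera); when the switch falls in the
unsequenced insert of a paired-end fragment, the signature is instead a
read pair whose mates map to the same strand (insertion chimera).

The detector assumes (i) primary alignments of paired-end reads are
available in SAM with reliable FLAG and CIGAR fields, (ii) a single-end
chimera appears as a terminally soft-clipped alignment — the aligner maps
one segment and clips the other, and (iii) a genuine junction retains its
overlap: the end of the former subsection re-occurs in the reference
immediately before the following subsection's junction (or mirrored). The
overlap requirement is the main specificity filter: coincidental clipped
alignments rarely carry one.

## Pipeline

**Stage A — pair classification.** Raw read pairs containing an `N` base
can be dropped up front (`prefilter_reads`). Aligned pairs are partitioned
into exactly one category: unmapped pairs and proper full-length pairs are
removed; both mates mapped to the same strand of the same chromosome is an
insertion chimera; a qualifying terminal soft clip on either mate (even on
a proper pair — aligners happily flag a clipped pair proper) makes the
pair a soft-clip candidate; everything else is other-discordant.
Inter-chromosomal same-strand pairs are deliberately *not* called
insertion chimeras: chimera segments are by definition near each other on
one chromosome, so such pairs fall to other-discordant. Insertion
classification takes precedence over soft clips so each pair lands in one
category and the rate denominator stays clean.

**Stage B — split and realign.** A soft-clipped read is cut exactly at the
clip boundary; no junction trimming is attempted, since overlap discovery
is entirely the next stage's job. Subsections shorter than

    min_len(L) = floor(log4 L) + 1

for a chromosome of length L bp are removed — below that length a
sequence is expected to occur more than once by chance in L bp — with an
absolute floor of 8 bp. The bracket is read as floor: for the largest
human chromosome (249,250,621 bp) the rule gives 14. The formula is
evaluated in exact integer arithmetic (`floor(log4 L) =
(L.bit_length() - 1) // 2`), so boundary cases at powers of four are
exact where a float log would wobble. Both subsections are gated
symmetrically. Reads clipped at both ends split at the longer clip (ties:
trailing), the shorter clip's bases staying attached to the aligned part;
a `skip` policy is available. Hard clips carry no sequence and are
transparent. The two subsections are re-emitted as pseudo paired-end
records under a reversible name encoding (origin id, mate, split
position, lengths) and realigned.

Two realignment routes exist. The built-in aligner does an exhaustive
exact-match scan of both strands of every chromosome: one occurrence is a
unique hit, zero is unmapped, two or more is multi-mapped and discarded —
deterministic placement is preferred over random multi-hit reporting,
which is a known source of irreproducible counts. A query equal to its
own reverse complement at a single locus is strand-ambiguous and treated
as multi-mapped. Mismatch- and indel-tolerant realignment is available
only through the external adapter, which runs any paired-end aligner via
a `{ref} {fq1} {fq2} {out}` command template and joins its SAM back to
the origins by the name encoding.

**Stage C — overlap search and validation.** Realigned subsection pairs
on the same strand are potential direct chimeras; on opposite strands,
potential inverted chimeras. The junction overlap is sought on both
sides with a 31 nt comparison window:

* *tail side* — the last 31 nt of the former subsection (N-padded in
  front if shorter) against the 31 reference bases immediately preceding
  the following subsection's first aligned base, read in the following
  subsection's orientation (`[start-31, start)` forward for a `+` hit;
  the bases after its end, reverse-complemented, for a `-` hit);
* *head side* — the mirror: the first 31 nt of the following subsection
  against the 31 reference bases immediately after the former
  subsection's last aligned base in the former's orientation.

Each side is scanned cyclically, shortening by one base per loop from the
30 bp maximum down to the 3 bp minimum, and accepts the first (longest)
length with at most one mismatch — never at the overlap's first base, and
`N` matches nothing, not even another `N`. Out-of-range reference context
is N-padded rather than erroring. The window is one base wider than the
maximum accepted overlap so the 31st base can support the
mismatch-position rule. When both sides find an overlap the longer wins;
ties go to the tail side (recorded in the output). The two-sided search is
not redundant: a chimera planted tail-side in original read orientation
surfaces as a head-side overlap when the aligner stores the read
reverse-complemented.

A candidate is valid iff both subsections are ≥ 30 bp, the two hits lie
on one chromosome 25–5000 bp apart, and an overlap ≥ 3 bp was found.
Rejections report one dominant reason in fixed precedence (subsection,
then distance, then overlap). Distance is the absolute difference of the
two hits' reference start coordinates: start-to-start is symmetric under
orientation and matches the local-window framing of the distance cap; a
`gap` mode (bases between the nearer ends) is available as an option.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 31 nt | comparison window cut on each side |
| `max_overlap` / `min_overlap` | 30 / 3 bp | accepted overlap lengths ("longer than two bases") |
| `max_mismatches` | 1 | tolerated inside an overlap, never at its first base |
| `min_subsection` | 30 bp | minimum subsection length for a valid chimera |
| `distance_min` / `distance_max` | 25 / 5000 bp | allowed genomic distance between subsections |
| `hard_floor` | 8 bp | absolute minimum clip length at the split stage |
| `max_insertion_distance` | unlimited | optional cap on insertion-chimera mate distance |

The chimeric rate is pair-level: a pair counts once toward the numerator
if it is an insertion chimera or either mate yields ≥ 1 valid single-end
chimera, divided by the total pair count (0 is reported for empty input,
with a warning). The inverted share is 100 · inverted / (direct +
inverted), reported as absent when there are no single-end chimeras.

## Simulator

The generator emulates the template-switch mechanism with planted truth.
Its defaults are the study conditions used throughout the tests: a
200 kb uniform-random single-chromosome reference, 2 × 101 bp reads,
insert sizes ≈ N(300, 25), 100 direct + 100 inverted + 100 insertion
chimeras among 700 normal pairs, junction distances 25–5000 bp, overlaps
3–30 bp, subsections ≥ 30 bp, error-free reads (a uniform substitution
rate is available to exercise the mismatch tolerance). A single
chromosome suffices; the minimum-length rule is still exercised by
varying its length.

Planting is two-phase. First the junction geometry is drawn and the
overlap is *written into the reference*: the o-mer ending segment 1's
read-oriented slice is copied immediately upstream (in read orientation)
of segment 2's start. Editing the reference rather than the read keeps
the read an exact concatenation of two slices of the final reference, so
the realigner and the overlap engine see a self-consistent world — the
same shared-sequence structure the template switch itself produces. An
interval registry keeps the loci and junction windows of different plants
at least 2 × window apart (bounded retry, then an error); the overlap
length is drawn with o < l1 so the edit never duplicates a whole
subsection, which would make it multi-mapped. Second, after all edits,
every read — chimeric, insertion, normal — is materialized from the final
reference, and a truth-derived SAM is emitted (each single-end chimeric
read soft-clipped at its first locus, e.g. `64M37S`; minus-strand plants
stored reverse-complemented with the mirrored CIGAR), so the pipeline is
testable with no aligner at all. Identical configurations produce
byte-identical outputs.

What the simulator does *not* model: amplification bias and coverage
waviness, quality-score structure, indels, repetitive or low-complexity
reference sequence, and multi-chromosome genomes. Passing the recovery
test therefore demonstrates the correctness of the detection logic under
clean, uniquely-mappable conditions — not the detector's sensitivity on
real MDA data, where repeats, mismatched realignments and coverage
fluctuations will lower recall in ways only real benchmarks can measure.

## Numerical and design choices

* Coordinates are 0-based half-open internally; conversion to SAM's
  1-based convention happens only at the pysam I/O boundary.
* Secondary (0x100) and supplementary (0x800) records are dropped on
  ingest: clipped parts are realigned by the pipeline itself, not taken
  from the aligner's split records.
* The cyclical scan accepts the *first* satisfying length, i.e. the
  longest; enumeration from the top and taking the maximum are
  equivalent, which the brute-force oracle tests exploit.
* "No mismatch at the beginning of the overlap" is pinned to: the first
  (5′-most, read orientation) base of the candidate k-mer must match
  exactly.
* Degenerate inputs: empty SAM yields zero counts and rate 0 with a
  warning; out-of-range overlap context is N-padded; unknown chromosomes
  and malformed CIGARs raise typed errors; partial outputs are removed
  when a run fails.
* Determinism: no randomness anywhere in the detection path; two runs on
  identical inputs produce byte-identical TSV, filter list and report.

## Problem sizes

The test suite and the bundled acceptance checks run entirely at desk
scale: 200 kb references, 1000 read pairs, 1000 randomized oracle
triples on ≤ 10 kb references — a few seconds end to end. The
implementation is correctness-first and unoptimized for genome-scale
streaming; memory is proportional to the reference plus the pair dict.

## Known limitations

* The built-in realigner is exact-match only; reads with sequencing
  errors in a subsection require the external aligner route.
* Overlaps spanning chromosome ends or assembled-gap junctions are not
  modelled (N-padding makes them fail the match rules).
* Gap-tolerant (indel) overlap comparison is out of scope.
* Proper-pair status is trusted from the aligner's FLAG; it is not
  re-derived from the insert-size distribution.
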