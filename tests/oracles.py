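"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive everything from first principles: reference
bases are fetched one position at a time with explicit bounds checks, the
reverse complement is built from a dict, and every candidate overlap
length is enumerated and tested literally against the rules (at most one
mismatch, never at the overlap's first base, N matches nothing). The
oracle shares no slicing or padding code with the package.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def base_at(seq: str, i: int) -> str:
    return seq[i] if 0 <= i < len(seq) else "N"


def window_oriented(seq: str, start: int, end: int, strand: str) -> str:
    out = "".join(base_at(seq, i) for i in range(start, end))
    return rc(out) if strand == "-" else out


def bases_agree(a: str, b: str) -> bool:
    return a == b and a != "N" and b != "N"


def _acceptable(t: str, e: str, max_mismatches: int) -> bool:
    if not bases_agree(t[0], e[0]):
        return False
    return sum(0 if bases_agree(x, y) else 1 for x, y in zip(t, e)) <= max_mismatches


def oracle_tail(former_seq, following_hit, ref_seq, window=31, max_overlap=30,
                min_overlap=3, max_mismatches=1):
    """Longest acceptable tail-side overlap length, or None."""
    padded = "N" * window + former_seq
    T = padded[len(padded) - window:]
    if following_hit.strand == "+":
        E = window_oriented(ref_seq, following_hit.ref_start - window,
                            following_hit.ref_start, "+")
    else:
        E = window_oriented(ref_seq, following_hit.ref_end,
                            following_hit.ref_end + window, "-")
    hits = [k for k in range(min_overlap, max_overlap + 1)
            if _acceptable(T[window - k:], E[window - k:], max_mismatches)]
    return max(hits) if hits else None


def oracle_head(following_seq, former_hit, ref_seq, window=31, max_overlap=30,
                min_overlap=3, max_mismatches=1):
    """Longest acceptable head-side overlap length, or None."""
    T = (following_seq + "N" * window)[:window]
    if former_hit.strand == "+":
        E = window_oriented(ref_seq, former_hit.ref_end,
                            former_hit.ref_end + window, "+")
    else:
        E = window_oriented(ref_seq, former_hit.ref_start - window,
                            former_hit.ref_start, "-")
    hits = [k for k in range(min_overlap, max_overlap + 1)
            if _acceptable(T[:k], E[:k], max_mismatches)]
    return max(hits) if hits else None


def oracle_scan_occurrences(ref_seq: str, query: str):
    """Literal per-position scan of both strands for exact occurrences."""
    out = []
    n, m = len(ref_seq), len(query)
    rcq = rc(query)
    for pos in range(n - m + 1):
        window = ref_seq[pos:pos + m]
        if all(bases_agree(a, b) for a, b in zip(window, query)):
            out.append((pos, "+"))
        if all(bases_agree(a, b) for a, b in zip(window, rcq)):
            out.append((pos, "-"))
    return out
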