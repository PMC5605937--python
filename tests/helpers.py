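"""Independent brute-force oracles used to cross-check the package."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_map(query: str, genome_seq: str, min_identity: float, circular: bool = True):
    """Hit set over every position and both strands, by direct comparison.

    Returns a set of (ref_start, strand, n_mismatches) where ref_start is the
    forward coordinate of the query's 5'-most aligned base (rightmost for '-').
    Independent of the seed-and-extend path: no index, no early abort.
    """
    n = len(query)
    L = len(genome_seq)
    ext = genome_seq + (genome_seq[: n - 1] if circular else "")
    n_starts = L if circular else L - n + 1
    allowed = int(n * (1.0 - min_identity) + 1e-9)
    hits = set()
    for strand, q in (("+", query), ("-", rc(query))):
        for start in range(max(0, n_starts)):
            seg = ext[start : start + n]
            mm = sum(1 for a, b in zip(q, seg) if a != b or a == "N")
            if mm <= allowed:
                ref = start if strand == "+" else (start + n - 1) % L
                hits.add((ref, strand, mm))
    return hits


def brute_force_offtargets(protospacer: str, genome_seq: str, max_mm: int, circular: bool = True):
    """Naive both-strand NGG-adjacent match counter (per exact mismatch level)."""
    t = len(protospacer) + 3
    L = len(genome_seq)
    ext = genome_seq + (genome_seq[: t - 1] if circular else "")
    n_starts = L if circular else L - t + 1
    counts = {m: 0 for m in range(max_mm + 1)}
    for start in range(max(0, n_starts)):
        window = ext[start : start + t]
        # forward: [protospacer][NGG]
        if window[21] == "G" and window[22] == "G":
            mm = sum(1 for a, b in zip(protospacer, window[:20]) if a != b)
            if mm <= max_mm:
                counts[mm] += 1
        # reverse: forward-frame [CCN][rc(protospacer)]
        if window[0] == "C" and window[1] == "C":
            mm = sum(1 for a, b in zip(rc(protospacer), window[3:]) if a != b)
            if mm <= max_mm:
                counts[mm] += 1
    return counts


def stepped_quality_trim(seq: str, quals, qmin: int, qavg: float):
    """Hand-stepped reference for the 3' trimming rule (no shared code)."""
    s = list(seq)
    q = list(quals)
    while s:
        mean = sum(q) / len(q)
        if q[-1] < qmin or mean < qavg:
            s.pop()
            q.pop()
        else:
            break
    return "".join(s), q


def write_fastq(path, records):
    """records: list of (id, seq, qual_string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
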