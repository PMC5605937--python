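"""Cas9 sgRNA selection-design helper for lysogen isolation.

Candidate protospacers must span the integration junction (so integration
disrupts the target and spares the lysogen) and be unique in the genome
within the allowed mismatch budget; a non-unique target -- e.g. inside a
duplicated locus -- would kill every cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import Genome, revcomp

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
TARGET_LEN = PROTOSPACER_LEN + PAM_LEN
DEFAULT_SEARCH_RADIUS = 30
DEFAULT_MAX_MM = 2
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class GuideCandidate:
    protospacer: str  # 20 nt, 5'->3' on its own strand
    pam: str  # NGG immediately 3' of the protospacer
    strand: str
    protospacer_start: int  # 0-based forward coord of the protospacer's 5'-most base
    spans_junction: bool
    offtarget_counts: dict[int, int] = field(default_factory=dict)  # exact-mm -> count
    accepted: bool = False
    cut_distance: int | None = None  # |cut site - insertion point|, for ranking

    def total_within(self, max_mm: int) -> int:
        return sum(c for m, c in self.offtarget_counts.items() if m <= max_mm)

    def target_interval(self) -> tuple[int, int]:
        """0-based half-open forward-genome interval of protospacer+PAM."""
        if self.strand == "+":
            return self.protospacer_start, self.protospacer_start + TARGET_LEN
        return self.protospacer_start - TARGET_LEN + 1, self.protospacer_start + 1

    def reextract(self, genome: Genome) -> str:
        """Protospacer+PAM re-read from the genome (consistency invariant)."""
        start, end = self.target_interval()
        seq = genome.fetch(start, end - start)
        return seq if self.strand == "+" else revcomp(seq)


def _is_pam(seq3: str) -> bool:
    return len(seq3) == 3 and seq3[1] == "G" and seq3[2] == "G"


def enumerate_candidates(
    genome: Genome,
    site_position: int,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> list[GuideCandidate]:
    """All NGG-adjacent 20-mers on either strand near an integration site.

    ``site_position`` is 1-based (first base of the strand-exchange region);
    the insertion point is the boundary immediately 5' of it. The whole
    protospacer+PAM interval must lie within +-``search_radius`` of the
    insertion point; ``spans_junction`` requires at least one base on each
    side. An empty list means no PAM is available near the site.
    """
    b = site_position - 1  # insertion boundary sits between b-1 and b
    L = len(genome)
    lo = b - search_radius
    hi = b + search_radius  # interval must fit inside [lo, hi)
    candidates: list[GuideCandidate] = []
    for s in range(lo, hi - TARGET_LEN + 1):
        window = genome.fetch(s, TARGET_LEN)
        spans = s < b < s + TARGET_LEN
        # '+' strand: protospacer then NGG
        if _is_pam(window[PROTOSPACER_LEN:]):
            candidates.append(
                GuideCandidate(
                    protospacer=window[:PROTOSPACER_LEN],
                    pam=window[PROTOSPACER_LEN:],
                    strand="+",
                    protospacer_start=s % L,
                    spans_junction=spans,
                )
            )
        # '-' strand: forward CCN then the revcomp protospacer
        rc = revcomp(window)
        if _is_pam(rc[PROTOSPACER_LEN:]):
            candidates.append(
                GuideCandidate(
                    protospacer=rc[:PROTOSPACER_LEN],
                    pam=rc[PROTOSPACER_LEN:],
                    strand="-",
                    protospacer_start=(s + TARGET_LEN - 1) % L,
                    spans_junction=spans,
                )
            )
    if not candidates:
        logger.warning(
            "no PAM available within +-%d nt of position %d", search_radius, site_position
        )
    return candidates


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        codes[arr == ord(base)] = i
    return codes


def count_offtargets(
    candidate: GuideCandidate, genome: Genome, max_mm: int = DEFAULT_MAX_MM
) -> dict[int, int]:
    """Exhaustive both-strand scan for NGG-adjacent matches with <= max_mm
    substitutions; the on-target site itself is included in the counts."""
    if "N" in candidate.protospacer:
        candidate.offtarget_counts = {m: 0 for m in range(max_mm + 1)}
        return candidate.offtarget_counts
    L = len(genome)
    ext = genome.sequence + (genome.sequence[: TARGET_LEN - 1] if genome.circular else "")
    codes = _encode(ext)
    n_starts = L if genome.circular else L - TARGET_LEN + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, TARGET_LEN)[:n_starts]
    counts = {m: 0 for m in range(max_mm + 1)}
    G = _BASE_INDEX["G"]
    C = _BASE_INDEX["C"]

    # forward-strand occurrences: [protospacer][NGG]
    pat = _encode(candidate.protospacer)
    mm = (win[:, :PROTOSPACER_LEN] != pat).sum(axis=1)
    pam_ok = (win[:, PROTOSPACER_LEN + 1] == G) & (win[:, PROTOSPACER_LEN + 2] == G)
    for m in range(max_mm + 1):
        counts[m] += int(((mm == m) & pam_ok).sum())

    # reverse-strand occurrences read forward as [CCN][revcomp(protospacer)]
    rc_pat = _encode(revcomp(candidate.protospacer))
    mm_rc = (win[:, PAM_LEN:] != rc_pat).sum(axis=1)
    pam_rc = (win[:, 0] == C) & (win[:, 1] == C)
    for m in range(max_mm + 1):
        counts[m] += int(((mm_rc == m) & pam_rc).sum())

    candidate.offtarget_counts = counts
    return counts


def _cut_boundary(candidate: GuideCandidate) -> int:
    """Forward-genome coordinate of the blunt cut (3 bp 5' of the PAM)."""
    start, end = candidate.target_interval()
    if candidate.strand == "+":
        return start + 17
    return end - 17


def select_guides(
    candidates: list[GuideCandidate],
    site_position: int,
    max_mm: int = DEFAULT_MAX_MM,
    genome_length: int | None = None,
) -> list[GuideCandidate]:
    """Accept junction-spanning candidates unique within ``max_mm`` mismatches,
    ranked by cut-site distance to the insertion point (nearest first)."""
    b = site_position - 1
    accepted = []
    for cand in candidates:
        cand.accepted = (
            cand.spans_junction and cand.offtarget_counts and cand.total_within(max_mm) == 1
        )
        d = abs(_cut_boundary(cand) - b)
        if genome_length:
            d = min(d % genome_length, (genome_length - d) % genome_length)
        cand.cut_distance = d
        if cand.accepted:
            accepted.append(cand)
    accepted.sort(key=lambda c: (c.cut_distance, c.protospacer_start, c.strand))
    if not accepted:
        logger.warning(
            "no junction-spanning unique guide near position %d; "
            "consider widening the radius or relaxing max_mm",
            site_position,
        )
    return accepted
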