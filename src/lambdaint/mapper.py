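"""Seed-and-extend short-query mapper with an identity cutoff.

Queries here are short (16-23 nt host remnants and 20 nt read-2 prefixes), so
extension is ungapped: at a 95% identity cutoff no indel is admissible for
these lengths. Identity is (query length - mismatches) / query length, and a
hit is reported only when it reaches ``min_identity``. N in the genome (or
query) counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequence_io import Genome, revcomp

DEFAULT_SEED_K = 12
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MAX_INSERT = 1000


@dataclass
class MapperConfig:
    min_identity: float = DEFAULT_MIN_IDENTITY
    seed_k: int = DEFAULT_SEED_K
    max_insert: int = DEFAULT_MAX_INSERT


@dataclass(frozen=True)
class MappingHit:
    """One ungapped alignment of a query to the forward genome frame.

    ``ref_start`` is the 0-based forward-genome coordinate of the query's
    5'-most aligned base: for '+' hits the leftmost aligned position, for '-'
    hits the rightmost.
    """

    ref_start: int
    strand: str
    identity: float
    n_mismatches: int
    length: int

    def interval(self) -> tuple[int, int]:
        """0-based half-open aligned interval in forward coordinates
        (unwrapped; may exceed genome length on circular genomes)."""
        if self.strand == "+":
            return self.ref_start, self.ref_start + self.length
        return self.ref_start - self.length + 1, self.ref_start + 1


@dataclass
class JunctionMapping:
    pair_id: str
    replicate_id: str
    read1_hit: MappingHit | None
    read2_hit: MappingHit | None
    status: str  # unique | ambiguous | unmapped | discordant


class GenomeIndex:
    """Exact k-mer lookup table over the forward genome strand.

    Reverse-strand queries are served by looking up their reverse
    complement, so both strands are represented via canonical forward
    indexing. Circular genomes index origin-spanning k-mers too.
    """

    def __init__(self, genome: Genome, k: int = DEFAULT_SEED_K):
        if k < 8:
            raise ValueError(f"seed length k={k} too unspecific (minimum 8)")
        self.k = k
        self.genome_length = len(genome)
        self.circular = genome.circular
        # extension overhang lets origin-spanning alignments use plain slicing
        overhang = 64 if genome.circular else 0
        self.ext = genome.sequence + genome.sequence[:overhang]
        table: dict[str, list[int]] = {}
        n_starts = self.genome_length if genome.circular else self.genome_length - k + 1
        seq = self.ext
        for i in range(max(0, n_starts)):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append(i)
        self.table = table

    def lookup(self, kmer: str) -> list[int]:
        return self.table.get(kmer, [])


def build_index(genome: Genome, k: int = DEFAULT_SEED_K) -> GenomeIndex:
    return GenomeIndex(genome, k)


def _count_mismatches(query: str, segment: str, allowed: int) -> int:
    """Mismatches between equal-length strings, early-aborting past ``allowed``.
    Any N on either side is a mismatch."""
    if segment == query and "N" not in query:
        return 0
    mm = 0
    for a, b in zip(query, segment):
        if a != b or a == "N":
            mm += 1
            if mm > allowed:
                return mm
    return mm


def _window_variants(window: str, max_mm: int):
    """All strings within ``max_mm`` substitutions of ``window`` (incl. itself)."""
    variants = {window}
    frontier = {window}
    for _ in range(max_mm):
        nxt = set()
        for w in frontier:
            for i in range(len(w)):
                for b in "ACGT":
                    if b != w[i]:
                        nxt.add(w[:i] + b + w[i + 1 :])
        nxt -= variants
        variants |= nxt
        frontier = nxt
    return variants


def map_read(
    query: str,
    index: GenomeIndex,
    genome: Genome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[MappingHit]:
    """All hits of ``query`` on both strands with identity >= ``min_identity``.

    Seeding is complete for the identity cutoff: when the query is long
    enough for the pigeonhole argument (length >= (allowed_mm + 1) * k) the
    disjoint exact seed windows suffice; otherwise every string within
    allowed_mm substitutions of the first k-window is looked up, which covers
    any placement directly. Best-identity hits are returned first.
    """
    k = index.k
    n = len(query)
    if n < k:
        raise ValueError(f"query length {n} shorter than seed length {k}")
    L = index.genome_length
    allowed = int(n * (1.0 - min_identity) + 1e-9)
    ext = index.ext
    hits: list[MappingHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        candidates: set[int] = set()

        def add(start: int) -> None:
            if index.circular:
                candidates.add(start % L)
            elif 0 <= start <= L - n:
                candidates.add(start)

        if allowed == 0 or n >= (allowed + 1) * k:
            # disjoint windows: at least one is mismatch-free in any hit
            offsets = set(range(0, n - k + 1, k))
            offsets.add(n - k)
            for off in offsets:
                for p in index.lookup(q[off : off + k]):
                    add(p - off)
        else:
            # short query: mutate the first window through the mismatch budget
            for variant in _window_variants(q[:k], allowed):
                for p in index.lookup(variant):
                    add(p)
        for start in candidates:
            mm = _count_mismatches(q, ext[start : start + n], allowed)
            if mm <= allowed:
                ref_start = start if strand == "+" else (start + n - 1) % L
                hits.append(
                    MappingHit(
                        ref_start=ref_start,
                        strand=strand,
                        identity=(n - mm) / n,
                        n_mismatches=mm,
                        length=n,
                    )
                )
    hits.sort(key=lambda h: (-h.identity, h.ref_start, h.strand))
    return hits


def _concordant_span(
    h_plus: MappingHit, h_minus: MappingHit, L: int, circular: bool
) -> int | None:
    """Implied fragment span of a forward-reverse pair, or None if not FR."""
    start = h_plus.interval()[0] % L
    end_unwrapped = h_minus.interval()[1]
    end = end_unwrapped % L if end_unwrapped % L != 0 else L if end_unwrapped else 0
    span = end - start
    if circular:
        span %= L
        if span == 0:
            span = L
    if span <= 0:
        return None
    return span


def map_pair(
    junction,
    index: GenomeIndex,
    genome: Genome,
    config: MapperConfig = MapperConfig(),
    read1_hits: Sequence[MappingHit] | None = None,
    read2_hits: Sequence[MappingHit] | None = None,
) -> JunctionMapping:
    """Map both mates of an accepted junction and resolve pairing status.

    A concordant pairing needs opposite strands, forward-reverse orientation
    and an implied fragment span <= ``max_insert`` (circular-aware). Status is
    unique iff exactly one concordant pairing maximizes summed identity.
    Precomputed hit lists may be supplied to reuse a per-query cache.
    """
    if read1_hits is None:
        read1_hits = map_read(junction.host_seq1, index, genome, config.min_identity)
    if not read1_hits:
        return JunctionMapping(junction.pair_id, junction.replicate_id, None, None, "unmapped")
    if read2_hits is None:
        read2_hits = map_read(junction.host_seq2, index, genome, config.min_identity)

    L = index.genome_length
    best: tuple[MappingHit, MappingHit] | None = None
    best_score = -1.0
    n_best = 0
    for h1 in read1_hits:
        for h2 in read2_hits:
            if h1.strand == h2.strand:
                continue
            h_plus, h_minus = (h1, h2) if h1.strand == "+" else (h2, h1)
            span = _concordant_span(h_plus, h_minus, L, genome.circular)
            if span is None or span > config.max_insert:
                continue
            score = h1.identity + h2.identity
            if score > best_score + 1e-12:
                best_score = score
                best = (h1, h2)
                n_best = 1
            elif score > best_score - 1e-12:
                n_best += 1
    if best is None:
        return JunctionMapping(
            junction.pair_id, junction.replicate_id, None, None, "discordant"
        )
    status = "unique" if n_best == 1 else "ambiguous"
    return JunctionMapping(junction.pair_id, junction.replicate_id, best[0], best[1], status)


def map_library(
    junctions: Iterable,
    index: GenomeIndex,
    genome: Genome,
    config: MapperConfig = MapperConfig(),
) -> tuple[list[JunctionMapping], dict[str, int]]:
    """Map a stream of accepted junctions with a per-query hit cache."""
    cache: dict[str, list[MappingHit]] = {}

    def hits_for(q: str) -> list[MappingHit]:
        h = cache.get(q)
        if h is None:
            h = map_read(q, index, genome, config.min_identity)
            cache[q] = h
        return h

    mappings: list[JunctionMapping] = []
    counts = {"unique": 0, "ambiguous": 0, "unmapped": 0, "discordant": 0}
    for junction in junctions:
        m = map_pair(
            junction,
            index,
            genome,
            config,
            read1_hits=hits_for(junction.host_seq1),
            read2_hits=hits_for(junction.host_seq2),
        )
        counts[m.status] += 1
        mappings.append(m)
    return mappings, counts
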