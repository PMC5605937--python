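"""Read-level filtering and trimming cascade for junction libraries.

A read pair is kept only when read 1 carries the constant phage anchor with
no mismatch. The anchor (and anything 5' of it) is stripped, the remnant is
3'-quality-trimmed, the 7-base strand-exchange region is removed, and length
thresholds are applied to the host remnant and the read-2 prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .sequence_io import ReadPair
from .synthetic import DEFAULT_ANCHOR

REJECTION_REASONS = ("no_anchor", "too_short", "low_quality")


@dataclass
class FilterConfig:
    anchor: str = DEFAULT_ANCHOR
    overlap_trim: int = 7  # 5' strand-exchange bases removed from the remnant
    min_read1_len: int = 16
    read2_prefix_len: int = 20
    qmin: int = 10  # minimum Phred of every retained 3' base
    qavg: int = 15  # minimum mean Phred of the retained read

    def __post_init__(self) -> None:
        if self.overlap_trim < 0:
            raise ValueError("overlap_trim must be >= 0")
        if self.min_read1_len < 1:
            raise ValueError("min_read1_len must be >= 1")
        if not self.anchor or any(c not in "ACGT" for c in self.anchor):
            raise ValueError("anchor must be a non-empty uppercase ACGT string")


@dataclass
class TrimmedJunction:
    host_seq1: str
    host_seq2: str
    pair_id: str
    replicate_id: str = ""
    rejection_reason: str = "none"

    @property
    def accepted(self) -> bool:
        return self.rejection_reason == "none"


@dataclass
class FilterReport:
    total: int = 0
    accepted: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECTION_REASONS}
    )

    def record(self, junction: TrimmedJunction) -> None:
        self.total += 1
        if junction.accepted:
            self.accepted += 1
        else:
            self.rejected[junction.rejection_reason] += 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"total": self.total, "accepted": self.accepted, "rejected": self.rejected},
                indent=1,
            )
        )


def find_anchor(read1_seq: str, anchor: str) -> int | None:
    """0-based offset of the first exact occurrence of ``anchor``, or None.

    No mismatches are tolerated; a single substitution inside the anchor
    makes the read unusable for junction calling.
    """
    idx = read1_seq.find(anchor)
    return idx if idx >= 0 else None


def quality_trim_3prime(
    seq: str, quals: Sequence[int], qmin: int, qavg: float
) -> tuple[str, Sequence[int]]:
    """Iteratively drop the 3'-terminal base while it is below ``qmin`` or the
    current mean Phred is below ``qavg``; may return an empty remnant."""
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    n = len(seq)
    total = sum(quals)
    while n > 0 and (quals[n - 1] < qmin or total < qavg * n):
        n -= 1
        total -= quals[n]
    return seq[:n], quals[:n]


def process_pair(pair: ReadPair, config: FilterConfig) -> TrimmedJunction:
    """Apply the full cascade to one pair; rejections are data, not errors.

    Order: anchor find/strip (bases 5' of the anchor are discarded too) ->
    3' quality trim -> strand-exchange trim -> length checks on both mates.
    """
    offset = find_anchor(pair.read1_seq, config.anchor)
    if offset is None:
        return TrimmedJunction("", "", pair.pair_id, pair.replicate_id, "no_anchor")
    start = offset + len(config.anchor)
    remnant = pair.read1_seq[start:]
    remnant_q = pair.read1_qual[start:]
    remnant, remnant_q = quality_trim_3prime(remnant, remnant_q, config.qmin, config.qavg)
    if not remnant:
        return TrimmedJunction("", "", pair.pair_id, pair.replicate_id, "low_quality")
    host_seq1 = remnant[config.overlap_trim:]
    if len(host_seq1) < config.min_read1_len:
        return TrimmedJunction("", "", pair.pair_id, pair.replicate_id, "too_short")
    if len(pair.read2_seq) < config.read2_prefix_len:
        return TrimmedJunction("", "", pair.pair_id, pair.replicate_id, "too_short")
    host_seq2 = pair.read2_seq[: config.read2_prefix_len]
    return TrimmedJunction(host_seq1, host_seq2, pair.pair_id, pair.replicate_id, "none")


def filter_library(
    pairs: Iterable[ReadPair], config: FilterConfig
) -> tuple[Iterator[TrimmedJunction], FilterReport]:
    """Stream accepted junctions; the report is complete once the stream is
    fully consumed (accepted + sum(rejected) == total)."""
    report = FilterReport()

    def _gen() -> Iterator[TrimmedJunction]:
        for pair in pairs:
            junction = process_pair(pair, config)
            report.record(junction)
            if junction.accepted:
                yield junction

    return _gen(), report
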