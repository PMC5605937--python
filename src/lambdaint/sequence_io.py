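"""Readers/writers for the standard formats the pipeline touches.

Provides a coordinate-safe :class:`Genome` abstraction (circular by default,
so windows spanning the origin never fail), paired-FASTQ streaming, a small
GFF3 loader, and the site-catalog writers (BED6 + TSV).

Coordinate conventions: everything internal is 0-based half-open; user-facing
tables are 1-based inclusive; BED follows the BED convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# maps ASCII Phred+33 characters to raw Phred values (clamped at 0)
_PHRED_TABLE = bytes(max(0, i - 33) for i in range(256))


class FormatError(ValueError):
    """Raised for malformed input files."""


class PairingError(ValueError):
    """Raised when R1/R2 FASTQ files disagree on record count."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def base_frequencies(sequence: str) -> dict[str, float]:
    """Fraction of each base among {A,C,G,T}; N is excluded from the denominator."""
    counts = {b: sequence.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise FormatError("sequence contains no A/C/G/T bases")
    return {b: c / total for b, c in counts.items()}


@dataclass
class Genome:
    """A single chromosome with circular-coordinate arithmetic.

    ``fetch`` wraps modulo length when ``circular`` is true and therefore
    never fails for any start coordinate.
    """

    name: str
    sequence: str
    circular: bool = True
    base_frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty genome sequence")
        if not self.base_frequencies:
            self.base_frequencies = base_frequencies(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Subsequence of ``length`` bases starting at 0-based ``start``.

        Circular genomes wrap modulo the genome length; linear genomes raise
        ``IndexError`` for out-of-range windows.
        """
        n = len(self.sequence)
        if length < 0 or length > n:
            raise ValueError(f"window length {length} outside [0, {n}]")
        if not self.circular:
            if start < 0 or start + length > n:
                raise IndexError(
                    f"window [{start}, {start + length}) off linear genome of length {n}"
                )
            return self.sequence[start : start + length]
        start %= n
        end = start + length
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class ReadPair:
    """One paired-end read with Phred scores and replicate provenance."""

    read1_seq: str
    read1_qual: Sequence[int]
    read2_seq: str
    read2_qual: Sequence[int]
    pair_id: str
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for seq, qual, mate in (
            (self.read1_seq, self.read1_qual, 1),
            (self.read2_seq, self.read2_qual, 2),
        ):
            if len(seq) != len(qual):
                raise FormatError(
                    f"pair {self.pair_id} read {mate}: sequence length {len(seq)} "
                    f"!= quality length {len(qual)}"
                )
            if qual and (min(qual) < 0 or max(qual) > 60):
                raise FormatError(
                    f"pair {self.pair_id} read {mate}: Phred score outside [0, 60]"
                )


@dataclass(frozen=True)
class GeneRecord:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    feature_kind: str  # CDS | rRNA | other


@dataclass
class GeneAnnotation:
    records: list[GeneRecord] = field(default_factory=list)

    def genes(self) -> list[GeneRecord]:
        """Records usable for gene-context classification (CDS and rRNA)."""
        return [r for r in self.records if r.feature_kind in ("CDS", "rRNA")]

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, circular: bool = True) -> Genome:
    """Load the first record of a FASTA file as a :class:`Genome`.

    Additional records are ignored with a warning; characters outside
    {A,C,G,T,N} (after uppercasing) are rejected with their position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        logger.warning(
            "%s: %d records found, using first (%s)", path, len(records), records[0].id
        )
    seq = str(records[0].seq).upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise FormatError(f"{path}: illegal character {ch!r} at position {i + 1}")
    return Genome(name=records[0].id, sequence=seq, circular=circular)


def phred_from_ascii(qual_line: str) -> bytes:
    """Decode a Phred+33 quality string to raw scores (as a byte array)."""
    return qual_line.encode("ascii").translate(_PHRED_TABLE)


def phred_to_ascii(scores: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in scores)


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path, replicate_id: str = ""
) -> Iterator[ReadPair]:
    """Stream matched read pairs from two Phred+33 FASTQ files.

    Records are paired by file order; pair IDs are taken from the read-1
    headers (first whitespace token). A record-count mismatch raises
    :class:`PairingError` once the shorter file is exhausted.
    """
    _SENTINEL = object()
    with open(path_r1) as f1, open(path_r2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        while True:
            rec1 = next(it1, _SENTINEL)
            rec2 = next(it2, _SENTINEL)
            if rec1 is _SENTINEL and rec2 is _SENTINEL:
                return
            if rec1 is _SENTINEL or rec2 is _SENTINEL:
                raise PairingError(
                    f"record count mismatch between {path_r1} and {path_r2}"
                )
            title1, seq1, q1 = rec1
            _, seq2, q2 = rec2
            yield ReadPair(
                read1_seq=seq1.upper(),
                read1_qual=phred_from_ascii(q1),
                read2_seq=seq2.upper(),
                read2_qual=phred_from_ascii(q2),
                pair_id=title1.split()[0],
                replicate_id=replicate_id,
            )


_GFF_NAME_KEYS = ("gene", "Name", "locus_tag")


def read_gff(path: str | Path) -> GeneAnnotation:
    """Load a GFF3 file into a :class:`GeneAnnotation`.

    CDS and rRNA features keep their kind; every other feature type is
    marked ``other``. Unparseable lines are skipped with a warning. Gene
    names fall back through gene= / Name= / locus_tag= attributes.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: skipping unparseable line", path, lineno)
                continue
            _, _, ftype, start_s, end_s, _, strand, _, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-numeric coordinates, skipped", path, lineno)
                continue
            if start > end or strand not in ("+", "-"):
                logger.warning("%s:%d: bad span or strand, skipped", path, lineno)
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            name = next(
                (attr_map[k] for k in _GFF_NAME_KEYS if k in attr_map), f"feature_{lineno}"
            )
            kind = ftype if ftype in ("CDS", "rRNA") else "other"
            records.append(GeneRecord(name, start, end, strand, kind))
    if not any(r.feature_kind in ("CDS", "rRNA") for r in records):
        logger.warning("%s: no CDS/rRNA features retained; sites will be uncategorized", path)
    records.sort(key=lambda r: (r.start, r.end, r.name))
    return GeneAnnotation(records=records)


# ---------------------------------------------------------------------------
# Site-catalog output

SITE_TSV_COLUMNS = [
    "site_id",
    "position_1based",
    "strand",
    "total_reads",
    "reads_per_replicate",
    "detection_frequency",
    "is_attB",
    "nearest_gene",
    "category",
    "motif_score",
    "relative_score",
]


def write_site_outputs(catalog, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write a finalized site catalog as BED6 and TSV.

    BED is 0-based half-open with the score column holding the rounded
    relative motif score x100 (0 if unscored); the TSV is 1-based inclusive.
    The two files always refer to the same base: BED start + 1 == TSV
    position_1based.
    """
    rows = []
    bed_lines = []
    for site in catalog.sites:
        rel = site.relative_score
        bed_score = int(round(rel * 100)) if rel is not None else 0
        pos0 = site.position - 1
        bed_lines.append(
            f"{catalog.genome_name}\t{pos0}\t{pos0 + 1}\t{site.site_id}\t{bed_score}\t{site.strand}"
        )
        rows.append(
            {
                "site_id": site.site_id,
                "position_1based": site.position,
                "strand": site.strand,
                "total_reads": site.total_reads,
                "reads_per_replicate": json.dumps(site.reads_per_replicate, sort_keys=True),
                "detection_frequency": site.detection_frequency,
                "is_attB": site.is_attB,
                "nearest_gene": site.nearest_gene if site.nearest_gene else "",
                "category": site.category if site.category else "",
                "motif_score": "" if site.motif_score is None else site.motif_score,
                "relative_score": "" if site.relative_score is None else site.relative_score,
            }
        )
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    df = pd.DataFrame(rows, columns=SITE_TSV_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)


def read_site_table(tsv_path: str | Path) -> pd.DataFrame:
    """Re-read a site TSV written by :func:`write_site_outputs`."""
    df = pd.read_csv(tsv_path, sep="\t", keep_default_na=False, na_values=[])
    if not df.empty:
        df["reads_per_replicate"] = df["reads_per_replicate"].map(json.loads)
    return df
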