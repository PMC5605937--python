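"""Synthetic junction-library simulator with a known ground truth.

Generates a random host genome, plants one high-frequency attB site plus many
low-frequency secondary sites sampled around a sequence motif, and emits
paired-end FASTQ libraries whose read 1 carries a constant 45-nt phage anchor
followed by the 7-nt strand-exchange overlap and the host flank. A
:class:`GroundTruthManifest` records every planted site and the realized
per-replicate read allocation so full-pipeline recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import Genome, revcomp

# Constant attL-derived phage anchor carried at the 5' end of every junction read 1.
DEFAULT_ANCHOR = "GTTGCAACAAATTGATAAGCAATGCTTTTTTATAATGCCAACTTA"

MOTIF_WIDTH = 29
# window labels run -14..+14; label 0 is the first base of the 7-nt overlap
CENTER_OFFSET = 14
# strongly conserved positions of the generating motif (label -> base)
CONSERVED_POSITIONS = {
    -10: "C",
    -7: "C",
    -6: "T",
    -5: "T",
    -3: "T",
    -2: "T",
    -1: "T",
    5: "A",
    6: "A",
}
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParameterError(ValueError):
    """Raised for out-of-range simulation parameters."""


@dataclass
class SimulationConfig:
    """All knobs of the library simulator (defaults mirror the assay design)."""

    genome_length: int = 100_000
    gc_content: float = 0.5
    n_secondary_sites: int = 50
    secondary_read_fraction: float = 0.0051  # target secondary:attB read ratio
    n_replicates: int = 8
    reads_per_replicate: int = 5_000
    read_length: int = 75
    insert_size_mean: float = 300.0
    insert_size_sd: float = 40.0
    substitution_error_rate: float = 0.0
    quality_profile: list[float] | None = None  # per-cycle mean Phred, 3' decay
    quality_sd: float = 2.0
    background_read_fraction: float = 0.0
    anchor_mutation_fraction: float = 0.0
    anchor: str = DEFAULT_ANCHOR
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()
        if self.quality_profile is None:
            # linear decay 38 -> 30 keeps every base far above the trim thresholds
            self.quality_profile = [
                float(q) for q in np.linspace(38.0, 30.0, self.read_length)
            ]

    def validate(self) -> None:
        fracs = {
            "secondary_read_fraction": self.secondary_read_fraction,
            "background_read_fraction": self.background_read_fraction,
            "anchor_mutation_fraction": self.anchor_mutation_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.gc_content < 1.0:
            raise ParameterError(f"gc_content must be in (0, 1), got {self.gc_content}")
        if self.genome_length < 10 * self.read_length:
            raise ParameterError(
                f"genome_length {self.genome_length} < 10 x read_length {self.read_length}"
            )
        if self.read_length <= len(self.anchor) + 7:
            raise ParameterError("read_length must exceed anchor length + overlap")
        if self.n_replicates < 1 or self.reads_per_replicate < 0:
            raise ParameterError("n_replicates >= 1 and reads_per_replicate >= 0 required")


@dataclass
class PlantedSite:
    position: int  # 0-based first base of the 7-nt overlap on the integration strand
    strand: str
    window: str  # realized 29-mer on the integration strand
    overlap: str  # 7-nt strand-exchange sequence
    reads_per_replicate: list[int] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    attB: PlantedSite
    secondary_sites: list[PlantedSite]
    anchor_sequence: str
    config: dict
    background_per_replicate: list[int] = field(default_factory=list)

    @property
    def all_sites(self) -> list[PlantedSite]:
        return [self.attB] + self.secondary_sites

    def total_junction_reads(self) -> int:
        return sum(sum(s.reads_per_replicate) for s in self.all_sites)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            attB=PlantedSite(**raw["attB"]),
            secondary_sites=[PlantedSite(**s) for s in raw["secondary_sites"]],
            anchor_sequence=raw["anchor_sequence"],
            config=raw["config"],
            background_per_replicate=raw.get("background_per_replicate", []),
        )


def default_motif_matrix(conservation: float = 0.91) -> np.ndarray:
    """Generating base-probability matrix (29x4, columns A,C,G,T).

    Conserved positions put ``conservation`` mass on their base; all other
    positions are uniform.
    """
    probs = np.full((MOTIF_WIDTH, 4), 0.25)
    other = (1.0 - conservation) / 3.0
    for label, base in CONSERVED_POSITIONS.items():
        row = np.full(4, other)
        row[_BASE_INDEX[base]] = conservation
        probs[label + CENTER_OFFSET] = row
    return probs


def consensus_of(matrix: np.ndarray) -> str:
    return "".join(BASES[i] for i in matrix.argmax(axis=1))


def sample_windows(
    matrix: np.ndarray,
    n: int,
    rng: np.random.Generator,
    fidelity: float = 1.0,
) -> list[str]:
    """Sample ``n`` windows column-wise from ``matrix``.

    ``fidelity`` < 1 mixes the matrix toward uniform, producing noisier
    windows (used to model poorly matching sites).
    """
    probs = fidelity * matrix + (1.0 - fidelity) * 0.25
    width = matrix.shape[0]
    out = []
    for _ in range(n):
        idx = [rng.choice(4, p=probs[j]) for j in range(width)]
        out.append("".join(BASES[i] for i in idx))
    return out


def generate_genome(config: SimulationConfig) -> Genome:
    """i.i.d. random genome at the requested GC content; deterministic per seed."""
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=config.genome_length, p=p)
    seq = "".join(BASES[c] for c in codes)
    return Genome(name="sim_genome", sequence=seq, circular=True)


def _circular_distance(a: int, b: int, n: int) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def plant_sites(
    genome: Genome,
    generator: np.ndarray | str,
    config: SimulationConfig,
) -> tuple[Genome, GroundTruthManifest]:
    """Overwrite the genome with planted motif windows and return ground truth.

    One attB site (the generator consensus) plus ``n_secondary_sites`` windows
    sampled column-wise from the generating matrix, at non-overlapping uniform
    positions with equiprobable strands.
    """
    if isinstance(generator, str):
        if len(generator) != MOTIF_WIDTH:
            raise ParameterError(f"consensus must be {MOTIF_WIDTH} nt")
        matrix = np.full((MOTIF_WIDTH, 4), 0.01)
        for j, b in enumerate(generator):
            matrix[j, _BASE_INDEX[b]] = 0.97
    else:
        matrix = np.asarray(generator, dtype=float)
        if matrix.shape != (MOTIF_WIDTH, 4):
            raise ParameterError(f"generator matrix must be {MOTIF_WIDTH}x4")

    rng = np.random.default_rng([config.seed, 1])
    n_sites = config.n_secondary_sites + 1
    min_sep = 2 * MOTIF_WIDTH  # keeps windows disjoint and attB isolated
    positions: list[int] = []
    failures = 0
    while len(positions) < n_sites:
        cand = int(rng.integers(0, len(genome)))
        if all(_circular_distance(cand, p, len(genome)) >= min_sep for p in positions):
            positions.append(cand)
        else:
            failures += 1
            if failures > 1000:
                raise ParameterError(
                    "could not place non-overlapping sites after 1000 resamples; "
                    "genome too small for n_secondary_sites"
                )
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_sites)]

    seq = list(genome.sequence)
    n = len(seq)

    def plant(pos: int, strand: str, window: str) -> None:
        forward = window if strand == "+" else revcomp(window)
        start = pos - CENTER_OFFSET
        for j, b in enumerate(forward):
            seq[(start + j) % n] = b

    sites: list[PlantedSite] = []
    consensus = consensus_of(matrix)
    for i, (pos, strand) in enumerate(zip(positions, strands)):
        window = consensus if i == 0 else sample_windows(matrix, 1, rng)[0]
        plant(pos, strand, window)
        sites.append(
            PlantedSite(
                position=pos,
                strand=strand,
                window=window,
                overlap=window[CENTER_OFFSET : CENTER_OFFSET + 7],
                reads_per_replicate=[0] * config.n_replicates,
            )
        )

    planted_genome = Genome(
        name=genome.name, sequence="".join(seq), circular=genome.circular
    )
    manifest = GroundTruthManifest(
        attB=sites[0],
        secondary_sites=sites[1:],
        anchor_sequence=config.anchor,
        config=asdict(config),
        background_per_replicate=[0] * config.n_replicates,
    )
    return planted_genome, manifest


def _quality_string(rng: np.random.Generator, profile: np.ndarray, sd: float, length: int) -> str:
    q = rng.normal(profile[:length], sd)
    q = np.clip(np.rint(q), 2, 40).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    if positions.size == 0:
        return seq
    out = list(seq)
    for i in positions:
        current = out[i]
        alternatives = [b for b in BASES if b != current]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _junction_reads(
    genome: Genome, site: PlantedSite, insert: int, read_length: int, anchor: str
) -> tuple[str, str]:
    """Error-free read pair for one junction fragment (host-side length ``insert``)."""
    host_len = read_length - len(anchor)
    p = site.position
    if site.strand == "+":
        host1 = genome.fetch(p, host_len)
        read2 = revcomp(genome.fetch(p + insert - read_length, read_length))
    else:
        host1 = revcomp(genome.fetch(p - host_len + 1, host_len))
        read2 = genome.fetch(p + 1 - insert, read_length)
    return anchor + host1, read2


def simulate_library(
    genome: Genome,
    manifest: GroundTruthManifest,
    config: SimulationConfig,
    out_dir: str | Path,
) -> list[tuple[Path, Path]]:
    """Write per-replicate paired FASTQ files and record realized read counts.

    Junction pairs choose attB vs. a (uniformly chosen) secondary site so the
    expected secondary:attB read ratio equals ``secondary_read_fraction``;
    background pairs come from random genome positions with no anchor.
    Substitution errors hit host-derived bases only; the anchor stays exact
    except in the ``anchor_mutation_fraction`` subset. Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    read_len = config.read_length
    anchor = config.anchor
    profile = np.asarray(config.quality_profile, dtype=float)
    sites = manifest.all_sites
    for s in sites:
        s.reads_per_replicate = [0] * config.n_replicates
    manifest.background_per_replicate = [0] * config.n_replicates
    f = config.secondary_read_fraction
    p_secondary = f / (1.0 + f)  # so that E[secondary]/E[attB] == f
    insert_lo = max(read_len + 10, 100)
    insert_hi = min(900, len(genome) // 2)

    paths: list[tuple[Path, Path]] = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, 2, rep])
        n_pairs = config.reads_per_replicate
        is_background = rng.random(n_pairs) < config.background_read_fraction
        is_secondary = rng.random(n_pairs) < p_secondary
        which_secondary = rng.integers(0, max(1, len(manifest.secondary_sites)), n_pairs)
        inserts = np.clip(
            np.rint(rng.normal(config.insert_size_mean, config.insert_size_sd, n_pairs)),
            insert_lo,
            insert_hi,
        ).astype(int)
        mutate_anchor = rng.random(n_pairs) < config.anchor_mutation_fraction
        bg_positions = rng.integers(0, len(genome), n_pairs)
        bg_strand_plus = rng.random(n_pairs) < 0.5

        lines1: list[str] = []
        lines2: list[str] = []
        rep_id = f"rep{rep + 1}"
        for i in range(n_pairs):
            pair_id = f"{rep_id}:{i:06d}"
            if is_background[i]:
                pos = int(bg_positions[i])
                frag = genome.fetch(pos, int(inserts[i]))
                if not bg_strand_plus[i]:
                    frag = revcomp(frag)
                read1 = frag[:read_len]
                read2 = revcomp(frag)[:read_len]
                manifest.background_per_replicate[rep] += 1
            else:
                if is_secondary[i] and manifest.secondary_sites:
                    site = manifest.secondary_sites[int(which_secondary[i])]
                    site_idx = 1 + int(which_secondary[i])
                else:
                    site = manifest.attB
                    site_idx = 0
                read1, read2 = _junction_reads(
                    genome, site, int(inserts[i]), read_len, anchor
                )
                sites[site_idx].reads_per_replicate[rep] += 1
                if config.substitution_error_rate > 0:
                    host_hits = np.flatnonzero(
                        rng.random(read_len - len(anchor)) < config.substitution_error_rate
                    )
                    host_part = _mutate(read1[len(anchor):], host_hits, rng)
                    read1 = read1[: len(anchor)] + host_part
                    r2_hits = np.flatnonzero(
                        rng.random(read_len) < config.substitution_error_rate
                    )
                    read2 = _mutate(read2, r2_hits, rng)
                if mutate_anchor[i]:
                    j = int(rng.integers(0, len(anchor)))
                    mutated = _mutate(read1[: len(anchor)], np.array([j]), rng)
                    read1 = mutated + read1[len(anchor):]
            q1 = _quality_string(rng, profile, config.quality_sd, len(read1))
            q2 = _quality_string(rng, profile, config.quality_sd, len(read2))
            lines1.append(f"@{pair_id}\n{read1}\n+\n{q1}\n")
            lines2.append(f"@{pair_id}\n{read2}\n+\n{q2}\n")

        p1 = out_dir / f"{rep_id}_R1.fastq"
        p2 = out_dir / f"{rep_id}_R2.fastq"
        p1.write_text("".join(lines1))
        p2.write_text("".join(lines2))
        paths.append((p1, p2))
    return paths
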