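"""End-to-end orchestration: simulate -> filter -> map -> call -> motif -> guides.

A single declarative config drives every stage; one global seed fans out to
per-stage seeds so runs are reproducible and individually debuggable. The
RunSummary aggregates all stage counts and satisfies the upstream
conservation identities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .junction_filter import FilterConfig, FilterReport, filter_library
from .mapper import MapperConfig, build_index, map_library
from .motif import (
    build_matrix,
    extract_windows,
    relative_scores,
    scan_genome,
    score_by_detection_frequency,
)
from .guides import count_offtargets, enumerate_candidates, select_guides
from .sequence_io import (
    Genome,
    read_fasta,
    read_fastq_pairs,
    read_gff,
    write_site_outputs,
)
from .site_caller import categorize_by_gene, classify_attB, mappings_to_catalog
from .synthetic import (
    SimulationConfig,
    default_motif_matrix,
    generate_genome,
    plant_sites,
    simulate_library,
)

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    tolerance: int = 0
    min_reads: int = 1
    attB_position: int | None = None  # 1-based; None -> auto (max-read site)
    attB_strand: str | None = None
    attB_window: int = 10
    near_window: int = 500


@dataclass
class MotifConfig:
    offset_left: int = 14
    offset_right: int = 14
    pseudocount: float = 1.0
    top_k: int = 10


@dataclass
class GuideConfig:
    search_radius: int = 30
    max_mm: int = 2


@dataclass
class PipelineConfig:
    """Union of all stage settings; defaults match the assay's published values
    (45-nt anchor, 7-base overlap trim, 16/20 length floors, Phred 10/15,
    95 percent identity, 29-base window, 8 replicates)."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    guides: GuideConfig = field(default_factory=GuideConfig)
    simulation: SimulationConfig | None = None
    seed: int = 0
    output_dir: str = "lambdaint_out"

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "filter": FilterConfig,
            "mapper": MapperConfig,
            "caller": CallerConfig,
            "motif": MotifConfig,
            "guides": GuideConfig,
        }
        for name, typ in sections.items():
            if name in raw:
                kwargs[name] = typ(**raw[name])
        if raw.get("simulation") is not None:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        for scalar in ("seed", "output_dir"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> tuple[list[str], list[str]]:
    """Range-check every field; returns (errors, warnings), all at once."""
    errors: list[str] = []
    warnings: list[str] = []
    f, m, c = config.filter, config.mapper, config.caller
    if not 0.0 < m.min_identity <= 1.0:
        errors.append(f"mapper.min_identity must be in (0, 1], got {m.min_identity}")
    if m.seed_k < 8:
        errors.append(f"mapper.seed_k must be >= 8, got {m.seed_k}")
    if m.max_insert < 1:
        errors.append(f"mapper.max_insert must be >= 1, got {m.max_insert}")
    if f.overlap_trim < 0:
        errors.append("filter.overlap_trim must be >= 0")
    if f.min_read1_len < 1:
        errors.append("filter.min_read1_len must be >= 1")
    if f.read2_prefix_len < m.seed_k:
        errors.append("filter.read2_prefix_len must be >= mapper.seed_k")
    if f.qavg < f.qmin:
        warnings.append(
            f"filter.qavg ({f.qavg}) < filter.qmin ({f.qmin}): allowed but unusual"
        )
    if c.tolerance < 0:
        errors.append("caller.tolerance must be >= 0")
    if c.min_reads < 1:
        errors.append("caller.min_reads must be >= 1")
    if c.attB_window < 0:
        errors.append("caller.attB_window must be >= 0")
    if config.motif.pseudocount < 0:
        errors.append("motif.pseudocount must be >= 0")
    if config.motif.offset_left < 0 or config.motif.offset_right < 0:
        errors.append("motif offsets must be >= 0")
    if config.guides.max_mm < 0:
        errors.append("guides.max_mm must be >= 0")
    if config.simulation is not None:
        try:
            config.simulation.validate()
        except ValueError as exc:
            errors.append(str(exc))
    return errors, warnings


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(
    config: PipelineConfig,
    genome_path: str | Path | None = None,
    read_pairs: list[tuple[str | Path, str | Path]] | None = None,
    annotation_path: str | Path | None = None,
) -> dict:
    """Execute the full pipeline and write all outputs under ``output_dir``.

    Either ``config.simulation`` is set (a synthetic genome and library are
    generated first) or ``genome_path`` plus per-replicate ``read_pairs``
    must be given. Returns the RunSummary dict (also written as
    summary.json). Deterministic given config + seed.
    """
    errors, warnings = validate_config(config)
    for w in warnings:
        logger.warning("config: %s", w)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
    }

    manifest = None
    if config.simulation is not None:
        stage = "simulate"
        try:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            genome = generate_genome(sim)
            genome, manifest = plant_sites(genome, default_motif_matrix(), sim)
            fastq_dir = out / "reads"
            read_pairs = simulate_library(genome, manifest, sim, fastq_dir)
            manifest.to_json(out / "manifest.json")
            fasta = out / "genome.fasta"
            fasta.write_text(f">{genome.name}\n{genome.sequence}\n")
            genome_path = fasta
            logger.info("simulate: %d replicates, %d junction reads",
                        sim.n_replicates, manifest.total_junction_reads())
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    elif genome_path is None or not read_pairs:
        raise ValueError("need either a simulation config or genome_path + read_pairs")
    else:
        genome = read_fasta(genome_path)

    # --- filter + map, per replicate ---------------------------------------
    try:
        index = build_index(genome, config.mapper.seed_k)
    except Exception as exc:  # noqa: BLE001
        raise StageError("index", exc) from exc

    filter_reports: dict[str, FilterReport] = {}
    mappings_by_rep: dict[str, list] = {}
    map_counts_total = {"unique": 0, "ambiguous": 0, "unmapped": 0, "discordant": 0}
    for i, (r1, r2) in enumerate(read_pairs):
        rep_id = Path(r1).name.replace("_R1.fastq", "") or f"rep{i + 1}"
        try:
            pairs = read_fastq_pairs(r1, r2, replicate_id=rep_id)
            accepted, report = filter_library(pairs, config.filter)
            mappings, counts = map_library(accepted, index, genome, config.mapper)
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter/map", exc) from exc
        filter_reports[rep_id] = report
        mappings_by_rep[rep_id] = mappings
        for k, v in counts.items():
            map_counts_total[k] += v

    total_report = FilterReport()
    total_report.total = sum(r.total for r in filter_reports.values())
    total_report.accepted = sum(r.accepted for r in filter_reports.values())
    for r in filter_reports.values():
        for reason, c in r.rejected.items():
            total_report.rejected[reason] += c
    total_report.to_json(out / "filter_report.json")

    # --- call ---------------------------------------------------------------
    try:
        catalog = mappings_to_catalog(
            mappings_by_rep,
            overlap_trim=config.filter.overlap_trim,
            genome_length=len(genome),
            circular=genome.circular,
            tolerance=config.caller.tolerance,
            min_reads=config.caller.min_reads,
            genome_name=genome.name,
        )
        catalog = classify_attB(
            catalog,
            attB_position=config.caller.attB_position,
            attB_strand=config.caller.attB_strand,
            window=config.caller.attB_window,
            genome_length=len(genome),
            auto=config.caller.attB_position is None,
        )
        gene_summary = None
        if annotation_path is not None:
            annotation = read_gff(annotation_path)
            gene_summary = categorize_by_gene(catalog, annotation, config.caller.near_window)
    except Exception as exc:  # noqa: BLE001
        raise StageError("call", exc) from exc

    # --- motif --------------------------------------------------------------
    scan = None
    per_freq = per_class = None
    try:
        windows = extract_windows(
            genome, catalog, config.motif.offset_left, config.motif.offset_right
        )
        if len(windows) >= 2:
            matrix = build_matrix(
                windows,
                pseudocount=config.motif.pseudocount,
                background=genome.base_frequencies,
            )
            catalog = relative_scores(
                matrix, catalog, genome, config.motif.offset_left, config.motif.offset_right
            )
            scan = scan_genome(matrix, genome, catalog, top_k=config.motif.top_k)
            per_freq, per_class = score_by_detection_frequency(catalog)
            matrix.to_meme(out / "matrix.meme")
            per_freq.to_csv(out / "score_by_frequency.tsv", sep="\t", index=False)
            per_class.to_csv(out / "score_by_class.tsv", sep="\t", index=False)
            import pandas as pd

            pd.DataFrame(
                {
                    "bin_left": scan.histogram_edges[:-1],
                    "bin_right": scan.histogram_edges[1:],
                    "count": scan.histogram_counts,
                }
            ).to_csv(out / "scan_histogram.tsv", sep="\t", index=False)
        else:
            logger.warning("fewer than 2 sites: motif stage skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError("motif", exc) from exc

    # --- guides (top secondary site, if any) --------------------------------
    guide_rows = []
    try:
        secondary = catalog.secondary_sites()
        if secondary:
            target = max(secondary, key=lambda s: s.total_reads)
            cands = enumerate_candidates(genome, target.position, config.guides.search_radius)
            for cand in cands:
                count_offtargets(cand, genome, config.guides.max_mm)
            accepted = select_guides(
                cands, target.position, config.guides.max_mm, genome_length=len(genome)
            )
            order = {id(c): i for i, c in enumerate(accepted)}
            for cand in cands:
                guide_rows.append(
                    {
                        "target_site": target.site_id,
                        "protospacer": cand.protospacer,
                        "pam": cand.pam,
                        "strand": cand.strand,
                        "protospacer_start_1based": cand.protospacer_start + 1,
                        "spans_junction": cand.spans_junction,
                        "offtargets": json.dumps(cand.offtarget_counts),
                        "accepted": cand.accepted,
                        "rank": order.get(id(cand), ""),
                    }
                )
            import pandas as pd

            pd.DataFrame(guide_rows).to_csv(out / "guides.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("guides", exc) from exc

    write_site_outputs(catalog, out / "sites.bed", out / "sites.tsv")

    freq_hist: dict[int, int] = {}
    for s in catalog.sites:
        freq_hist[s.detection_frequency] = freq_hist.get(s.detection_frequency, 0) + 1
    strand_counts = {
        "+": sum(1 for s in catalog.secondary_sites() if s.strand == "+"),
        "-": sum(1 for s in catalog.secondary_sites() if s.strand == "-"),
    }
    summary.update(
        {
            "filter": {
                "total": total_report.total,
                "accepted": total_report.accepted,
                "rejected": total_report.rejected,
            },
            "mapping": map_counts_total,
            "sites": {
                "total": len(catalog),
                "secondary": len(catalog.secondary_sites()),
                "attB": len(catalog) - len(catalog.secondary_sites()),
                "attB_reads_total": catalog.attB_reads_total,
                "secondary_reads_total": catalog.secondary_reads_total,
                "ratio_secondary_to_attB": catalog.ratio_secondary_to_attB,
                "detection_frequency_histogram": {str(k): v for k, v in sorted(freq_hist.items())},
                "strand_counts": strand_counts,
            },
            "gene_context": gene_summary,
            "motif": {
                "scan_mean": scan.mean if scan else None,
                "scan_sd": scan.sd if scan else None,
                "n_windows_scanned": scan.n_windows if scan else 0,
                "group_means": (
                    {str(r["group"]): r["mean_score"] for _, r in per_class.iterrows()}
                    if per_class is not None
                    else None
                ),
            },
            "guides": {"n_candidates": len(guide_rows),
                       "n_accepted": sum(1 for g in guide_rows if g["accepted"])},
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
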