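"""Convert uniquely mapped junctions into an integration-site catalog.

Sites are keyed by (position, strand) where position is the 1-based
coordinate of the first base of the 7-nt strand-exchange region on the
integration strand. The catalog carries per-replicate read counts, detection
frequencies, the attB/secondary split with its read-ratio statistic, and
gene-context categories.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .mapper import JunctionMapping
from .sequence_io import GeneAnnotation

logger = logging.getLogger(__name__)

CATEGORIES = ("within_gene", "upstream", "downstream", "intergenic_far")
# detection-frequency display classes: found in 1, 2-4, or >4 replicates
FREQUENCY_CLASSES = (("1", 1, 1), ("2-4", 2, 4), (">4", 5, 10**9))


def frequency_class(detection_frequency: int) -> str:
    for label, lo, hi in FREQUENCY_CLASSES:
        if lo <= detection_frequency <= hi:
            return label
    raise ValueError(f"bad detection frequency {detection_frequency}")


@dataclass
class IntegrationSite:
    position: int  # 1-based, first base of the strand-exchange region
    strand: str
    reads_per_replicate: dict[str, int] = field(default_factory=dict)
    detection_frequency: int = 0
    is_attB: bool = False
    nearest_gene: str | None = None
    category: str | None = None
    motif_score: float | None = None
    relative_score: float | None = None
    site_id: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_replicate.values())


@dataclass
class SiteCatalog:
    sites: list[IntegrationSite] = field(default_factory=list)
    n_replicates: int = 0
    genome_name: str = "genome"
    attB_reads_total: int = 0
    secondary_reads_total: int = 0
    ratio_secondary_to_attB: float | None = None

    def __len__(self) -> int:
        return len(self.sites)

    def secondary_sites(self) -> list[IntegrationSite]:
        return [s for s in self.sites if not s.is_attB]

    def site_by_key(self, position: int, strand: str) -> IntegrationSite | None:
        for s in self.sites:
            if s.position == position and s.strand == strand:
                return s
        return None


def infer_junction(
    mapping: JunctionMapping,
    overlap_trim: int,
    genome_length: int,
    circular: bool = True,
) -> tuple[int, str]:
    """Integration-site coordinate implied by a uniquely mapped junction.

    The mapped read-1 remnant begins immediately 3' of the trimmed
    strand-exchange region, so the site sits ``overlap_trim`` bases toward
    the anchor: upstream on '+' hits, downstream (in forward coordinates) on
    '-' hits. Returns (1-based position, strand), wrapped on circular genomes.
    """
    if mapping.status != "unique":
        raise ValueError(f"infer_junction requires a unique mapping, got {mapping.status}")
    hit = mapping.read1_hit
    if hit.strand == "+":
        pos0 = hit.ref_start - overlap_trim
    else:
        pos0 = hit.ref_start + overlap_trim
    if circular:
        pos0 %= genome_length
    elif not 0 <= pos0 < genome_length:
        raise ValueError(f"junction position {pos0} outside linear genome")
    return pos0 + 1, hit.strand


def collapse_and_merge(
    junctions_by_replicate: Mapping[str, Sequence[tuple[int, str]]],
    tolerance: int = 0,
    min_reads: int = 1,
    n_replicates: int | None = None,
    genome_name: str = "genome",
) -> SiteCatalog:
    """Merge per-replicate junction calls into a deduplicated site catalog.

    Junctions on the same strand within ``tolerance`` nt merge into one site
    (default 0: exact coordinate, since the overlap trim already normalizes
    the junction register); the representative position is the one with the
    most reads. ``detection_frequency`` counts replicates with at least
    ``min_reads`` reads.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    replicates = sorted(junctions_by_replicate)
    counts: dict[tuple[int, str], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for rep in replicates:
        for pos, strand in junctions_by_replicate[rep]:
            counts[(pos, strand)][rep] += 1

    # cluster per strand by chaining positions closer than tolerance
    merged: dict[tuple[int, str], dict[str, int]] = {}
    for strand in ("+", "-"):
        keyed = sorted(
            (pos, per_rep) for (pos, s), per_rep in counts.items() if s == strand
        )
        cluster: list[tuple[int, dict[str, int]]] = []

        def flush() -> None:
            if not cluster:
                return
            rep_counts: dict[str, int] = defaultdict(int)
            for _, per_rep in cluster:
                for rep, c in per_rep.items():
                    rep_counts[rep] += c
            # representative = position with most reads, smallest on ties
            rep_pos = max(cluster, key=lambda t: (sum(t[1].values()), -t[0]))[0]
            merged[(rep_pos, strand)] = dict(rep_counts)

        prev: int | None = None
        for pos, per_rep in keyed:
            if prev is not None and pos - prev > tolerance:
                flush()
                cluster = []
            cluster.append((pos, per_rep))
            prev = pos
        flush()

    sites = []
    for (pos, strand), per_rep in sorted(merged.items()):
        full = {rep: per_rep.get(rep, 0) for rep in replicates}
        detection = sum(1 for c in full.values() if c >= min_reads)
        sites.append(
            IntegrationSite(
                position=pos,
                strand=strand,
                reads_per_replicate=full,
                detection_frequency=detection,
            )
        )
    sites.sort(key=lambda s: (s.position, s.strand))
    for i, site in enumerate(sites, 1):
        site.site_id = f"site_{i:04d}"
    return SiteCatalog(
        sites=sites,
        n_replicates=n_replicates if n_replicates is not None else len(replicates),
        genome_name=genome_name,
    )


def mappings_to_catalog(
    mappings_by_replicate: Mapping[str, Sequence[JunctionMapping]],
    overlap_trim: int,
    genome_length: int,
    circular: bool = True,
    tolerance: int = 0,
    min_reads: int = 1,
    genome_name: str = "genome",
) -> SiteCatalog:
    """Convenience composition: infer junctions from unique mappings, then merge."""
    junctions = {
        rep: [
            infer_junction(m, overlap_trim, genome_length, circular)
            for m in ms
            if m.status == "unique"
        ]
        for rep, ms in mappings_by_replicate.items()
    }
    return collapse_and_merge(
        junctions, tolerance=tolerance, min_reads=min_reads, genome_name=genome_name
    )


def _circular_distance(a: int, b: int, n: int | None) -> int:
    d = abs(a - b)
    if n is None:
        return d
    d %= n
    return min(d, n - d)


def classify_attB(
    catalog: SiteCatalog,
    attB_position: int | None = None,
    attB_strand: str | None = None,
    window: int = 10,
    genome_length: int | None = None,
    auto: bool = False,
) -> SiteCatalog:
    """Flag attB-proximal sites and compute the secondary:attB read ratio.

    ``attB_position`` is 1-based. In ``auto`` mode the single site with the
    most reads is taken as attB. Sites within +-``window`` nt (circular when
    ``genome_length`` given) are flagged ``is_attB``; the ratio is
    secondary_reads_total / attB_reads_total (None when undefined).
    """
    if auto:
        if not catalog.sites:
            logger.warning("empty catalog: no attB site found in auto mode")
            catalog.ratio_secondary_to_attB = None
            return catalog
        top = max(catalog.sites, key=lambda s: s.total_reads)
        attB_position, attB_strand = top.position, top.strand
    if attB_position is None:
        raise ValueError("attB_position required unless auto=True")
    for site in catalog.sites:
        site.is_attB = _circular_distance(site.position, attB_position, genome_length) <= window
    catalog.attB_reads_total = sum(s.total_reads for s in catalog.sites if s.is_attB)
    catalog.secondary_reads_total = sum(
        s.total_reads for s in catalog.sites if not s.is_attB
    )
    if catalog.attB_reads_total > 0:
        catalog.ratio_secondary_to_attB = (
            catalog.secondary_reads_total / catalog.attB_reads_total
        )
    else:
        logger.warning("no reads at attB; secondary:attB ratio undefined")
        catalog.ratio_secondary_to_attB = None
    return catalog


def categorize_by_gene(
    catalog: SiteCatalog,
    annotation: GeneAnnotation,
    near_window: int = 500,
) -> dict:
    """Assign each site a gene-context category and summarize the catalog.

    A site inside a CDS/rRNA span is ``within_gene``; otherwise the nearest
    gene decides: within ``near_window`` nt the site is ``upstream`` when it
    lies 5' of the gene start in the gene's own orientation, ``downstream``
    when 3' of its end; anything farther is ``intergenic_far``. Distances are
    linear (annotation coordinates).
    """
    genes = annotation.genes()
    if not genes:
        logger.warning("empty annotation: all sites marked intergenic_far")
        for site in catalog.sites:
            site.category = "intergenic_far"
            site.nearest_gene = None
    else:
        for site in catalog.sites:
            pos = site.position
            containing = [g for g in genes if g.start <= pos <= g.end]
            if containing:
                # most specific (smallest) containing feature
                gene = min(containing, key=lambda g: g.end - g.start)
                site.category = "within_gene"
                site.nearest_gene = gene.name
                continue
            gene = min(
                genes,
                key=lambda g: (pos - g.end if pos > g.end else g.start - pos, g.start),
            )
            dist = pos - gene.end if pos > gene.end else gene.start - pos
            site.nearest_gene = gene.name
            if dist > near_window:
                site.category = "intergenic_far"
            elif pos < gene.start:
                site.category = "upstream" if gene.strand == "+" else "downstream"
            else:
                site.category = "downstream" if gene.strand == "+" else "upstream"

    n = len(catalog.sites)
    category_counts = {c: 0 for c in CATEGORIES}
    strand_counts = {"+": 0, "-": 0}
    for site in catalog.sites:
        category_counts[site.category] += 1
        strand_counts[site.strand] += 1
    return {
        "n_sites": n,
        "within_gene_fraction": (category_counts["within_gene"] / n) if n else None,
        "category_counts": category_counts,
        "strand_counts": strand_counts,
    }
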