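import math

import numpy as np
import pytest

from lambdaint.junction_filter import FilterConfig, filter_library
from lambdaint.mapper import JunctionMapping, MapperConfig, MappingHit, build_index, map_library
from lambdaint.sequence_io import GeneAnnotation, GeneRecord, read_fastq_pairs, revcomp
from lambdaint.site_caller import (
    IntegrationSite,
    SiteCatalog,
    categorize_by_gene,
    classify_attB,
    collapse_and_merge,
    frequency_class,
    infer_junction,
    mappings_to_catalog,
)
from lambdaint.synthetic import (
    SimulationConfig,
    default_motif_matrix,
    generate_genome,
    plant_sites,
    simulate_library,
)


def _unique_mapping(ref_start, strand):
    hit = MappingHit(ref_start=ref_start, strand=strand, identity=1.0, n_mismatches=0, length=23)
    return JunctionMapping("p", "r", hit, None, "unique")


def run_pipeline(cfg, genome, paths):
    """filter -> map -> junctions per replicate (shared by several tests)."""
    idx = build_index(genome)
    mappings = {}
    for i, (r1, r2) in enumerate(paths):
        rep = f"rep{i + 1}"
        accepted, _ = filter_library(read_fastq_pairs(r1, r2, rep), FilterConfig(anchor=cfg.anchor))
        mappings[rep], _ = map_library(accepted, idx, genome, MapperConfig())
    return mappings


class TestInferJunction:
    def test_plus_strand_arithmetic(self):
        pos, strand = infer_junction(_unique_mapping(107, "+"), 7, 10_000)
        assert (pos, strand) == (101, "+")

    def test_minus_strand_arithmetic(self):
        pos, strand = infer_junction(_unique_mapping(93, "-"), 7, 10_000)
        assert (pos, strand) == (101, "-")

    def test_wraparound(self):
        pos, strand = infer_junction(_unique_mapping(3, "+"), 7, 10_000)
        assert (pos, strand) == (9_997, "+")

    def test_non_unique_rejected(self):
        m = JunctionMapping("p", "r", None, None, "ambiguous")
        with pytest.raises(ValueError):
            infer_junction(m, 7, 10_000)

    def test_simulator_round_trip_both_strands(self, small_sim):
        cfg, genome, manifest, paths = small_sim
        mappings = run_pipeline(cfg, genome, paths)
        called = set()
        for rep, ms in mappings.items():
            for m in ms:
                if m.status == "unique":
                    called.add(infer_junction(m, 7, len(genome)))
        truth = {(s.position + 1, s.strand) for s in manifest.all_sites
                 if sum(s.reads_per_replicate) > 0}
        assert called == truth
        assert any(s == "-" for _, s in truth)  # both strands exercised

    def test_origin_spanning_site_recovered(self, tmp_path):
        # force a site whose window spans the circular origin
        cfg = SimulationConfig(genome_length=5_000, n_secondary_sites=0,
                               n_replicates=1, reads_per_replicate=200, seed=3)
        genome, manifest = plant_sites(generate_genome(cfg), default_motif_matrix(), cfg)
        manifest.attB.position = 2  # overlap region spans the origin
        seq = list(genome.sequence)
        start = manifest.attB.position - 14
        window = (manifest.attB.window if manifest.attB.strand == "+"
                  else revcomp(manifest.attB.window))
        for j, b in enumerate(window):
            seq[(start + j) % len(seq)] = b
        genome.sequence = "".join(seq)
        paths = simulate_library(genome, manifest, cfg, tmp_path)
        mappings = run_pipeline(cfg, genome, paths)
        catalog = mappings_to_catalog(mappings, 7, len(genome))
        assert {(s.position, s.strand) for s in catalog.sites} == {
            (manifest.attB.position + 1, manifest.attB.strand)
        }


class TestCollapseAndMerge:
    def test_detection_frequency_and_class(self):
        junctions = {f"rep{i}": [(500, "+")] for i in range(1, 6)}
        junctions.update({f"rep{i}": [] for i in range(6, 9)})
        catalog = collapse_and_merge(junctions)
        assert len(catalog) == 1
        site = catalog.sites[0]
        assert site.detection_frequency == 5
        assert frequency_class(site.detection_frequency) == ">4"

    def test_opposite_strands_distinct(self):
        catalog = collapse_and_merge({"r1": [(100, "+"), (100, "-")]})
        assert len(catalog) == 2

    def test_tolerance_merging(self):
        junctions = {"r1": [(100, "+")], "r2": [(101, "+")]}
        assert len(collapse_and_merge(junctions, tolerance=0)) == 2
        merged = collapse_and_merge(junctions, tolerance=2)
        assert len(merged) == 1
        assert merged.sites[0].reads_per_replicate == {"r1": 1, "r2": 1}

    def test_negative_tolerance(self):
        with pytest.raises(ValueError):
            collapse_and_merge({}, tolerance=-1)

    def test_read_conservation(self, small_sim):
        cfg, genome, manifest, paths = small_sim
        mappings = run_pipeline(cfg, genome, paths)
        n_unique = sum(
            1 for ms in mappings.values() for m in ms if m.status == "unique"
        )
        catalog = mappings_to_catalog(mappings, 7, len(genome))
        assert sum(s.total_reads for s in catalog.sites) == n_unique

    def test_per_replicate_counts_match_manifest(self, small_sim):
        cfg, genome, manifest, paths = small_sim
        mappings = run_pipeline(cfg, genome, paths)
        catalog = mappings_to_catalog(mappings, 7, len(genome))
        for planted in manifest.all_sites:
            if sum(planted.reads_per_replicate) == 0:
                continue
            site = catalog.site_by_key(planted.position + 1, planted.strand)
            assert site is not None
            got = [site.reads_per_replicate[f"rep{i + 1}"] for i in range(cfg.n_replicates)]
            assert got == planted.reads_per_replicate


class TestClassifyAttB:
    def _catalog(self, reads_attB, reads_sec):
        sites = [
            IntegrationSite(position=1_000, strand="+",
                            reads_per_replicate={"r1": reads_attB}),
            IntegrationSite(position=5_000, strand="-",
                            reads_per_replicate={"r1": reads_sec}),
        ]
        return SiteCatalog(sites=sites, n_replicates=1)

    def test_flag_and_ratio(self):
        catalog = classify_attB(self._catalog(200, 10), 1_000, "+")
        assert catalog.sites[0].is_attB and not catalog.sites[1].is_attB
        assert catalog.ratio_secondary_to_attB == pytest.approx(0.05)

    def test_window_tolerance(self):
        catalog = classify_attB(self._catalog(200, 10), 1_008, "+", window=10)
        assert catalog.sites[0].is_attB

    def test_only_attB_ratio_zero(self):
        catalog = SiteCatalog(sites=[IntegrationSite(position=10, strand="+",
                                                     reads_per_replicate={"r1": 5})])
        catalog = classify_attB(catalog, 10, "+")
        assert catalog.ratio_secondary_to_attB == 0.0
        assert len(catalog.secondary_sites()) == 0

    def test_auto_picks_max_reads(self):
        catalog = classify_attB(self._catalog(200, 10), auto=True)
        assert catalog.sites[0].is_attB

    def test_empty_catalog_na(self, caplog):
        with caplog.at_level("WARNING"):
            catalog = classify_attB(SiteCatalog(), auto=True)
        assert catalog.ratio_secondary_to_attB is None

    def test_auto_matches_truth_on_simulation(self, small_sim):
        cfg, genome, manifest, paths = small_sim
        mappings = run_pipeline(cfg, genome, paths)
        catalog = mappings_to_catalog(mappings, 7, len(genome))
        auto = classify_attB(catalog, auto=True, genome_length=len(genome))
        attB_sites = [s for s in auto.sites if s.is_attB]
        assert [(s.position, s.strand) for s in attB_sites] == [
            (manifest.attB.position + 1, manifest.attB.strand)
        ]

    def test_planted_ratio_recovered(self, small_sim):
        cfg, genome, manifest, paths = small_sim
        mappings = run_pipeline(cfg, genome, paths)
        catalog = mappings_to_catalog(mappings, 7, len(genome))
        catalog = classify_attB(catalog, manifest.attB.position + 1,
                                manifest.attB.strand, genome_length=len(genome))
        f = cfg.secondary_read_fraction
        n = catalog.attB_reads_total + catalog.secondary_reads_total
        p = f / (1 + f)
        sigma = math.sqrt(p * (1 - p) / n) / (1 - p)
        assert abs(catalog.ratio_secondary_to_attB - f) <= 3 * sigma

    def test_ratio_estimator_unbiased_over_seeds(self, tmp_path):
        f = 0.05
        ratios = []
        for seed in range(20):
            cfg = SimulationConfig(
                genome_length=10_000, n_secondary_sites=3, n_replicates=2,
                reads_per_replicate=1_000, secondary_read_fraction=f, seed=100 + seed,
            )
            genome, manifest = plant_sites(generate_genome(cfg), default_motif_matrix(), cfg)
            paths = simulate_library(genome, manifest, cfg, tmp_path / str(seed))
            mappings = run_pipeline(cfg, genome, paths)
            catalog = mappings_to_catalog(mappings, 7, len(genome))
            catalog = classify_attB(catalog, manifest.attB.position + 1,
                                    manifest.attB.strand, genome_length=len(genome))
            ratios.append(catalog.ratio_secondary_to_attB)
        assert abs(np.mean(ratios) - f) <= 0.1 * f

    def test_strand_balance_on_symmetric_simulation(self):
        cfg = SimulationConfig(genome_length=200_000, n_secondary_sites=300, seed=21)
        _, manifest = plant_sites(generate_genome(cfg), default_motif_matrix(), cfg)
        n_plus = sum(1 for s in manifest.secondary_sites if s.strand == "+")
        n_minus = len(manifest.secondary_sites) - n_plus
        assert abs(n_plus - n_minus) <= 2 * 3 * math.sqrt(300 * 0.25)


def _annotation():
    return GeneAnnotation(records=[
        GeneRecord("geneA", 100, 200, "+", "CDS"),
        GeneRecord("geneB", 1_000, 1_400, "-", "CDS"),
        GeneRecord("rrsX", 5_000, 6_500, "+", "rRNA"),
    ])


def _site(pos, strand="+"):
    return IntegrationSite(position=pos, strand=strand, reads_per_replicate={"r1": 1})


class TestCategorizeByGene:
    def test_within_cds(self):
        catalog = SiteCatalog(sites=[_site(150)])
        categorize_by_gene(catalog, _annotation())
        assert catalog.sites[0].category == "within_gene"
        assert catalog.sites[0].nearest_gene == "geneA"

    def test_upstream_downstream_orientation(self):
        # site at 95, 5 nt before a + gene starting at 100 -> upstream
        catalog = SiteCatalog(sites=[_site(95)])
        categorize_by_gene(catalog, GeneAnnotation([GeneRecord("g", 100, 200, "+", "CDS")]))
        assert catalog.sites[0].category == "upstream"
        # same position, - strand gene (its start is coordinate 200) -> downstream
        catalog = SiteCatalog(sites=[_site(95)])
        categorize_by_gene(catalog, GeneAnnotation([GeneRecord("g", 100, 200, "-", "CDS")]))
        assert catalog.sites[0].category == "downstream"

    def test_downstream_of_plus_gene(self):
        catalog = SiteCatalog(sites=[_site(210)])
        categorize_by_gene(catalog, GeneAnnotation([GeneRecord("g", 100, 200, "+", "CDS")]))
        assert catalog.sites[0].category == "downstream"

    def test_intergenic_far(self):
        catalog = SiteCatalog(sites=[_site(50_000)])
        summary = categorize_by_gene(catalog, _annotation(), near_window=500)
        assert catalog.sites[0].category == "intergenic_far"
        assert summary["within_gene_fraction"] == 0.0

    def test_empty_annotation_warns(self, caplog):
        catalog = SiteCatalog(sites=[_site(100)])
        with caplog.at_level("WARNING"):
            categorize_by_gene(catalog, GeneAnnotation([]))
        assert catalog.sites[0].category == "intergenic_far"

    def test_rrna_counts_as_gene(self):
        catalog = SiteCatalog(sites=[_site(5_500)])
        categorize_by_gene(catalog, _annotation())
        assert catalog.sites[0].category == "within_gene"
        assert catalog.sites[0].nearest_gene == "rrsX"

    def test_within_gene_fraction_construction_echo(self):
        # catalog built so exactly 77.6% of sites (194/250) sit inside CDS spans
        genes = [GeneRecord(f"g{i}", 10_000 + 1_000 * i, 10_400 + 1_000 * i, "+", "CDS")
                 for i in range(194)]
        sites = [_site(10_100 + 1_000 * i) for i in range(194)]
        sites += [_site(700 + 2 * i) for i in range(56)]  # far from every gene
        catalog = SiteCatalog(sites=sites)
        summary = categorize_by_gene(catalog, GeneAnnotation(genes), near_window=100)
        assert summary["n_sites"] == 250
        assert summary["within_gene_fraction"] == pytest.approx(0.776, abs=1 / 250)

    def test_summary_strand_counts(self):
        catalog = SiteCatalog(sites=[_site(150, "+"), _site(160, "-"), _site(170, "-")])
        summary = categorize_by_gene(catalog, _annotation())
        assert summary["strand_counts"] == {"+": 1, "-": 2}
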