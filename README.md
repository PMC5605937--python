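# lambdaint

Detection of bacteriophage integration sites in a bacterial genome from
junction-enriched paired-end sequencing reads, with downstream motif (PSSM)
analysis and a CRISPR sgRNA selection-design helper. A built-in synthetic
library simulator with a ground-truth manifest makes every stage verifiable
at desk scale.

## Method overview

Read 1 of each junction pair carries a constant 45-nt phage anchor, then the
7-nt strand-exchange overlap, then the host flank; read 2 is the distal end
of the fragment. The pipeline:

1. **filter** — keep pairs whose read 1 contains the anchor with *no*
   mismatch; strip the anchor, quality-trim the 3′ end (minimum Phred 10,
   mean ≥ 15), trim the 7-base strand-exchange region, and require ≥ 16
   remaining bases plus a 20-base read-2 prefix.
2. **map** — seed-and-extend ungapped mapping of both mates at a 95%
   identity cutoff (both strands, circular-aware), with concordant-pair
   resolution (unique / ambiguous / unmapped / discordant).
3. **call** — infer the integration coordinate from each uniquely mapped
   junction, merge across replicates into a site catalog with per-replicate
   read counts and detection frequencies, flag attB, compute the
   secondary:attB read ratio, and categorize sites against a GFF3 annotation
   (within gene / upstream / downstream / intergenic).
4. **motif** — build a 29-base position-specific scoring matrix over the
   detected sites (label 0 = first overlap base), score each site, scan the
   whole genome for the baseline score distribution, and relate score to
   detection frequency.
5. **guides** — enumerate NGG-adjacent 20-mers near a site, require the
   target to span the junction (so integration disrupts it) and be unique in
   the genome within a mismatch budget.
6. **simulate** — generate a random genome with one planted attB site plus
   motif-sampled secondary sites and emit per-replicate paired FASTQ with a
   JSON ground-truth manifest.

## CLI

```bash
# end-to-end on a simulated library
lambdaint all --out-dir run1 --seed 7

# stage by stage
lambdaint simulate --out-dir sim --seed 7
lambdaint filter --r1 sim/reads/rep1_R1.fastq --r2 sim/reads/rep1_R2.fastq \
    --out-fasta rep1.fasta --report rep1_filter.json
lambdaint map --genome sim/genome.fasta --trimmed rep1.fasta --out rep1_map.tsv
lambdaint call --genome sim/genome.fasta --mappings rep1_map.tsv ... --out-dir calls
lambdaint motif --catalog calls/sites.tsv --genome sim/genome.fasta --out-dir motif_out
lambdaint guides --genome sim/genome.fasta --site 12345,+ --out guides.tsv
```

`lambdaint all` accepts a YAML config (`--config`) mirroring
`PipelineConfig`; all defaults match the assay's published thresholds
(45-nt anchor, 7-base overlap trim, 16/20 length floors, Phred 10/15,
95% identity, 29-base motif window, 8 replicates).

Outputs: `sites.tsv` (1-based) + `sites.bed` (BED6), `matrix.meme`,
`filter_report.json`, `score_by_frequency.tsv`, `scan_histogram.tsv`,
`guides.tsv`, and a machine-readable `summary.json` with all stage counts.

## Layout

```
src/lambdaint/
  sequence_io.py     FASTA/FASTQ/GFF3/BED/TSV I/O, circular Genome
  synthetic.py       library simulator + ground-truth manifest
  junction_filter.py anchor/quality/overlap trimming cascade
  mapper.py          seed-and-extend mapper, identity cutoff, pairing
  site_caller.py     junction inference, replicate merging, attB/gene context
  motif.py           PSSM build/score, genome scan, frequency grouping
  guides.py          sgRNA enumeration, off-target scan, uniqueness screen
  pipeline.py        config, validation, end-to-end orchestration
  cli.py             click CLI
```
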