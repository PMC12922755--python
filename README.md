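# aneucall

Arm-level aneuploidy analysis for low-pass WGS cohorts of pancreatic
neoplasia, with a ground-truthed synthetic-cohort simulator so every stage
can be exercised and verified without external data.

The package covers:

- **genome_model** — hg19 autosome scaffolding: 500-kb bin grids anchored at
  position 1, p/q arm definitions from packaged centromere coordinates,
  named driver loci (1q23.2, 1q42.13, 8q24.21, MYC), BED I/O.
- **synthetic_cohort** — seeded generation of karyotypes (grade-dependent
  arm/focal gain-loss probabilities, whole-genome doubling, purity
  admixture), median-normalized bin-call rendering, per-nucleus FISH counts,
  dosage-responsive expression matrices, and UID-barcoded duplex amplicon
  reads, all with a machine-readable truth table.
- **cna_calls** — bin-call matrix ingest ({G,N,L} per 500-kb bin), sample QC
  (strict MAD < 0.15; variance-ratio flagging), arm-level event calling
  (full-arm rule: gained bins ≥ arm bins − 3; partial events need a run of
  ≥ `min_run` consecutive altered bins, default 6 = 3 Mb), cohort frequency
  tables, full-vs-partial breakdowns.
- **focal_mapping** — per-bin gain-fraction profiles over tumors with
  subchromosomal gains, plateau peak detection, locus-inclusion calls
  (strict majority of overlapping bins), joint two-locus classification, and
  a copy-number–expression correlation screen (default α = 1e-5).
- **cooccur_stats** — exact two-tailed Fisher test implemented from first
  principles (method of small p-values), context-event fractions among
  focal-event carriers, between-stratum comparisons, pairwise
  independence/exclusivity tables with Haldane-corrected odds ratios.
- **fish_scoring** — signal-count capping at 10, per-sample summaries
  (mean, % nuclei ≥ 3 and ≥ 4 signals), positivity rules (≥ 3 in ≥ 20%,
  ≥ 4 in ≥ 10%, strict majority), and WGS/FISH concordance classification
  (low-purity vs relative-copy-number discordance).
- **duplex_caller** — 14-nt UID extraction, Watson/Crick strand assignment,
  duplex grouping, consensus variant support (> 80% of reads in *both*
  strand families), and the filter chain: > 2 mutant template molecules,
  ≥ 5× template coverage, ≥ 30 bp from the template ends, ≥ 2
  catalog annotations with a confirmed-somatic flag, and the ≥ 10 KRAS
  template sample gate.
- **cli_pipeline / cli** — end-to-end orchestration with deterministic,
  seed-reproducible outputs and summary plots.

## CLI

```sh
# simulate a cohort with ground truth
aneucall simulate --seed 7 --n-per-grade '{"PDAC": 50, "HG_PANIN": 20}' --out sim/

# arm-level calls + frequency tables
aneucall call-arms --bins sim/bin_calls.tsv --meta sim/lesion_meta.tsv --out arms/

# localize minimal commonly gained regions
aneucall localize --bins sim/bin_calls.tsv --arm 1q --mode partial_only --out loc/

# co-occurrence context statistics
aneucall cooccur --arm-calls arms/arm_calls.tsv --meta sim/lesion_meta.tsv \
    --focal 1q:GAIN --context 8q:GAIN,9p:LOSS,17p:LOSS,18q:LOSS --out ctx.json

# FISH scoring
aneucall fish-score --counts sim/fish_counts.tsv --rule ge3_at_20pct --out fish.tsv

# duplex mutation calling
aneucall duplex-call --fastq r1.fastq r2.fastq --amplicons amplicons.tsv \
    --cosmic cosmic.tsv --out calls/

# full pipeline with report + plots
aneucall report --seed 7 --out run/ --plots
```

All file formats are plain text: TSV matrices (`chrom`, `start`, `end`, one
column per sample; calls in {G,N,L}), BED for loci (0-based half-open on
disk, converted to 1-based inclusive on read), uncompressed FASTQ for reads
(UID = first 14 bases of read 1), JSON for reports and truth tables.

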