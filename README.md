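# magcurate

Curation toolkit for metagenome-assembled genome (MAG) bins from non-axenic
cultures. It implements the computations that sit *around* a standard
assembly/binning/QC pipeline:

- **Preset selection** for a composition+coverage binner by ordered bin QC
  statistics (contamination, then strain heterogeneity, then completeness).
- **rRNA-fate diagnostics**: why contigs carrying multi-copy rRNA operons are
  rejected by binning — excess coverage and divergent tetranucleotide
  frequencies (TNFs) — and mechanical affiliation of classified rRNA genes to
  taxonomically congruent bins.
- **Contamination screening** of a bin by splitting it into non-overlapping
  250-nt pseudo-reads and classifying each by its best homology hit.
- **Completeness-normalized genomic identity**: a k-mer containment measure
  that compares bins of very different completeness on an equal footing.
- **Reporting**: type-7 quantile summaries, Pearson correlations and bin
  accounting over packaged bin-QC and rRNA fixture tables.
- A **seeded synthetic community generator** (genome-specific Markov-chain
  compositions, distinct coverage levels, collapsed multi-copy rRNA operons,
  truth labels) so every stage is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `magcurate.formats_io` | FASTA, depth/QC/rRNA/hit/bin tables, GFF loci, packaged fixtures |
| `magcurate.synthetic_community` | seeded synthetic metagenomes with truth labels |
| `magcurate.composition_profiles` | 136-dim canonical TNF vectors, bin profiles, divergence scores |
| `magcurate.reference_binning` | single-linkage TNF+coverage binner, presets, preset selection, merge advisory, quality tiers |
| `magcurate.rrna_fate` | loss-mechanism verdicts for rRNA loci; taxon-congruence affiliation |
| `magcurate.contamination_screen` | pseudo-read splitting, best-hit classification, foreign fraction |
| `magcurate.bin_identity` | canonical k-mer sets and completeness-normalized containment |
| `magcurate.reporting_stats` | type-7 quantiles, Pearson r, bin accounting, OG filtering |

Packaged data (`src/magcurate/data/`): transcribed bin QC (`table3.tsv`) and
SSU rRNA (`table4.tsv`) fixture tables, phylum group sets, a small taxonomy
and an rRNA-label synonym map.

## CLI

All commands are subcommands of `magcurate`:

```sh
magcurate simulate --genomes specs.tsv --seed 1 --out community/
magcurate bin --fasta contigs.fasta --depth depth.tsv --preset veryspecific --out bins.tsv
magcurate select-preset --qc-dir qc_tables/
magcurate tnf --fasta contigs.fasta --bins bins.tsv --depth depth.tsv --out divergence.tsv
magcurate rrna-fate --gff rrna.gff --bins bins.tsv --fasta contigs.fasta --depth depth.tsv --out fate.tsv
magcurate affiliate --rrna-taxa loci.tsv --bin-taxa bins_taxa.tsv
magcurate contam --fasta bin.fasta --hits hits.tsv --self-taxon Cyanobacteria --out screen.tsv
magcurate identity --a binA.fasta --b binB.fasta --completeness-a 0.9 --completeness-b 0.5
magcurate report --out report.json
magcurate og-filter --table ogs.tsv --min-organisms 62 --max-mean-copy 1.1
```

Tabular dialects are tab-separated UTF-8 with a header row; missing values
are written as `na` and parsed to an explicit missing state, never 0. Depth
tables use the MetaBAT-style columns `contigName`, `contigLen`,
`totalAvgDepth`.

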