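# scafpipe

A draft-genome analysis toolkit covering four stages that commonly follow a
de novo assembly, plus seeded synthetic-data generators so every stage is
testable closed-loop against known truth:

- **Assembly I/O and statistics** — FASTA/GFF3/map/hit-table readers and
  writers, length filtering, N50/GC/N statistics (`scafpipe.genome_io`).
- **K-mer genome-size estimation** — vectorised canonical k-mer counting,
  error-trough / coverage-peak detection (heterozygous and homozygous
  peaks), genome size from the homozygous peak (`scafpipe.kmer`).
- **Scaffold anchoring and pseudomolecules** — genetic-map assignment
  (majority linkage group, orientation from the cM-vs-bp slope) and
  synteny assignment (collinear best-hit runs of ≥5 genes, OLS R² > 0.6),
  conflict resolution with map precedence, ordering with cM→bp projection,
  concatenation with 10 kb N spacers, AGP v2.1 output and GFF3/map
  coordinate liftover, per-chromosome reporting (`scafpipe.anchoring`).
- **Variant analysis** — VCF hard filtering with two presets (ddRAD:
  DP≥5, quality >10, MAF≥0.2, missing <0.5; resequencing: quality ≥50,
  GQ≥20, DP∈[10,100]), substitution spectrum and Ts/Tv, densities per
  100 kb of non-N sequence, per-sample heterozygosity, and effect
  classification into SO terms with HIGH/MODERATE/LOW/MODIFIER impacts
  (`scafpipe.variants`).
- **Marker design** — CAPS scanning against a 19-enzyme palindromic panel,
  ≤15 bp indel marker selection, imperfect-SSR detection (seeded,
  mismatch-penalised extension with canonical motifs), genic
  classification, and deterministic primer design with nearest-neighbour
  melting temperatures (`scafpipe.markers`).
- **Synthetic data** — seeded generators for genomes (with valid ORFs and
  SSR implants), scaffold fragmentations, genetic maps, ortholog hit
  tables, diploid variant sets with target Ts/Tv, and uniform-coverage
  reads, each with a truth table (`scafpipe.synthetic`).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and an
acceptance suite (`tests/test_acceptance.py`) that checks published
arithmetic identities, closed-loop anchoring/genome-size recovery on
synthetic data, dual-route oracle equivalences (CAPS digests, SSR dynamic
programming, effect retranslation, exhaustive primer scan) and structural
identities (AGP/liftover round trips, threshold monotonicity).

## CLI

```sh
scafpipe stats scaffolds.fasta --min-len 1000
scafpipe kmer reads.fastq -k 17
scafpipe anchor scaffolds.fasta --map map.tsv --hits hits.tsv \
    --genes genes.gff3 --ref-lengths chrom_lengths.tsv \
    --r2 0.6 --min-genes 5 --spacer 10000 --min-orient-markers 2
scafpipe variants calls.vcf --preset reseq --genome asm.fasta --genes genes.gff3
scafpipe markers asm.fasta --vcf calls.vcf --genes genes.gff3
scafpipe simulate genome --seed 1 --config genome.yaml --out sim/
scafpipe report --stats-dir stats_out --anchor-dir anchor_out
```

Every randomised subcommand requires an explicit `--seed`; every run writes
a `manifest.json` with parameters, input digests and the package version.

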