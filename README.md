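# dibench

Benchmarking toolkit for evaluating genome assemblies, aligned sequencing
reads and phased variant call sets against a **complete diploid truth
genome**. Given the two haplotype sequences of a benchmark individual,
`dibench` catalogs every base-level difference of a test dataset in truth
coordinates, phase-aware.

What it computes:

* **Benchmark index** — heterozygous-site catalog (from hap1-vs-hap2
  alignments), haplotype-specific canonical k-mer markers (default k=31),
  short tandem run annotations (1-4 bp units), low-confidence regions.
* **Haplotype phasing of assemblies** — a two-state HMM over marker
  observations segments each contig into hap1/hap2 blocks; phase-switch
  counts and rates per aligned Mb.
* **Assembly evaluation** — NGAx continuity from alignment blocks (broken at
  indels ≥ 10 kb), a discrepancy catalog (12 substitution types with Ti/Tv,
  indels, and phase-consistent alleles at het sites which are excluded from
  the error count), alignment-based QV = −10·log10(#discrepancies/#aligned
  bases), mononucleotide-run accuracy per run length, uncovered-base
  accounting, and BED-based include/exclude stratification of all metrics.
* **Read profiling** — aligned/clipped/unaligned base totals, the 12-cell
  substitution spectrum, indel rates, per-reported-Q calibration
  (observed vs reported quality, indels attributed to the 5′ base),
  homopolymer accuracy with a 5 bp flank rule, read-arrival dispersion
  (Poisson-scaled CDF with below/above-median KS distances) and coverage vs
  %GC in 100 bp windows.
* **Variant constructed genomes (VCGs)** — apply a phased (g)VCF to a
  reference per haplotype, mask loci below GQ thresholds (default
  10/20/30/40) plus uncalled/unphased regions, and score the constructed
  genomes against the benchmark.
* **Fixtures** — seeded, fully deterministic simulators for diploid genomes
  (SNV/indel/SV heterozygosity, tandem-run seeding, N gaps), corrupted test
  assemblies (planted substitutions, indels, phase switches, dropouts) and
  reads (error rates or per-base quality models, miscalibration, GC-bias
  dropout), all with exact truth tables and truth alignments — no external
  aligner or downloads needed.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` exercises the full acceptance suite (identity
evaluation, planted-error recovery, Viterbi-vs-enumeration oracle, threshold
semantics, read-metric recovery, dispersion detection, VCG round trips,
stratification additivity) on multi-megabase fixtures.

## CLI

```text
dibench index          --hap1 H1.fa --hap2 H2.fa [--lowconf L.bed] [--hap-align h1_vs_h2.paf] --k 31 --out IDX
dibench phase          --index IDX --assembly ASM.fa [--p-switch 1e-5 --p-error 0.02] --out DIR
dibench eval-assembly  --index IDX --aln ALN.paf --assembly ASM.fa [--include R.bed]... [--exclude R.bed]... --out DIR
dibench eval-reads     --index IDX --bam READS.bam [--bin 1000 --window 100] --out DIR
dibench build-vcg      --ref REF.fa --vcf CALLS.vcf [--gvcf CALLS.g.vcf] --gq 10,20,30,40 --out DIR
dibench simulate       genome|assembly|reads [--spec FILE] --seed N --out DIR
dibench report         DIR1/summary.json DIR2/summary.json ...
```

Assembly alignments are consumed, not produced: provide PAF with `cg` CIGAR
tags (e.g. `minimap2 -c --eqx`) or BAM; reads as BAM/SAM with `=`/`X` CIGARs
or MD tags. Machine-readable `summary.json` files are the primary output of
every run; TSV/BED files are derived views, and `dibench report` combines
summaries from multiple runs (refusing to mix different benchmark indexes).

Simulation spec files are plain `key = value` lines overriding the
dataclass defaults in `dibench.sim` (e.g. `chrom_len = 1000000`,
`sub_rate = 0.001`).

## Layout

```
src/dibench/
  sequtil.py   sequence encoding, canonical k-mers, FASTA/BED I/O
  index.py     DiploidBenchmark, het catalog, MarkerSet, RunCatalog
  phase.py     marker scan, two-state Viterbi, switch statistics
  alignio.py   PAF/SAM/BAM ingestion into AlignmentSegment
  assembly.py  NGAx, discrepancy catalog, QV, run accuracy, stratification
  reads.py     read profiling, calibration, dispersion, GC coverage
  vcg.py       (g)VCF parsing, variant application, GQ masking, scoring
  sim.py       fixture generators with truth bookkeeping
  cli.py       `dibench` entry point
```
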