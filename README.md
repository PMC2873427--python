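# allelesplice

Transcript structure variation (TSV) analysis from EST-to-genome spliced
alignments: detect structural differences between transcript isoforms,
classify them into the six canonical categories, call SNPs from EST
mismatches, and decide — from linked SNP patterns alone — whether each
structural difference is produced by **two gene alleles** or by
**alternative splicing** of a single allele.

The package is aimed at transcriptomics of outbred or pooled samples (the
motivating system is the malaria mosquito *Anopheles gambiae*, whose EST
libraries pool many individuals at roughly one SNP per 100 bp), where
genomic DNA from each individual is unavailable and allele-specific isoforms
must be recognized *in silico*.

## Method

1. **Ingest** (`alignment_io`). Spliced alignments (BED12 or GFF3) are kept
   when coverage > 80% and identity > 95% (strict); single-exon alignments
   are removed (possible genomic DNA or pre-mRNA contamination); each EST
   keeps only its best placement (max identity × coverage). Alignments are
   clustered by single-linkage exonic overlap per chromosome and strand;
   members with identical intron chains collapse into isoforms.
2. **Detect** (`tsv_detect`). Every localized difference between two isoform
   intron chains over their shared span becomes one event: intron retention
   (IntronR), alternative acceptor (AltA), alternative donor (AltD),
   alternative donor-and-acceptor (AltS), exon skipping (ExonS), or Others.
   Events found independently by two aligners can be intersected to remove
   alignment artifacts. An event is *in-frame* when the exonic length
   difference between the isoforms is divisible by 3.
3. **SNPs** (`snp_call`). Mismatches between each best-aligned EST and the
   reference are called per position; at the empirical EST error rate of
   0.0044 substitutions/bp one spurious SNP is expected per 227 bp of single
   EST, so only *mSNPs* — mismatches seen in more than one EST — are used
   downstream.
4. **Source** (`allelic_classify`). For an event with EST groups
   G1 and G2 (one per isoform), every cross-group pair is compared at the
   mSNP positions both ESTs cover. AS isoforms are spliced from the same
   pre-mRNA and share their allele's SNP pattern, so **any** fully matching
   informative pair ⇒ alternative splicing; informative pairs that all
   mismatch ⇒ allelic; no informative pair ⇒ undetermined.
5. **Impact** (`impact_annotate`). Each event's variable region is placed
   against gene models (CDS / 5′UTR / 3′UTR by maximal overlap) and frame
   consequences are tabulated.

A first-class synthetic-data generator (`synthetic_data`) builds loci with
two alleles, one structural variant per gene, linked SNPs, and error-bearing
ESTs, with complete truth tables — every stage is testable without external
data.

## Worked example

```sh
allelesplice simulate --n-genes 60 --seed 4 --out-dir sim
cat > run.yaml <<EOF
alignments: sim/alignments.bed12
genome: sim/genome.fa
est_fasta: sim/ests.fa
gene_models: sim/genes.gff3
out_dir: out
EOF
allelesplice run --config run.yaml
```

prints

```
60 genes, 527 ESTs, 694 planted SNPs -> sim
60 events
allelic fraction: 0.367
```

and `out/summary.txt` contains, among other tables,

```
   type  allelic  alternative_splicing  undetermined  fraction_allelic
IntronR       13                    21             0          0.382353
...
    all       22                    38             0          0.366667
```

All 60 planted events were recovered; 22 of the 60 were called allelic
(the generator plants each event as allelic with probability 0.28, so a
60-gene draw landing at 0.367 is within binomial sampling error). The
`snps` line of the filter ledger (`1563 -> 318`) shows the mSNP filter
discarding sequencing-error singletons while keeping multi-EST variants.
Individual stages are also available as subcommands
(`ingest`, `detect`, `intersect`, `snps`, `classify`, `impact`) and as
library functions.

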