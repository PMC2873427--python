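# Methods

## Model and assumptions

A transcript structure variation (TSV) event is a localized difference
between the intron chains of two isoforms at one locus. Its *source* is
either **allelic** (the two isoforms are transcribed from two gene alleles
whose genomic difference forces different structures) or **alternative
splicing** (both isoforms derive from the same pre-mRNA). The classifier
rests on three assumptions:

1. AS isoforms share a pre-mRNA, hence the same allele SNPs; allelic
   isoforms carry their respective alleles' SNPs.
2. SNPs within a gene are tightly linked to a structural variant in the same
   gene (negligible intragenic recombination at the relevant scale).
3. ESTs sample alleles without strong bias.

Under these assumptions the decision rule over EST SNP patterns is: compare
every cross-group EST pair at the mSNP positions covered by *both* ESTs
(reference-matching bases are part of a pattern — otherwise an EST of the
reference allele would carry no information); a single fully matching
informative pair proves a shared allele across the two isoform groups
(⇒ alternative splicing); informative pairs that all mismatch indicate
distinct alleles (⇒ allelic); no informative pair ⇒ undetermined.
Undetermined is a first-class verdict: it is reported, and excluded from
allelic-fraction denominators. Matching uses the full shared EST span, not
only the variable region, since informative SNPs typically flank the event.

## Event classification

Isoform chains are compared over the genomic span covered by both. Differing
introns are grouped into overlap-connected runs; each run is classified in a
fixed decision order — intron retention; exon skipping; shared donor
(alternative acceptor); shared acceptor (alternative donor); overlapping
introns differing at both ends (AltS); everything else Others. Donor and
acceptor are biological labels, so AltA/AltD swap genomic sides on the minus
strand; strand-unknown clusters use the plus-strand convention. Choices made
where the category pictures leave room:

* AltS requires the two introns to overlap genomically; corresponding but
  disjoint introns fall to Others.
* Intron retention requires the retaining isoform to cover the intron with
  at least one aligned exonic base beyond each end, so marginal overhangs
  are not called retention.
* Any difference touching either isoform's terminal aligned base is Others:
  a truncated EST cannot be distinguished from real variation there.
* Event identity for merging and for two-aligner intersection is
  (type, chromosome, strand, variable region, flanking junction
  coordinates); identical events from several isoform pairs merge with EST
  support unioned per side, the exon-richer ("inclusion") isoform being
  side a.
* `length_difference` is the absolute difference in exonic bases between
  the two isoforms over the variable region, restricted to the span both
  isoforms cover; `in_frame` ⇔ divisible by 3.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 0.80 | strict lower bound on EST fraction aligned |
| `min_identity` | 0.95 | strict lower bound on aligned-base identity |
| `min_ests` | 2 | mSNP support threshold (>1 EST) |
| `slack` | 0 bp | coordinate tolerance for two-aligner intersection |
| `end_mask` | 3 bp | mismatches ignored near alignment ends |
| `gap_mask` | 5 bp | mismatches ignored near splice junctions |
| `near_end_fraction` | 0.10 | CDS tail regarded as "near the stop codon" |

The masks are mismatch-calling hygiene for spliced-alignment artifacts;
setting both to 0 restores literal every-position calling. The near-end
threshold is descriptive only (the distance itself is always reported).

## Coordinates and formats

Internally 0-based half-open throughout. BED12 is native; GFF3 input/output
converts from 1-based inclusive. Coverage and identity travel in extended
BED12 columns 13/14 (fractions) or GFF3 `coverage=`/`identity=` attributes
(percentages). Alignments lacking metrics are rejected, passed, or
recomputed from sequence, per configuration. The alignment model is
block-concatenation: the strand-oriented EST aligns contiguously over the
exon blocks from query offset `q_start` (0 for BED12, which carries no query
coordinates). SNPs are reported on the genome's forward strand, one record
per (position, alternative base) — the pattern comparison works on base
identities, so multi-allelic sites stay separate records. Gene models are
read with gffutils; UTRs absent from the annotation are reconstructed as
exon − CDS, split by transcription direction.

## Impact annotation

The variable region is assigned to the transcript with maximal base overlap
(ties by gene id), then to the category — CDS, 5′UTR, 3′UTR — with maximal
overlap within that transcript (ties CDS > UTR5 > UTR3); no overlap ⇒
intergenic. Category territory is the *genomic span* of the category's
intervals: a retained intron between two CDS exons interrupts the coding
sequence and counts as CDS even though it overlaps no CDS exon base. For
CDS events the distance from the region's 3′-most base to the stop codon is
reported in spliced coordinates.

## Synthetic data generator

Each gene occupies its own chromosome: 4–8 exons of 90–300 bp, introns of
60–200 bp, 150 bp flanks. One structural variant per gene is drawn from the
default type mix 0.500 / 0.122 / 0.171 / 0.134 / 0.073 for
IntronR / AltA / AltD / AltS / ExonS — the five classifiable categories'
observed field frequencies renormalized without the residual class, which
cannot be planted as a defined two-isoform contrast. With probability 0.28
the variant is allelic. Donor/acceptor shifts are 4–30 bp; variants keep at
least 40 bp of flanking exon and 30 bp of intron.

SNPs: background density 0.01/bp on exonic sequence common to both isoforms
(intronic SNPs are invisible in ESTs and are never planted), plus one
guaranteed **tag SNP** 10–25 bp upstream of the variant — the tight-linkage
assumption made concrete, and placed clear of the default end/junction
masks. The tag ensures every sampled EST carries at least one linked marker,
which is what makes error-free verdicts deterministic; the truth table
flags tag SNPs so density checks can test background placement alone.

ESTs are 350–700 bp windows of the mature transcript, always spanning the
variant with ≥30 exonic bases each side and at least one splice junction
(a junction-free window would be indistinguishable from genomic DNA and
discarded by the uniexonic filter). Errors are uniform substitutions at
0.0044/bp — no indels, matching the arithmetic that equates one expected
false SNP with a 227 bp EST. For allelic genes, isoform i is expressed from
allele i. For AS genes the locus is equally polymorphic but both alleles
express both isoforms, and EST→allele assignment alternates within each
isoform group: purely random assignment would leave a few percent of AS
genes with allele-pure groups, which no SNP-based method could score
correctly; balanced assignment models pooled libraries in which both alleles
of an expressed locus are sampled.

What passing tests on this generator do **not** show about real data:
robustness to alignment error (truth alignments are exact), to indels or
clustered errors, to allele-biased expression, to loci with more than two
isoforms or more than one event, or to paralogous mis-mapping.

## Numerical and degenerate-input choices

* Best-placement ties break by (chromosome, start, input order);
  cluster members sort by (start, end, EST id); all outputs are
  deterministic, and the simulator is byte-identical for a fixed seed.
* A cluster with one isoform yields no events; an empty event list yields
  empty summary tables; an all-undetermined type reports a missing (NaN)
  allelic fraction rather than zero.
* Tied exonic content in an event (possible for AltS) assigns sides by
  sorted EST ids.
* Terminal-touching differences can be observed over different overlaps in
  different isoform pairs; the merged event keeps the largest measured
  length difference.

## Known limitations

* No indel or quality-aware SNP calling; ESTs are treated as plain reads.
* PSL input is not supported; alignments come as BED12 or GFF3.
* The residual "Others" class is not sub-classified and is excluded from
  source classification.
* Verdicts are pattern comparisons, not phasing: allele frequencies and
  recombination are out of scope.
* Problem sizes in the test suite and acceptance script (200-gene and
  500-gene studies, 200 random oracle clusters, 1500 simulated length
  differences) are the package's chosen study sizes; they give binomial
  confidence intervals of a few percentage points on recovered fractions.
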