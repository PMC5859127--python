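# Methods

## The comparison being modelled

Bulk RNA-seq libraries are prepared either by polyA+ selection, which
captures polyadenylated, mostly mature transcripts, or by rRNA depletion,
which keeps everything that is not ribosomal — including polyA−
transcripts and substantial amounts of incompletely spliced pre-mRNA.
`libprep` implements the quantitative comparison between the two: how
reads distribute over exons/introns/intergenic space, which genes each
protocol detects, how much sequencing depth each needs for the same exonic
coverage, how concordant the two quantifications are, and where rRNA
depletion systematically *overestimates* genes whose exons sit inside
other genes' introns.

## Gene models and coordinates

Internal coordinates are 0-based half-open; GTF is read and written as
1-based closed. Quantification is union-exon based: all transcript exons
of a gene are merged into a disjoint sorted set; the complementary
intervals inside the span are the introns; exons and introns exactly tile
the span (a tested invariant). Genes whose union is a single exon simply
have no introns — they are legal models and are excluded from the
intron-rate statistic by its filters, not by the parser.

Biotype collapse to the five categories is a shipped TSV table
(`libprep/data/biotype_map.tsv`, overridable) plus two rule families that
Gencode spells combinatorially: any `gene_type` containing `pseudogene` is
a pseudogene and `TR_*`/`IG_*` prefixes are TCR/BCR. Unknown strings go to
an explicit `other` bucket, logged and excluded from five-way summaries.

Two distinct overlap notions are kept deliberately separate, because the
analysis uses them for different purposes:

* the **intron-rate filter** flag (`overlaps_other_gene`) is span-vs-span
  and strand-blind by default (the conservative reading; exon-vs-exon and
  strand-aware variants are configuration switches);
* the **counting exclusion** uses multi-gene *exonic* regions — positions
  covered by union exons of ≥ 2 genes — since only there is an exonic read
  genuinely unattributable.

## Counting rules

Only uniquely mapped fragments are counted; a read pair counts once. Two
rules coexist:

* **Classification** (QC): exonic if any block touches any union exon by
  ≥ 1 bp; else intronic on any intron touch; else intergenic. The exonic
  percentage of a library is the exonic classification total over the
  total sequenced reads.
* **Assignment** (quantification): a fragment is counted for gene G iff
  its blocks overlap G's union exons by ≥ 25 bp in total, touch no
  multi-gene exonic base, and no second gene also reaches 25 bp (else it
  is ambiguous and counted for nobody). Fragments that fail exonic
  assignment but touch introns are tallied *intronic* for the gene with
  the largest intronic overlap (ties broken lexicographically by gene id —
  an arbitrary but deterministic rule); these intronic tallies exist only
  to feed the intron-rate statistic.

Assignment is strictly a subset of classification (minimum overlap,
ambiguity, exclusion), which is why "usable" fractions sit below exonic
percentages. Both are reported and the gap is visible in the count-table
summary. Counting is order-independent and is verified exactly against a
nested-loop oracle in the test suite.

Strandedness: both rules are strand-blind by default with a `stranded`
switch, since protocol comparisons of this kind are dominated by
coordinate overlap, and the convention used for counting is rarely stated;
the choice is recorded in run manifests.

## Expression units and thresholds

RPKM = count / (union-exon kb) / (library-size millions); CPM analogous.
The default library size is the per-sample *counted* reads (sum of
assigned exonic counts) — "per million mapped reads" is ambiguous when
only assigned reads enter the matrix, so the convention is explicit,
switchable, and recorded in the `ExpressionMatrix` provenance field.
Thresholds used throughout, all strict inequalities as conventionally
printed: expressed at RPKM > 0.1 (on merged replicates); correlation
filter drops genes with RPKM < 0.5 in *every* sample; intron-rate filter
requires ≥ 1 RPKM in all samples; DE requires mean RPKM > 0.5. Replicate
merging adds counts and library sizes, which makes merged RPKM identical
to re-counting pooled fragments (tested).

Correlations (sample-sample and per-biotype protocol concordance) are
Pearson on log2(CPM+1), with Spearman available by flag; concordance also
flags genes with |log2((CPM_riboZ+1)/(CPM_polyA+1))| > 4. Structure-bin
summaries of the intron rate use half-decade log10 bins of total intron
length and intron-count bins {1, 2–5, 6–10, 11–20, >20}; the extra-depth
figure is reported rounded to the nearest 10% with the raw value
alongside.

## Differential expression

The comparison's substance is the DE *definition* (FC > 2, BH adjusted
p < 0.05, mean RPKM > 0.5) and the per-biotype direction summaries. The
default per-gene test is an exact conditional binomial: conditional on a
gene's pooled count k = kA + kB, kA ~ Binomial(k, NA/(NA+NB)) under equal
concentration; two-sided p by tail doubling, p = 1 for zero-count genes.
This is the correct exact test under Poisson/multinomial sampling and is
deliberately simple — it models no biological dispersion and is labelled a
pluggable stand-in: per-gene p-values computed elsewhere (e.g. a
negative-binomial GLM) can be passed through unchanged. BH adjustment
delegates to statsmodels and is verified against a literal step-up
reference. log2FC uses mean CPM per group with pseudo-count 0.5 (the
convention is stated because no standard exists); "up" means higher under
rRNA depletion. The direction-split table normalises within biotype
(up/(up+down) per category); normalising across all DE genes is available
by flag.

## The synthetic generator

The generator emulates read *provenance*, not sequence: fragments are
75 bp coordinate intervals (spliced mature fragments may span junctions as
multiple blocks), with no quality strings, error model, GC or coverage
bias, and no degradation model. Each fragment is drawn as: intergenic with
probability `intergenic_fraction`; otherwise a gene is drawn and the
fragment is nascent with probability `nascent_fraction` (uniform start
over the unspliced span — pre-mRNA) or mature (uniform over the spliced
transcript; genes shorter than 75 bp yield truncated fragments covering
the gene, which is exactly why nested 60–66 bp genes can also *receive*
host reads). `nascent_fraction` is defined conditional on a fragment being
genic; preset mixtures are polyA-like (0.06 nascent) and
rRNA-depletion-like (0.50 blood-like, 0.34 colon-like), with intergenic
fractions 0.20–0.28. Under the polyA protocol gene draws are additionally
weighted by a per-gene capture probability (histone-like gene and small
RNAs 0, dominant lncRNA 0.05, coding genes 1).

`abundance_profile` entries are expected shares of **counted** reads.
Since nascent fragments mostly never get counted, draw weights are
rescaled by each gene's counting probability `(1−f) + f·κ_g`, where `κ_g`
is the exactly computed probability (vectorised start-position scan over
the gene's own geometry) that a nascent fragment is exonic-assigned to the
gene. Configured shares are then recovered in expectation by the pipeline;
cross-gene assignment (nested genes capturing host reads) is deliberately
outside `κ` — it is the artifact under study, not part of the target
share. The default scenario pins the dominant lncRNA at 2.7% of counted
reads and gives the blood preset a high-abundance compact globin-like
gene.

Default gene geometry was chosen from the closed-form expectation of the
per-gene intron rate rather than by trial: with genic nascent share f, a
gene's expected rate is `f·pI / (f·pI + f·pE + (1−f))`, where pI (pE) is
the probability that a nascent fragment is intronic-tallied
(exonic-assigned). Coding genes with ~120–200 bp exons and 8–16 kb introns
give pI ≈ 0.98, pE ≈ 0.016, hence rate ≈ 0.49 at f = 0.5 and ≈ 0.06 at
f = 0.06 — matching the regime rRNA-depleted blood libraries actually show
(medians near 0.5) and making intron rate grow geometrically with intron
length, as observed. Truth labels distinguish mature, nascent-intronic
(fragment clear of its own gene's exons), nascent-exonic and intergenic;
`truth_summaries` turns them into recovery targets. The residual gap
between truth-intronic and pipeline-intronic is fragments of a host gene
overlapping a *nested* gene's exon (classified exonic) — of order 10⁻⁴ at
default layouts, which is why recovery tests can use a ±0.01 band
dominated by sampling noise.

What passing tests on this generator do **not** show: behaviour under
alignment error, positional/GC bias, transcript-level ambiguity within a
gene, real abundance distributions over ~58 000 genes, or degraded (FFPE)
RNA. The generator's scenario knobs are modelling conventions, not
estimates fitted to any dataset.

## Scale of the shipped analyses

The packaged simulations run at 2×10⁵ fragments over a ~1 Mb toy
chromosome with ~28 genes (recovery analyses), 5×10⁴ for the nested-gene
artifact scenario, and 20–50 replicate null simulations at 1.5×10³
fragments per sample for the multiple-testing calibration — sizes chosen
so binomial sampling error sits well inside the tolerances being checked
while the whole suite runs in about a minute. The published QC table is
16 replicates at 50 M reads each and enters as printed input, not as
simulation output.

## Degenerate inputs and numerical conventions

Zero library sizes, empty replicate groups, non-positive thresholds,
mixed-chromosome genes and malformed GTF attribute blocks fail fast with
named errors; empty fragment sets yield all-zero columns with a warning;
genes with zero intronic+exonic counts are excluded from intron rates
(NaN, logged); categories with no genes report missing (NaN) correlations
and direction fractions rather than zeros. Subsampling canonicalises
fragment order by read id before drawing, so results are independent of
input order. All randomness flows from explicit integer seeds; rerunning
any stage with the same configuration is byte-identical.

## Known limitations

* The binomial DE test ignores biological dispersion; with genuinely
  variable replicates it is anticonservative, which is acceptable only
  because protocol comparison on technical replicates is the use case.
* The counting engine holds fragments in memory as Python objects; it is
  sized for simulation-scale inputs (10⁵–10⁶ fragments), not for 50 M-read
  BAMs.
* BED12/SAM ingestion assumes deduplicated input and takes read 1 of a
  pair as the fragment; mate-aware fragment reconstruction is upstream's
  job.
* GFF3, transcript-level (isoform) models and chromosome-alias resolution
  are out of scope.
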