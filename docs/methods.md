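# Methods

## Scope and data model

The package annotates full-length transcriptome data structurally.  Its
universal currency is the `TranscriptModel`: a strand-aware, ordered,
non-overlapping exon chain on a chromosome, in 0-based half-open coordinates.
The 1-based closed convention of GFF3/GTF exists only at the file boundary;
using a single internal convention removes the usual off-by-one drift.
Adjacent exons (gap < 1 bp) are merged on ingest with a warning — zero-length
introns are format noise, not biology.  Strandless single-exon features are
accepted as "+" with an `strand_uncertain` flag rather than rejected, because
GFF in the wild contains them.  Raw base-calling, alignment and functional
annotation are out of scope: reads arrive as mapped exon chains (BED12 or
GFF3), and counts arrive as matrices.

## Locus collapse

Two reads belong to one gene when they are on the same chromosome and strand,
their spans overlap by more than `min_span_overlap_fraction` (default 0.20)
and at least one exon pair overlaps by more than
`min_exon_overlap_fraction` (default 0.20).  Design choices that were
genuinely open:

* **Overlap denominator.** "More than 20% overlap" does not say 20% of what.
  The implementation uses the *shorter* feature's length: it is symmetric and
  the strictest choice for nested fragments.  Both fractions are
  configurable, and both thresholds are strict (`>`).
* **From pairs to loci.** The pairwise relation is turned into loci by
  transitive closure (union-find / connected components) — the only
  order-independent completion.
* **Mono-exon redundancy.** Single-exon reads merge when mutually contained
  within a 20 bp end tolerance (configurable); merging is iterated to a
  fixpoint so that collapsing a collapsed set is a no-op.
* **Reliability filter.** A `min_support` threshold (default 1, i.e. off)
  drops weakly supported isoforms; the default preserves read counts so the
  partition invariant (every read in exactly one isoform) holds.

Multi-exon isoform identity is exact intron-chain equality; merged isoform
ends are the extreme observed read ends, so 5'/3' end variation never
fragments the isoform set.

## Novelty classification

A locus is a novel gene when its best span overlap with any reference gene is
at or below the threshold, or when the best-overlapping gene lies on the
opposite strand.  Among equally overlapping candidates (the shorter-feature
fraction saturates for nested genes) the more reciprocal match wins, then the
smaller start coordinate.

A transcript of a known gene is novel when it uses a splicing site absent
from the reference gene, or when exactly one of (isoform, reference gene) is
single-exon.  "New splicing site" is evaluated at the whole-junction level by
default (`site_level="junction"`): an exon-skipping isoform joins two
annotated boundaries into an unannotated intron and must count as novel,
which the junction reading captures and the boundary reading does not.  The
stricter boundary-level reading remains available as
`site_level="boundary"`.  The grammatically ambiguous single-exon clause is
resolved as: single/multi-exon mismatch ⇒ novel; both single-exon with
reciprocal overlap above the threshold ⇒ known — the only reading under which
any mono-exon transcript can ever be known.

## Alternative-splicing events

Events are extracted per isoform pair within the genomic region both span.
Anchors are the splice sites present in both isoforms plus the common-span
endpoints; a variant is a region between consecutive anchors where the two
exon/intron structures disagree.  The local structure pair determines the
type (ES, IR, AD, AA, MEE — donor means 5' splice site, so AD/AA flip with
strand); anything else, e.g. a double skip, is reported as `complex` and
excluded from the five-type table.  Disagreements flush against an unshared
span endpoint are terminal (TSS/polyA) variation, not splicing, and produce
no event.  Per-gene sets are the union over all pairs deduplicated by the key
(gene, type, variant region, anchors); per-sample counts re-run the analysis
on the sample-restricted isoform sets, so the pooled count is at least each
per-sample count but need not equal their sum — an event whose witnesses were
seen in different samples exists only in the pooled analysis.  The counting
unit (pairwise variants deduplicated by region) follows the variant semantics
of the standard AS-classification tools; no percent-spliced-in quantification
is attempted because the input is a transcript catalogue, not read counts per
junction.

## Polyadenylation sites

Read 3' ends (strand-aware terminal coordinates) are clustered per gene by
single linkage with `merge_window` = 24 bp and `min_site_support` = 2 —
declared defaults, not a claim about any external tool's internals.  The
representative position is the support-weighted mode (cleavage is discrete;
the mode is robust to stragglers), ties resolved toward the most distal
position in transcription direction.  Composition profiles cover ±50 bp on
the transcribed strand; the element scan is a fixed-consensus search for a
run of ≥ 10 A, matching the element such studies report, rather than de novo
motif discovery.  No internal-priming filter is applied.

## lncRNA calling and classification

The coding-potential score is a deliberate, clearly-labelled stand-in for the
CPC2/CNCI/CPAT/PLEK ensembles: longest ORF over the three forward frames
(ATG to stop, or to the open 3' end) plus a hexamer log-likelihood ratio with
a 6-mer model trained on the run's reference coding sequences (pseudocount 1)
against a uniform background.  A transcript is noncoding iff ORF < 100
codons AND score < 0 AND length ≥ 200 nt — the community-standard thresholds,
since no tool-specific values are authoritative here.  External per-transcript
calls can be supplied to reproduce an exact published toolchain.

Positional classes are assigned with precedence intronic → sense → antisense
→ intergenic.  Intronic (span entirely within a single intron of a reference
transcript, either strand) outranks the exonic-overlap classes so that
intron-contained transcripts form a class disjoint from sense — the reading
under which intronic can be a dominant class at all.  A transcript that
overlaps a gene body without touching an exon and without sitting in a single
intron is attributed to the gene as intronic; transcripts with no gene-span
overlap are intergenic.  Calls are invariant to reference gene order
(candidates ranked by precedence, exonic overlap, gene id).

## Differential expression

The stage is a self-contained negative-binomial Wald pipeline, a declared
stand-in for DESeq2 so the package has no heavy runtime dependency:
median-of-ratios size factors (total-count fallback with a warning when no
feature is positive everywhere); per-feature method-of-moments dispersions
pooled within groups, clipped to [1e-8, 10], shrunk on the log scale toward a
fitted a1/mu + a0 trend; log2FC from group means of normalised counts with a
0.5 pseudocount for display stability; Wald variance of a log NB mean by the
delta method, Var(log mu) ≈ (1/mu + alpha)/n; two-sided normal p-values;
BH-FDR across tested features, separately at transcript and gene level
(all-zero features excluded from testing and from the BH denominator).  The
DE call is |log2FC| > 1 and FDR < 0.05.  Gene counts are sums of member
transcripts.  An adapter ingests externally computed (id, log2FC, padj)
tables for users who need the exact external toolchain.  The cross-check
against pydeseq2 in the test suite compares fold-change estimates and strong
calls between the two independent implementations; it is a test oracle, not a
dependency of the method.

## The synthetic-data generator

The generator emulates the statistical structure each stage consumes, with
every draw a function of `SimConfig.seed`:

* One linear chromosome; genes separated by 2 kb spacers (multi-chromosome
  layouts add nothing to the algorithms).  Exons are 201 bp (a multiple of 3,
  so planted splicing events preserve reading frame), introns 399 bp;
  single-exon mRNAs are 603 bp, the realistic length class for mono-exonic
  coding genes.
* Isoform counts per gene follow a categorical distribution (default 60%
  single-isoform, tailing off to 5 isoforms).  Each additional isoform
  differs from the base isoform by exactly one planted event drawn from the
  AS mix (default IR 30%, ES 25%, AA 20%, AD 20%, MEE 5% — intron retention
  dominant, as in insect full-length data); events occupy disjoint internal
  exon slots so pairs of variants never interact, and the truth file records
  each event with the exact (type, region, anchors) key the classifier emits.
* Coding sequence is drawn from a fixed non-uniform codon-usage model (ATG
  start, no in-frame stops), written into exons in transcription direction.
  Retained introns and MEE partner exons also receive coding-like sequence so
  variant isoforms remain unambiguously coding.
* 1–8 polyadenylation sites per gene, spaced 60 bp (> 2x the 24 bp merge
  window, so clustering is identifiable), marching downstream from the
  annotated 3' end; the 10 bp downstream of each site is A-rich on the
  transcribed strand with per-base probability 0.9.
* Noncoding transcripts (300 nt, uniform-random sequence) are planted to
  satisfy each positional class strictly: inside the first intron of a host
  gene (intronic), overlapping a host's first exon by 60 bp on the same
  (sense) or opposite (antisense) strand, or mid-spacer (intergenic).  The
  default counts (10/6/4/6) make intronic the dominant planted class.  The
  60 bp exonic overlap keeps the coding-hexamer contamination of sense and
  antisense lncRNAs small.
* Reads are copies of true isoforms with Normal(0, 5 bp) end jitter truncated
  at splice boundaries (so degraded ends can never fake a splicing event —
  this isolates collapse testing from AS testing), 3' ends at a uniformly
  drawn planted site, and per-sample presence with probability 0.6 across
  three samples.  Intergenic mono-exon noise reads (150–350 nt, straddling
  the 200 nt lncRNA length threshold) make up ~5% of the output; they
  exercise novel-gene calling without confounding known loci.
* Counts are NB(mu, dispersion 0.1) over 5 + 5 replicates; 20% of transcripts
  receive a planted log2 fold change from ±{1.5, 2, 3}.  A separate
  isoform-switch generator plants genes whose two isoforms swap usage (80/20
  to 20/80) at constant gene totals, the scenario in which transcript-level
  testing must succeed and gene-level testing must stay silent.

What the generator does **not** emulate: base-level sequencing error,
chimeric reads, internal priming, multi-mapped read assignment across
isoforms, and biological coupling between splicing and expression.  Passing
the recovery tests therefore demonstrates algorithmic correctness under the
stated generative assumptions, not robustness to alignment artefacts of real
data.  With jitter and noise enabled, the lncRNA class table is dominated by
intergenic calls simply because noise reads are intergenic by construction;
the planted class mix is recovered exactly in the noise-free configuration.

The reference used for novelty testing is produced by withholding a random
subset of genes and isoforms from the truth annotation.  Only isoforms that
remain junction-novel against the retained set are withheld: an
intron-retention variant's junctions are a subset of its base isoform's, so
its omission is undetectable under the junction rule and withholding it would
make exact recovery ill-posed.  The novelty recovery oracle additionally runs
on a coding-only simulation, because a sense-overlapping noncoding transcript
merges into its host locus and is then (correctly) judged against the host
gene rather than its own reference entry.

## Numerical and reporting conventions

Percentages are reported to 2 decimals with round-half-up, and every
percentage in a pipeline summary is recomputed from its printed numerator and
denominator by an automatic self-audit (`audit_summary`) before the summary
is returned.  Means are reported to 2 decimals.  The hypergeometric
enrichment universe defaults to all genes with at least one collapsed
isoform.  Problem sizes in the test-suite oracles (200-read locus instances
across 100 seeds, loci with ≤ 6 isoforms for exhaustive pair enumeration,
≤ 100 ends for the clustering oracle, universes ≤ 25 for exact enumeration,
2,000 features for DE calibration, 100-gene end-to-end simulations) were
chosen so each oracle is exhaustive or statistically decisive at desk scale.

## Known limitations

* The same-gene rule's overlap denominator and the novelty rule's splicing-site
  granularity are interpretations of under-specified published criteria; both
  are configurable and documented rather than silently fixed.
* The coding-potential heuristic is not equivalent to the published ensemble
  tools; with the external-call adapter it is bypassed entirely.
* Complex AS variants are counted but not sub-typed.
* The NB Wald test uses a normal approximation with moment-based dispersions;
  with very few replicates it is slightly liberal relative to shrinkage
  estimators, which the null-calibration test bounds (KS < 0.1, empirical
  call rate ≤ nominal + Monte-Carlo error).
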