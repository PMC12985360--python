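# Methods

`exonsci` implements the downstream computational analysis for
combinatorial-indexing single-nucleus RNA-seq with full gene-body coverage:
from aligned, barcoded reads to gene- and exon-level count matrices, exon-level
differential expression with DEG-derived classification, exon-to-protein-domain
mapping, splicing-factor target enrichment, neighborhood-level differential
abundance, and HCR split-probe design. Because the analyses target data that
cannot be regenerated at desk scale, every stage is validated against a
synthetic-study generator whose ground truth is machine-readable.

## Read model and molecule identity

A read carries an RT barcode (10 nt; encodes the well of reverse transcription
and therefore the sample), a ligation barcode (10 nt), a UMI (8 nt), a primer
label (oligo-dT or random hexamer), and the tagmentation site of its fragment.
Cell identity is the (RT, ligation) combination; molecule identity is
(RT, ligation, UMI, tagmentation site). Both whitelists ship with the package
and were generated once with a pairwise Hamming distance of at least 3, so any
single substitution corrects to a unique entry.

Barcode correction accepts an exact match or the unique whitelist entry at
distance 1 and discards everything else (distance >= 2, or a distance-1 tie).
"Edit distance" is implemented as Hamming distance on these fixed-length
barcodes — for equal-length strings and a threshold below 2 the Levenshtein
and Hamming decisions coincide — with a Levenshtein mode available behind
`DemuxConfig.metric`. Deduplication keeps the first read per molecule key
after position sorting, so it is deterministic and order-independent; the
ligation barcode is part of the key by default (`include_lig=False` switches
to an RT-only key for protocols that treat the RT barcode alone as the cell
component).

## Gene and exon assignment

Exons are gene-level features: the union of a gene's transcript exons, merged
into disjoint intervals and numbered `gene:1`, `gene:2`, ... in transcription
order. Internal coordinates are 0-based half-open; GTF I/O converts to 1-based
inclusive at the file boundary only.

Assignment applies, in order: (1) direct same-strand overlap with exactly one
gene; (2) for oligo-dT molecules overlapping several genes, the gene whose
annotated 3' end is nearest the molecule's 3'-most aligned base (distance in
bp, ties broken lexicographically by gene id); ambiguous hexamer molecules are
discarded by default because 3' proximity is only meaningful for 3'-anchored
priming (`ambiguous_nondt_closest` applies the same rule to hexamers);
(3) rescue by the unique gene starting at most 1,000 bp downstream of the
molecule on the same strand (gap 0 = adjacent; a window of 0 disables the
rescue); then (4) rescue by the unique antisense overlap. Upstream rescue
precedes antisense rescue — a sense-strand interpretation is preferred when
both exist. Within the assigned gene, the exon with the greatest overlap wins;
residual ties go to the 3'-nearest exon for dT molecules and the lowest exon
index otherwise. A gene-assigned molecule overlapping no exon is intronic:
gene counts include it, exon counts do not.

The per-molecule API answers from an interval tree; the bulk path used on
multi-million-molecule tables performs the same candidate search with
vectorized interval joins. Both share the selection rules and are
cross-checked for equality in the test suite.

## Cell QC and doublet scoring

Cells are kept iff total UMIs >= `min_umis` (brain preset 500; cell-line
preset 1000) and detected genes >= 100, both boundaries inclusive. Doublet
scoring follows the simulated-doublet nearest-neighbor approach: synthetic
doublets are sums of random observed cell pairs at `sim_doublet_ratio` = 2x;
genes are filtered (`min_count` 3, `min_cells` 3) and ranked by an
above-Poisson variability score with the 85th-percentile cut; log-normalized
expression is reduced to 30 principal components fitted on observed cells;
a kNN graph (30 neighbors, widened by the simulation ratio) yields each
cell's smoothed simulated-neighbor fraction q, calibrated as

    score = q * rho / r / (1 - rho - q * (1 - rho - rho / r))

with rho = 0.06 the expected doublet rate and r the simulation ratio; calls
use score > 0.2. Equivalence with the original tool is asserted at the
ranking level (doublets score above singlets; AUROC on generator truth), not
per-score, since exact score values depend on internals the method's
description does not pin down.

## Differential expression

Counts per feature are modeled NB with a log link and per-cell totals as
offsets (size factors consistent with CPM). The per-feature overdispersion is
a method-of-moments estimate around the per-condition means with a
small-sample degrees-of-freedom correction, floored at 1e-4 and shared by the
full (intercept + condition) and reduced (intercept) fits; the LRT p comes
from chi-square with 1 df, with a Poisson fallback (flagged) when the NB fit
fails. Fold change is deliberately mean-based, not model-based:
`log2((CPM_alt + 1) / (CPM_ref + 1))` on condition-mean CPM, two-sided
(up or down beyond 1.5-fold). Genes and exons are tested together and a
single Benjamini-Hochberg correction spans the concatenated feature list; the
combined correction is what lends the weakly expressed exon features power.

Calling: DEG = FDR < 0.05, |FC| > 1.5, max-condition mean CPM > 25;
DEE = same but CPM > 10. A DEE is *DEG-derived* when its parent gene passes
the FDR/FC cutoffs at the exon-level CPM threshold (> 10) — the parent may
fail the gene-level CPM > 25 filter and not itself be a DEG; otherwise the
DEE is non-DEG-derived. Shared-feature concordance between two subtypes is
the Pearson correlation of log2 fold changes over features flagged in both.

## Exon-to-domain mapping

Each DEE is projected through every in-frame transcript of its parent gene:
the genomic interval is intersected with the CDS segments, mapped to
CDS-relative nucleotide offsets respecting strand, and converted to amino
acids with `(floor(start/3), ceil(end/3))` so partial codons count —
conservative for domain overlap. Transcripts whose total CDS length is not a
multiple of 3 are excluded from mapping. Domain tables are per-transcript
amino-acid intervals (1-based inclusive on disk); a hit requires >= 1 aa of
overlap, reported per (exon, transcript, domain) with a per-exon union
summary.

## Splicing-factor target enrichment

DEGs are intersected with a known splicing-factor set (direction retained).
For each factor, genes tested for DE (the universe; configurable) are
cross-classified DEE-parent x target, and enrichment is a one-sided (greater)
Fisher exact test — enrichment, not depletion, is the hypothesis. Targets
outside the universe are dropped with a log message.

## Neighborhood differential abundance

Neighborhoods are index cells (sampled at a configurable fraction) plus their
k = 60 Euclidean nearest neighbors on a provided embedding; a PCA utility
exists but any 2-D embedding is accepted. Per-neighborhood cell counts per
sample are tested with the same NB LRT (sample totals as offsets) and
BH-corrected across neighborhoods — plain BH replaces graph-weighted spatial
FDR deliberately; with the modest neighborhood counts here the weighting adds
machinery without changing calls materially. For labeling, each neighborhood
expands to all cells within a fixed radius of its index cell's 2-D
coordinates (default radius = median index-to-k-th-neighbor distance, since
no canonical value exists); it is labeled Young-/Aged-enriched iff one
condition strictly exceeds 70.5% of the expanded membership, on raw cell
counts (a group-size-normalized mode is available).

## Probe design

Split-probe candidates tile the transcript from position 100 (when length
permits) as 52-nt windows: two 25-nt half-sites around a 2-nt gap, following
the v3.0 split-initiator convention (both configurable). Filters are
conjunctive and flagged independently: homopolymer-class runs (poly A/T <= 5,
poly C/G <= 4 within the window), per-half GC in [45, 60]%, and <= 6
percentage points GC difference between halves. Selection maximizes the
minimum inter-pair spacing via binary search with a leftmost-greedy
feasibility check — deterministic and position-sorted; off-target screening
is out of scope, with a FASTA export hook for external screens.

## The synthetic study generator

The generator emulates the study design the pipeline assumes: two conditions
(young, aged) x 3 replicates x 500 cells, seven oligodendrocyte-lineage-like
subtypes whose mixing proportions shift with age (intermediate subtypes
depleted; a reactive-like subtype expanding from 2% to 20%), ~6% doublets
(sums of two independently drawn cells), single-substitution barcode errors
at 2% of reads, PCR duplication at a mean of 1.3 copies per molecule, and a
50/50 dT/hexamer primer mix. Genes (150 by default) carry 2-6 exons; one
transcript per gene; a contiguous in-frame CDS covering ~60% of the
transcript; 0-3 protein-domain intervals per transcript.

Expression is gamma-Poisson at the gene level: each cell x gene draws one
gamma multiplier (dispersion 0.2) shared across the gene's exon and intron
segments, and segment counts are Poisson given that multiplier. Marginally
each segment is NB with the configured dispersion, while the exon/intron
split of a gene's molecules is exactly multinomial — this mirrors
transcriptional bursting and makes intronic-fraction recovery exactly
binomial, which the recovery tests exploit. Per-cell depth is lognormal
(mean 1,200 molecules, sigma 0.35), chosen so the brain QC preset
(>= 500 UMIs, >= 100 genes over 150 genes) is the operative filter rather
than a formality.

Condition effects: 25% of genes draw a log2 fold change of magnitude
0.5-2 (splicing-factor genes are forced to >= 1 upregulation); 15% of exons
draw exon-level effects. Every exon effect is a usage (isoform) shift: the
affected exon's share moves while its sibling exons rescale so the gene's
exonic total — and hence its realized gene-level fold change — equals the
drawn gene effect exactly. Exon dynamics are therefore fully decoupled from
gene dynamics, and a gene is truly DE iff a gene-level effect was drawn.
Opposed exons pick their usage shift so the exon's total change flips the
sign of a DE parent gene's change (one low-weight exon per gene, shifts
capped so siblings can absorb them). 10% of genes are intron-dynamic, with
intronic read fractions of 0.95 (young) dropping to 0.77 (aged) against a
0.25 baseline, emulating an age-related unspliced-fraction shift; these
genes are excluded from the opposed-exon pool so the two mechanisms stay
separable. CLIP-style target lists are drawn per splicing factor with odds
4 toward genes carrying exon effects over a 25% base rate. Ground truth
records per-cell labels, doublet flags, target membership, and per-feature
fold changes on two scales: the absolute intensity ratio
(`realized_log2fc`) and the CPM-scale change (`cpm_log2fc`) — asymmetric DE
shifts total output between conditions, and an estimator normalized by cell
totals can only observe changes net of that library-composition shift, so
recovery is assessed on the CPM scale.

The generator does **not** emulate: base-level sequence error, ambient RNA,
batch effects beyond replicate labels, overlapping genes (so gene assignment
ambiguity and rescue are exercised by constructed fixtures, not the
simulation), isoform diversity within genes, or realistic transcript
sequence composition. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated model, not robustness to artifacts
absent from that model.

## Validation design and problem sizes

Unit tests pin exact rule fixtures (assignment branches, the 1,000/1,001 bp
rescue boundary, the CPM re-filter subtlety, the strict 70.5% labeling
boundary) and oracle equivalences (barcode correction vs all-pairs Hamming,
interval queries vs linear scan, coordinate mapping vs per-base enumeration,
BH vs sort-and-scan, Fisher vs hypergeometric tail sums). Statistical checks
run at sizes chosen to keep the default suite within minutes: NB-LRT type-I
error on 2,000 null features at 150 cells (99% binomial band around 0.05),
label-permutation DE, and null neighborhood calibration (~5% at p < 0.05;
neighborhoods overlap, so a generous band is used rather than a binomial
interval). Parameter recovery runs on the full default study (~3,000
singlets): mean log2FC error within +/-0.15 over high-expression genes
(true max-condition CPM >= 100), measured against the CPM-scale truth as
described above, DEG recall >= 0.8 at |drawn log2FC| >= 1, empirical FDR
<= 0.1 against drawn-effect truth, per-gene
intronic fractions inside 99% binomial intervals, doublet AUROC > 0.8, and
>= 90% of neighborhoods indexed in the planted aged-expanded subtype labeled
Aged-enriched.

`scripts/acceptance.py` recomputes all of these from scratch at a given seed
and writes them as JSON; see the README for how to run it.

## Numerical choices and degenerate inputs

All-zero features report p = 1 and log2FC = 0. Zero-total cells are excluded
from CPM with a warning. Identical groups in the intronic-fraction t test
report p = 1 (zero variance, zero difference). Exon-only DE input is tested
and flagged but left unclassified (no parent rows). Dispersion estimates are
clamped to [1e-4, 100]. Ties are always broken deterministically
(lexicographic ids, lowest exon index, position-sorted representatives), so
byte-identical outputs follow from identical seeds; the pipeline manifest
records output checksums to make this checkable.
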