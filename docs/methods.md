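# Methods

## Problem setting

tRNA-seq quantifies unique-sequence tRNA transcripts (isodecoders); a
paired input/IP RNA-seq experiment quantifies how strongly each mRNA is
translated. The analyses in this package connect the two: how variable is
tRNA expression at the isodecoder, anticodon (isoacceptor), and amino-acid
(isotype) level across tissues; whether anticodon-level structure is more
than an artifact of grouping; and whether the codon demand of highly
translated genes is matched by the tRNA supply of the same tissue.

## Inventory and grouping

Reference tRNA gene sets contain many copies transcribing identical mature
sequences; these are indistinguishable to sequencing and are collapsed into
one isodecoder per unique sequence (lexicographically first member name as
id). Collapsing is idempotent and refuses identical sequences carrying
conflicting anticodon annotations. Anticodons are stored in the DNA
alphabet (U→T on input). The isotype of an anticodon is derived by
reverse-complementing to its Watson–Crick codon and decoding with the
standard genetic code; iMet, SeC, and Sup keep their declared labels and
form groups separate from the standard isoacceptors (iMet-CAT ≠ Met-CAT).
Compartment (cytosolic vs mitochondrial) is taken from which reference
file a sequence came from, not from name parsing, because mitochondrial
naming conventions vary; mitochondrial features never merge into a
cytosolic group even when anticodons coincide.

## Normalization and summaries

Counts are scaled to reads per million mapped (RPM). RPM is compositional,
so the denominator is explicit: all mapped tRNA reads (default) or
cytosolic-only, the latter used for all cytosolic analyses because
mitochondrial content varies strongly between tissues for reasons
(mitochondrial abundance) unrelated to cytosolic translation. Aggregation
to isoacceptor/isotype is a plain within-group sum and commutes with RPM
normalization at fixed denominator.

Cross-sample dispersion uses the coefficient of variation, CV = sd/mean
with the n−1 sd, computed by default across all samples (a tissue-mean
mode first averages replicates). Features with zero mean are reported
missing, never as CV 0. Sample–sample correlations and isodecoder pair
correlations are Pearson correlations of log2(RPM+1) by default (raw mode
available); tRNA expression spans orders of magnitude and the log keeps a
few dominant species from carrying the correlation.

## Usage-bias metrics

All five metrics share one shape: observed usage divided by the
equal-usage expectation within a synonymous family.

* RSIU (isodecoders within an isoacceptor) and RSAU (anticodons within an
  isotype): n_i · x_ij / Σ_j x_ij with n_i the number of observed family
  members. Families with zero total are flagged missing rather than
  imputed, so unexpressed groups cannot fabricate usage values.
* Weighted RSCU: the classic relative synonymous codon usage with each
  gene's codon counts weighted by its IP FPKM. Here n_i is the
  genetic-code family size (6 for Leu even if one codon is absent from the
  gene set), matching the classic definition; all weights equal reduces to
  unweighted RSCU. Met and Trp are single-codon families with RSCU ≡ 1;
  stop codons belong to no family.
* Codon index: each gene contributes its within-gene codon proportions
  scaled by IP FPKM; the total is renormalized to sum to 1 over the 61
  sense codons.
* Amino-acid composition: comp_i = Σ_j n_ij · w_j with n_ij the count of
  codons encoding amino acid i in gene j. The printed definition of this
  quantity is ambiguous about whether the codon count sits inside the gene
  sum; it is implemented inside (a weighted sum of per-gene counts), which
  is the only dimensionally consistent reading and matches the verbal
  description "number of codons encoding the amino acid, weighted by
  translation level". Cross-sample comparisons use the normalized variant,
  since raw compositions scale with sequencing depth.

Weights default to per-sample IP FPKM; a tissue-mean weight mode is just a
different weight vector passed by the caller.

## Translational efficiency and strata

TE = IP FPKM / input FPKM per gene and sample, kept only where both FPKMs
are strictly greater than 1 (low-expression ratios are unstable). A gene
gets a tissue TE only if it passes the filter in every replicate of the
tissue; replicate TEs are then averaged before ranking (whether to average
before or after ranking was an open choice; averaging first makes strata a
property of the tissue, not of a replicate). HTG/LTG are the top/bottom
ceil(0.05·n) genes; MTG is the same-size window centered on the median
rank — "medium" has no standard definition, and the median-centered window
is the symmetric choice. All ties break lexicographically by gene id so
strata are byte-reproducible.

## tAI

Each sense codon's absolute adaptiveness is W_c = Σ (1−s)·A(anticodon)
over its decoding anticodons, where A is anticodon-level RPM of the tissue
pool (replicate mean, cytosolic only, special groups excluded) — the
expression-for-gene-copy-number substitution that makes the index
tissue-specific. Pairing rules per codon third position: the Watson–Crick
anticodon plus one wobble reader (G34:U3 s=0.41, I34:C3 s=0.28, I34:A3
s=0.9999, U34:G3 s=0.68); anticodons with A34 are treated as
inosine-modified; the bacterial lysidine rule (C34:A3, s=0.89) is off for
eukaryotes. The penalties are the canonical initial values of the tAI
method and are exposed for override; no regression re-estimation of s is
performed. Relative adaptiveness w = W/max(W); codons with no expressed
decoder receive the geometric mean of the nonzero w values and are
flagged, so a missing decoder neither zeroes a gene score nor silently
inflates it. Gene tAI is the geometric mean of w over the gene's sense
codons with multiplicity; ATG and TGG are included by default (flag to
exclude). For pool-vs-usage correlation, the decoding relation is
flattened to one-to-one (codon, anticodon) pairs — a codon read by k
anticodons contributes k paired observations.

## Permutation tests

The tested null is "anticodon labels are exchangeable across cytosolic
isodecoders": labels are permuted uniformly, features regrouped by the
permuted label (amino-acid identity follows the permuted anticodon through
the genetic code; special labels carry their declared isotype), and the
statistic — the mean over groups of the cross-sample CV of isoacceptor
expression, RSAU, or isotype expression — recomputed. Empirical p is the
plain proportion of permutations strictly beyond the observed value in the
declared tail (greater for the expression CVs, smaller for RSAU CV); ties
count as non-extreme, and a (b+1)/(n+1) continuity-corrected variant is
available by flag. A permutation-invariant statistic yields a constant
null; the result is flagged degenerate instead of reporting p = 0.
Special groups are excluded from permutation by default (they have no
synonymous alternatives); a flag includes them. The engine evaluates all
permutations of a batch with one bincount pass per sample, so 10,000
permutations of a ~200-isodecoder, 6-sample matrix take well under a
second.

## Synthetic data

The generator mirrors a three-tissue (brain/heart/testis), two-replicate
design. Isodecoder counts follow a hierarchical model chosen to mirror
exactly the three co-regulation strata the analyses probe: per-isodecoder
log-baselines ~ N(0, 1); independent Gaussian tissue effects at the
amino-acid (sigma_aa), anticodon (sigma_ac), and isodecoder (sigma_iso)
levels; a softmax turns summed log-abundances into a composition (RPM is
scale-free, so only the composition matters); means are the composition
times a library size split between a cytosolic and a mitochondrial block
(per-tissue mt fractions 0.389/0.644/0.111, the scale of mt-tRNA content
differences seen between mouse brain, heart, and testis); counts are
negative binomial via gamma–Poisson mixing with dispersion 0.05 (typical
bulk-RNA-seq biological replicate dispersion) at a library size of 1e6.
Default effect sds (sigma_aa 0.3, sigma_ac 0.1, sigma_iso 0.3) give
clearly tissue-specific isodecoders with milder anticodon-level structure.
The inventory draws 1–4 anticodons per amino acid and 1–9 isodecoders per
anticodon, giving ~45–50 standard isoacceptors and ~200–230 cytosolic
isodecoders plus the four special groups and 22 mt features — the scale of
a mouse tRNA reference.

CDS sets are ATG + iid sense codons + stop, with per-amino-acid synonymous
profiles (uniform by default, Dirichlet helper for biased sets).
Translatomes couple log TE to the pool-standardized gene tAI with strength
in [0,1] plus N(0, 0.5) noise; input FPKM is log-normal (log-mean 2.3 ≈
median 10 FPKM, log-sd 1, the scale of expressed-gene FPKM distributions);
IP = input × TE, with small log-normal replicate noise (sd 0.1) on both
channels.

What the generator does *not* emulate: read-level effects (mapping bias,
tRNA modification-induced misincorporation), correlated effect structure
across tissues, gene-length/GC confounding of FPKM, and isoform mixtures.
Passing recovery tests therefore shows the estimators and tests behave
correctly under the assumed sampling model, not that real libraries are
free of these artifacts.

## Verification sizes and numerical choices

The automated checks run at these sizes, chosen to keep the full suite
around a minute while leaving the Monte Carlo margins wide:

* metric exactness: 50 random instances (≤20 genes, ≤30 isodecoders)
  against independent nested-loop oracles, tolerance 1e-12;
* tAI: exact match (1e-12) to a 64×64 exhaustive pairing scan on random
  pools; concatenation identity to 1e-12;
* permutation calibration: 500 null datasets × 1,000 permutations per
  statistic; nominal-rate window 3–7% at α = 0.05 and KS uniformity at
  p > 0.01;
* structure recovery: 50 datasets at sigma_aa = 0.5, sigma_iso = 0.05,
  sigma_ac = 0 (strong amino-acid co-regulation, constant within-family
  anticodon ratios), requiring detection in ≥90%;
* coupling recovery: 50 datasets each at coupling 1 and 0 with 400 genes,
  requiring rank-sum p < 1e-3 in ≥95% (coupled) and ≤10% false positives
  (uncoupled);
* determinism: the pipeline fixture run twice must be byte-identical,
  which constrains all output formatting (sorted keys, fixed column
  order, pandas default float repr — the shortest round-trip
  representation, so written tables read back exactly).

Degenerate inputs are errors or flags, never silent zeros: zero-total
samples, all-zero pools, genes with no sense codons, and constant
permutation nulls all refuse or flag.

## Known limitations

* RSAU/RSIU use observed family sizes, so a family's n_i can differ
  between datasets in which different members are expressed.
* The permutation null permutes labels within the cytosolic standard set
  only; it does not model uncertainty in the counts themselves.
* tAI uses fixed canonical penalties; tissues could in principle differ in
  wobble-modification efficiency, which this parameterization cannot see.
* The FPKM > 1 filter interacts with TE: genes with extreme TE in either
  direction are more likely to fail it in one channel, so strata are
  defined on the filtered gene universe.
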