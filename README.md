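# trnatlas

Tools for asking whether tissue-specific tRNA pools shape tissue-specific
translation. Given tRNA-seq counts of unique-sequence tRNA transcripts
(isodecoders) and a paired input/IP RNA-seq translatome, `trnatlas`
quantifies tRNA expression at three resolutions, measures synonymous usage
bias, scores codon adaptation, and tests whether grouping-level variation
differs from what label permutation alone would produce. A synthetic-data
module generates all inputs with known ground truth, so every stage is
testable without access to sequencing data.

## What it computes

**Inventory and quantification.** tRNA reference FASTAs (GtRNAdb-style
names, cytosolic + mitochondrial) are collapsed to unique sequences; each
isodecoder is assigned to an isoacceptor (isotype, anticodon) and an isotype
(amino acid), with iMet, SeC, and suppressor tRNAs kept as separate groups.
Counts are normalized to RPM (all-mapped or cytosolic-only denominator) and
aggregated by group.

**Usage-bias metrics.** For a feature *j* in a synonymous family *i* with
*n<sub>i</sub>* members and abundance *x<sub>ij</sub>*:

    RSIU_ij / RSAU_ij = n_i * x_ij / Σ_j x_ij

at the isodecoder-within-anticodon and anticodon-within-amino-acid levels.
For codon usage of a gene set weighted by translation level (IP FPKM
*w<sub>k</sub>*):

    RSCU_ij = n_i * Σ_k x_ijk w_k / Σ_j Σ_k x_ijk w_k
    codon index_i  = Σ_j (x_ij / Σ_i x_ij) w_j, normalized to Σ_i = 1
    AA composition_i = Σ_j n_ij w_j  (optionally normalized)

**Translatome.** TE = IP FPKM / input FPKM for genes with both FPKMs > 1
(strict); genes are ranked by tissue-mean TE and split into HTG / MTG / LTG
(top, median-centered, bottom 5%).

**tAI.** Per-codon absolute adaptiveness W<sub>c</sub> = Σ (1−s) ·
RPM(anticodon) over the decoding anticodons, with canonical wobble penalties
(G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68); w = W / max W; gene tAI is the
geometric mean of w over the gene's codons. Abundance is the anticodon-level
RPM of a tissue's tRNA pool, i.e. expression substitutes for gene copy
number.

**Permutation tests.** Anticodon labels of cytosolic isodecoders are
permuted, features regrouped, and the mean CV across samples of isoacceptor
expression, RSAU, or isotype expression recomputed; the empirical p is the
fraction of permutations beyond the observed value in the stated tail.

**Association analyses.** Isodecoder pair co-expression by category (same
anticodon / same amino acid / different amino acid); tAI of TE strata under
matched and mismatched tissue pools; amino-acid composition of highly
translated genes vs isotype-level tRNA supply within and across tissues.

## Worked example

```sh
trnatlas simulate --seed 5 --out sim/
trnatlas permtest \
    --counts sim/trna_counts.tsv --sample-sheet sim/sample_sheet.tsv \
    --ct-fasta sim/trna_reference.fasta \
    --statistic rsau_cv --tail smaller --n-perm 1000 --seed 7 --out perm.json
```

prints

```
wrote 204 isodecoders x 6 samples to sim
p = 0.835 (rsau_cv, tail=smaller, n_perm=1000)
```

The simulated design is three tissues x two replicates with moderate
co-regulation (the generator's defaults). The RSAU test asks whether
anticodon usage bias within amino acids varies *less* across samples than
after anticodon-label permutation; p = 0.835 means 835 of 1000 permuted
datasets had a smaller mean RSAU CV than the observed one — no usage-bias
stabilization, the expected answer here, since the default simulation
injects its tissue signal as expression-level effects rather than as
anticodon preference shifts.

The full pipeline runs from one YAML config and writes ~20 TSV/JSON tables
plus a manifest of output hashes:

```sh
trnatlas run --config tests/data/pipeline_config.yaml --out results/
```

As a library:

```python
from trnatlas import (TrnaSimConfig, simulate_trna_counts, compute_rpm,
                      permutation_test)
counts, records, truth = simulate_trna_counts(TrnaSimConfig(seed=1))
rpm = compute_rpm(counts, records, denominator="ct_only")
res = permutation_test(rpm, records, "isotype_expression_cv", "greater",
                       n_perm=10_000, seed=1)
print(res.observed, res.p)
```

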