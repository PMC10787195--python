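"""Synonymous-usage metrics for codons, anticodons, and isodecoders.

Five related quantities describe how translation distributes itself over
interchangeable alternatives:

* RSIU — relative synonymous isodecoder usage: within an isoacceptor with n_i
  isodecoders, RSIU_ij = n_i * x_ij / sum_j x_ij of the isodecoder RPMs.
* RSAU — relative synonymous anticodon usage: the same ratio for anticodons
  within an amino-acid isotype.
* weighted RSCU — the classic relative synonymous codon usage of Sharp &
  Li, with each gene's codon counts weighted by its translation level
  (IP FPKM): RSCU_ij = n_i * sum_k x_ijk w_k / sum_j sum_k x_ijk w_k.
* codon index — the translation-weighted codon composition of a gene set:
  each gene contributes its codon proportions scaled by IP FPKM; the result
  is normalized to sum to 1 over the 61 sense codons.
* amino-acid composition — translation-weighted amino-acid counts,
  comp_i = sum_j n_ij w_j, where n_ij counts codons of amino acid i in gene j.

All of these equal 1 (or a flat profile) under no usage bias, and a family
mean of RSCU/RSAU/RSIU over its members is always 1 when every member is
observed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .genetic_code import (
    AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    normalize_nt,
)

ALL_CODONS = tuple(sorted(SENSE_CODONS + STOP_CODONS))


def count_codons(cds: str) -> pd.Series:
    """Count codon occurrences in an in-frame coding sequence.

    Returns counts over all 64 codons; use :func:`sense_counts` to drop the
    stop columns. The reading frame is trusted: an internal stop codon draws
    a warning but counting continues past it.
    """
    seq = normalize_nt(cds)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    valid = set(ALL_CODONS)
    for i, codon in enumerate(codons):
        if codon not in valid:
            raise ValueError(f"non-ACGT codon {codon!r} at position {3 * i}")
    internal = [c for c in codons[:-1] if c in STOP_CODONS]
    if internal:
        warnings.warn(
            f"internal stop codon(s) {sorted(set(internal))}; frame trusted",
            stacklevel=2,
        )
    tallies = Counter(codons)
    return pd.Series(
        [tallies.get(c, 0) for c in ALL_CODONS], index=list(ALL_CODONS), dtype=int
    )


def count_codons_table(cds_by_gene: Mapping[str, str]) -> pd.DataFrame:
    """Codon count table (genes x 64 codons) for a set of CDS sequences."""
    rows = {g: count_codons(s) for g, s in cds_by_gene.items()}
    table = pd.DataFrame(rows).T
    table.index.name = "gene"
    return table.loc[:, list(ALL_CODONS)]


def sense_counts(codon_counts: pd.DataFrame) -> pd.DataFrame:
    """Drop stop-codon columns, keeping the 61 sense codons."""
    return codon_counts.loc[:, [c for c in codon_counts.columns if c in CODON_TO_AA]]


def relative_synonymous_usage(
    values: pd.DataFrame | pd.Series, family_of: Mapping[str, object]
) -> pd.DataFrame | pd.Series:
    """Generic within-family relative usage: n_i * x / family sum.

    ``values`` holds non-negative abundances per feature (rows), per sample
    (columns) if a DataFrame. ``family_of`` maps each feature to its
    synonymous-family key; n_i is the number of features in the family.
    Families with zero total in a sample come out NaN (missing), not 0.
    """
    series_in = isinstance(values, pd.Series)
    vals = values.to_frame() if series_in else values
    missing = [f for f in vals.index if f not in family_of]
    if missing:
        raise ValueError(f"features without a family: {missing}")
    fam = pd.Series([family_of[f] for f in vals.index], index=vals.index)
    sizes = fam.map(fam.value_counts())
    totals = vals.groupby(fam).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = vals.mul(sizes, axis=0) / totals
    out = out.where(totals > 0)
    return out.iloc[:, 0] if series_in else out


def rsiu(rpm: pd.DataFrame | pd.Series, grouping) -> pd.DataFrame | pd.Series:
    """Relative synonymous isodecoder usage within isoacceptors."""
    return relative_synonymous_usage(rpm, grouping.isoacceptor_of)


def rsau(
    anticodon_rpm: pd.DataFrame | pd.Series, isotype_of_anticodon: Mapping[str, str]
) -> pd.DataFrame | pd.Series:
    """Relative synonymous anticodon usage within amino-acid isotypes.

    ``anticodon_rpm`` is indexed by isoacceptor key; ``isotype_of_anticodon``
    maps each key to its amino acid.
    """
    return relative_synonymous_usage(anticodon_rpm, isotype_of_anticodon)


def _check_weights(
    codon_counts: pd.DataFrame, weights: pd.Series, gene_set
) -> tuple[pd.DataFrame, pd.Series]:
    genes = list(gene_set) if gene_set is not None else list(codon_counts.index)
    if not genes:
        raise ValueError("empty gene set")
    absent = [g for g in genes if g not in codon_counts.index]
    if absent:
        raise ValueError(f"genes missing from codon table: {absent}")
    sub = sense_counts(codon_counts.loc[genes])
    w = weights.reindex(genes)
    if w.isna().any():
        raise ValueError(f"genes without weights: {list(w.index[w.isna()])}")
    if (w < 0).any():
        raise ValueError("negative weights")
    zero = sub.sum(axis=1) == 0
    if zero.any():
        warnings.warn(
            f"excluding genes with zero counted codons: {list(sub.index[zero])}",
            stacklevel=3,
        )
        sub, w = sub.loc[~zero], w.loc[~zero]
    if len(sub) == 0 or float(w.sum()) == 0:
        raise ValueError("no genes with positive codon counts and weights")
    return sub, w


def weighted_rscu(
    codon_counts: pd.DataFrame, weights: pd.Series, gene_set=None
) -> pd.Series:
    """Translation-weighted relative synonymous codon usage per sense codon.

    With all weights equal this reduces to the classic (unweighted) RSCU.
    Single-codon families (Met, Trp) are identically 1; families with zero
    weighted usage are NaN.
    """
    sub, w = _check_weights(codon_counts, weights, gene_set)
    weighted = sub.mul(w, axis=0).sum(axis=0)  # per-codon weighted total
    fam = {c: CODON_TO_AA[c] for c in weighted.index}
    return relative_synonymous_usage(weighted, fam)


def codon_index(
    codon_counts: pd.DataFrame, weights: pd.Series, gene_set=None
) -> pd.Series:
    """Translation-weighted codon composition of a gene set, summing to 1.

    Each gene contributes its within-gene codon proportions scaled by its
    weight; the total is renormalized over the 61 sense codons.
    """
    sub, w = _check_weights(codon_counts, weights, gene_set)
    props = sub.div(sub.sum(axis=1), axis=0)
    raw = props.mul(w, axis=0).sum(axis=0)
    return raw / raw.sum()


def amino_acid_composition(
    codon_counts: pd.DataFrame,
    weights: pd.Series,
    gene_set=None,
    normalize: bool = True,
) -> pd.Series:
    """Translation-weighted amino-acid usage: comp_i = sum_j n_ij * w_j.

    n_ij is the number of codons of amino acid i in gene j. The normalized
    variant (default) divides by the grand total so compositions are
    comparable across samples of different sequencing depth.
    """
    sub, w = _check_weights(codon_counts, weights, gene_set)
    aa = pd.Series({c: CODON_TO_AA[c] for c in sub.columns})
    per_aa = sub.T.groupby(aa).sum().T  # genes x amino acids
    raw = per_aa.mul(w, axis=0).sum(axis=0).reindex(list(AMINO_ACIDS), fill_value=0.0)
    return raw / raw.sum() if normalize else raw


def usage_long_table(values: pd.DataFrame, metric: str, level: str) -> pd.DataFrame:
    """Flatten a feature x sample metric table into long format for TSV."""
    long = values.reset_index(names="member").melt(
        id_vars="member", var_name="sample", value_name="value"
    )
    long.insert(0, "metric", metric)
    long.insert(1, "level", level)
    return long


# number of synonymous codons per amino acid (family size n_i of RSCU)
FAMILY_SIZES: dict[str, int] = {aa: len(c) for aa, c in SYNONYMOUS_FAMILIES.items()}
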