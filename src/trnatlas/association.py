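"""Correlation analyses linking tRNA expression to the translatome.

Three questions, three analyses:

* Are isodecoders co-expressed according to what they decode? Every
  unordered pair of isodecoders is scored with a Pearson correlation across
  samples and put in one of three categories — same anticodon, same amino
  acid but different anticodons, different amino acids — and the category
  distributions are compared with two-tailed rank-sum tests.
* Does a tissue's tRNA pool adapt to what that tissue translates? Gene tAI
  under a matched pool is compared between TE strata within a tissue, and
  each tissue's highly translated genes are scored under every tissue's pool
  to ask whether adaptation is tissue-matched.
* Does amino-acid demand track isotype supply? The translation-weighted
  amino-acid composition of the highly translated genes is correlated with
  isotype-level tRNA expression, within tissues (across the 20 amino acids)
  and across tissues (per-amino-acid mean-centered compositions against
  per-amino-acid Z-scored expression, pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .genetic_code import AMINO_ACIDS
from .inventory import IsodecoderRecord
from .translatome import TEStrata

SAME_ANTICODON = "same_anticodon"
SAME_AA_DIFF_ANTICODON = "same_aa_diff_anticodon"
DIFF_AA = "diff_aa"


@dataclass
class GroupComparison:
    """A two-group test result (rank-sum for unpaired, signed-rank paired)."""

    group_a: str
    group_b: str
    test: str
    statistic: float
    p: float


def rank_sum(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) comparison."""
    stat, p = stats.ranksums(a, b)
    return GroupComparison(label_a, label_b, "rank_sum_two_tailed", float(stat), float(p))


def signed_rank(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-tailed Wilcoxon signed-rank comparison for paired values.

    All-identical pairs carry no evidence either way and return p = 1
    instead of scipy's undefined statistic.
    """
    if np.allclose(np.asarray(a, dtype=float), np.asarray(b, dtype=float)):
        return GroupComparison(label_a, label_b, "signed_rank", 0.0, 1.0)
    stat, p = stats.wilcoxon(a, b)
    return GroupComparison(label_a, label_b, "signed_rank", float(stat), float(p))


def pair_correlation_categories(
    rpm: ExpressionMatrix,
    records: list[IsodecoderRecord],
    transform: str = "log2p1",
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Score all isodecoder pairs and compare the three co-expression classes.

    Pairs involving a zero-variance isodecoder get a missing PCC. Categories
    partition the N(N-1)/2 unordered pairs by the labels of the two records.
    """
    if rpm.values.shape[1] < 3:
        raise ValueError("pair correlations require at least 3 samples")
    by_id = {r.id: r for r in records}
    ids = [f for f in rpm.features if f in by_id]
    if len(ids) < 2:
        raise ValueError("need at least 2 isodecoders present in the matrix")
    vals = rpm.values.loc[ids]
    if transform == "log2p1":
        vals = np.log2(vals + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    arr = vals.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)

    rows = []
    for i, j in combinations(range(len(ids)), 2):
        a, b = by_id[ids[i]], by_id[ids[j]]
        if a.isoacceptor_key == b.isoacceptor_key:
            cat = SAME_ANTICODON
        elif a.isotype == b.isotype:
            cat = SAME_AA_DIFF_ANTICODON
        else:
            cat = DIFF_AA
        pcc = np.nan if sd[i] == 0 or sd[j] == 0 else corr[i, j]
        rows.append((ids[i], ids[j], pcc, cat))
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "pcc", "category"])

    comparisons = []
    groups = {c: pairs.loc[pairs["category"] == c, "pcc"].dropna() for c in
              (SAME_ANTICODON, SAME_AA_DIFF_ANTICODON, DIFF_AA)}
    for ca, cb in combinations(groups, 2):
        if len(groups[ca]) and len(groups[cb]):
            comparisons.append(rank_sum(groups[ca], groups[cb], ca, cb))
    return pairs, comparisons


def tai_te_analysis(
    tai_by_pool: pd.DataFrame, strata: dict[str, TEStrata]
) -> tuple[list[GroupComparison], pd.DataFrame, list[GroupComparison]]:
    """Within-tissue TE-strata tAI comparisons and the cross-tissue matrix.

    ``tai_by_pool`` is genes x pools (one column per tissue's tRNA pool).
    Returns (within-tissue comparisons under the matched pool, a matrix of
    median HTG tAI for each HTG set under each pool, cross-pool comparisons
    of each HTG set).
    """
    within: list[GroupComparison] = []
    for tissue, st in strata.items():
        if not (st.htg and st.mtg and st.ltg):
            raise ValueError(f"empty stratum for tissue {tissue!r}")
        if tissue not in tai_by_pool.columns:
            raise ValueError(f"no tAI column for pool {tissue!r}")
        tai = tai_by_pool[tissue]
        vals = {s: tai.loc[list(genes)].dropna()
                for s, genes in (("HTG", st.htg), ("MTG", st.mtg), ("LTG", st.ltg))}
        for a, b in (("HTG", "MTG"), ("HTG", "LTG"), ("MTG", "LTG")):
            cmp = rank_sum(vals[a], vals[b], f"{tissue}:{a}", f"{tissue}:{b}")
            within.append(cmp)

    pools = list(tai_by_pool.columns)
    matrix = pd.DataFrame(index=list(strata), columns=pools, dtype=float)
    cross: list[GroupComparison] = []
    for tissue, st in strata.items():
        htg = list(st.htg)
        for pool in pools:
            matrix.loc[tissue, pool] = float(tai_by_pool.loc[htg, pool].median())
        for pa, pb in combinations(pools, 2):
            cross.append(
                signed_rank(
                    tai_by_pool.loc[htg, pa],
                    tai_by_pool.loc[htg, pb],
                    f"{tissue}_HTG@{pa}",
                    f"{tissue}_HTG@{pb}",
                )
            )
    matrix.index.name = "htg_tissue"
    matrix.columns.name = "pool"
    return within, matrix, cross


def aa_coupling(
    compositions: pd.DataFrame,
    isotype_expression: pd.DataFrame,
    mode: str = "within_tissue",
) -> pd.DataFrame:
    """Correlate amino-acid composition of translation with isotype supply.

    ``compositions`` is tissues x amino acids (normalized); ``isotype_expression``
    is tissues x amino-acid isotypes (RPM). ``within_tissue`` returns one PCC
    per tissue over the shared amino acids; ``across_tissue`` mean-centers each
    amino acid's composition across tissues, Z-scores each isotype's
    expression across tissues, pools all (tissue, amino acid) points, and
    returns a single PCC. Special isotypes are not amino acids and are
    excluded by construction of the shared key set.
    """
    shared = [a for a in AMINO_ACIDS
              if a in compositions.columns and a in isotype_expression.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared amino-acid keys; need >= 3")
    comp = compositions[shared].astype(float)
    expr = isotype_expression[shared].astype(float)
    tissues = [t for t in comp.index if t in expr.index]
    comp, expr = comp.loc[tissues], expr.loc[tissues]

    if mode == "within_tissue":
        rows = []
        for t in tissues:
            r, p = stats.pearsonr(comp.loc[t], expr.loc[t])
            rows.append((t, float(r), float(p), len(shared)))
        return pd.DataFrame(rows, columns=["tissue", "pcc", "p", "n"])
    if mode == "across_tissue":
        centered = comp - comp.mean(axis=0)
        z = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
        x = centered.to_numpy().ravel()
        y = z.to_numpy().ravel()
        keep = ~(np.isnan(x) | np.isnan(y))
        r, p = stats.pearsonr(x[keep], y[keep])
        return pd.DataFrame(
            [("all", float(r), float(p), int(keep.sum()))],
            columns=["tissue", "pcc", "p", "n"],
        )
    raise ValueError(f"unknown mode {mode!r}")
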