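"""Expression-weighted tRNA adaptation index (tAI).

tAI scores how well a gene's codon usage matches a tRNA pool. Each sense
codon gets an absolute adaptiveness W_c = sum over decoding anticodons of
(1 - s) * abundance, where s is the selective penalty of the codon:anticodon
pairing class, and abundance here is the anticodon-level RPM of a tissue's
tRNA pool (expression replacing the usual gene copy number). Relative
adaptiveness is w_c = W_c / max W; a gene's tAI is the geometric mean of w
over its codons with multiplicity, so tAI is in (0, 1] and equals 1 only for
genes built entirely from the best-adapted codons.

Pairing classes and default penalties follow the canonical tAI model:
Watson-Crick pairs cost nothing; wobble reads carry class-specific penalties
(G34:U3 0.41, I34:C3 0.28, I34:A3 0.9999, U34:G3 0.68). Anticodons with A at
position 34 are treated as inosine-modified, so they read codons ending in
U, C, and A. The bacterial lysidine rule (C34 reading A-ending Ile codons,
s = 0.89) is disabled for eukaryotes.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import CODON_TO_AA, SENSE_CODONS, reverse_complement

#: default selective penalties per wobble class (canonical initial values)
DEFAULT_S: dict[str, float] = {
    "WC": 0.0,
    "I:U": 0.0,  # inosine (A34) reading U-ending codons; Watson-Crick-like
    "G:U": 0.41,
    "I:C": 0.28,
    "I:A": 0.9999,
    "U:G": 0.68,
    "L:A": 0.89,  # lysidine-modified C34 reading A-ending codons (bacteria)
}

# codon third base -> [(anticodon position-34 base, pairing class)]
_WOBBLE_34: dict[str, list[tuple[str, str]]] = {
    "T": [("A", "I:U"), ("G", "G:U")],
    "C": [("G", "WC"), ("A", "I:C")],
    "A": [("T", "WC"), ("A", "I:A"), ("C", "L:A")],
    "G": [("C", "WC"), ("T", "U:G")],
}


@dataclass(frozen=True)
class PairingRule:
    codon: str
    anticodon: str
    pairing_class: str
    s: float

    @property
    def weight(self) -> float:
        return 1.0 - self.s


@dataclass
class PairingRules:
    """Codon <-> anticodon decoding relations with wobble penalties."""

    rules: list[PairingRule]
    eukaryote: bool = True

    def for_codon(self, codon: str) -> list[PairingRule]:
        return [r for r in self.rules if r.codon == codon]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.codon, r.anticodon, r.pairing_class, r.s) for r in self.rules],
            columns=["codon", "anticodon", "pairing_class", "s"],
        )


def build_pairing_rules(
    s_overrides: Mapping[str, float] | None = None, eukaryote: bool = True
) -> PairingRules:
    """Enumerate all codon:anticodon decoding relations for sense codons.

    Every sense codon gets its Watson-Crick anticodon plus the wobble readers
    of its third position; relations are dropped when the weight (1 - s) is 0.
    """
    s_values = dict(DEFAULT_S)
    if s_overrides:
        unknown = set(s_overrides) - set(DEFAULT_S)
        if unknown:
            raise ValueError(f"unknown pairing classes: {sorted(unknown)}")
        s_values.update(s_overrides)
    for cls, s in s_values.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"penalty for {cls} outside [0, 1]: {s}")

    rules: list[PairingRule] = []
    for codon in SENSE_CODONS:
        wc_anticodon = reverse_complement(codon)
        for base34, cls in _WOBBLE_34[codon[2]]:
            if cls == "L:A" and eukaryote:
                continue
            anticodon = base34 + wc_anticodon[1:]
            rules.append(PairingRule(codon, anticodon, cls, s_values[cls]))
    return PairingRules(rules=rules, eukaryote=eukaryote)


def codon_adaptiveness(
    trna_pool: Mapping[str, float] | pd.Series, rules: PairingRules
) -> pd.DataFrame:
    """Absolute (W) and relative (w) adaptiveness per sense codon.

    ``trna_pool`` maps anticodon -> abundance (anticodon-level RPM of the
    tissue pool); anticodons absent from the pool contribute 0. Codons with
    no expressed decoder (W = 0) are assigned the geometric mean of the
    nonzero w values and flagged, so the geometric mean in gene tAI stays
    finite without dominating it.
    """
    pool = pd.Series(dict(trna_pool), dtype=float)
    if (pool < 0).any():
        raise ValueError("negative pool abundances")
    if len(pool) == 0 or float(pool.sum()) == 0:
        raise ValueError("tRNA pool is empty or all-zero")
    W = pd.Series(0.0, index=list(SENSE_CODONS))
    for rule in rules.rules:
        W[rule.codon] += rule.weight * float(pool.get(rule.anticodon, 0.0))
    w = W / W.max()
    substituted = w == 0
    if substituted.any():
        gmean_w = float(np.exp(np.log(w[~substituted]).mean()))
        w = w.mask(substituted, gmean_w)
    return pd.DataFrame({"W": W, "w": w, "substituted": substituted})


def gene_tai(
    codon_counts: pd.Series, w: pd.Series, exclude_single_codon_families: bool = False
) -> float:
    """Geometric mean of relative adaptiveness over a gene's sense codons.

    ``codon_counts`` gives the gene's codon occurrences (stop codons, if
    present, are ignored). The single-codon families ATG and TGG are included
    by default; set ``exclude_single_codon_families`` to drop them, as some
    tAI variants do.
    """
    counts = codon_counts.reindex(list(SENSE_CODONS), fill_value=0).astype(float)
    if exclude_single_codon_families:
        counts[["ATG", "TGG"]] = 0.0
    total = counts.sum()
    if total == 0:
        raise ValueError("gene has no counted sense codons")
    logs = np.log(w.reindex(counts.index).to_numpy())
    return float(np.exp((counts.to_numpy() * logs).sum() / total))


def genes_tai(
    codon_counts: pd.DataFrame, w: pd.Series, exclude_single_codon_families: bool = False
) -> pd.Series:
    """Vectorized gene tAI for a genes x codons count table."""
    counts = codon_counts.reindex(columns=list(SENSE_CODONS), fill_value=0).astype(float)
    if exclude_single_codon_families:
        counts[["ATG", "TGG"]] = 0.0
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(
            f"genes with no counted sense codons: {list(totals.index[totals == 0])}"
        )
    logs = np.log(w.reindex(counts.columns).to_numpy())
    out = pd.Series(np.exp(counts.to_numpy() @ logs / totals.to_numpy()), index=counts.index)
    out.name = "tai"
    return out


def expand_one_to_one_pairs(rules: PairingRules) -> list[tuple[str, str]]:
    """Flatten the decoding relation into one-to-one (codon, anticodon) pairs.

    A codon read by k anticodons appears k times, and an anticodon reading k
    codons appears k times, so paired codon-side and anticodon-side vectors
    can be correlated observation-by-observation.
    """
    return [(r.codon, r.anticodon) for r in rules.rules]


def pool_usage_correlation(
    isoacceptor_rpm: Mapping[str, float] | pd.Series,
    codon_index: pd.Series,
    pairs: list[tuple[str, str]],
) -> tuple[float, float]:
    """Pearson correlation between tRNA abundance and codon usage over pairs.

    Each one-to-one (codon, anticodon) pair contributes one observation:
    (pool RPM of the anticodon, codon-index value of the codon). Returns
    (PCC, two-sided p) from the correlation t-test.
    """
    pool = pd.Series(dict(isoacceptor_rpm), dtype=float)
    xs, ys = [], []
    for codon, anticodon in pairs:
        if codon in codon_index.index:
            xs.append(float(pool.get(anticodon, 0.0)))
            ys.append(float(codon_index[codon]))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 pairs with data, got {len(xs)}")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
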