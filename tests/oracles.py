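"""Independent brute-force reference implementations.

Everything here is written as plain nested loops over dictionaries, with no
reuse of the package's vectorized code paths, so it can serve as an
independent oracle for the metric, adaptiveness, and statistic computations.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_CODON_AA = {c: seq3(a) for c, a in
             CodonTable.unambiguous_dna_by_name["Standard"].forward_table.items()}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def count_codons_loop(cds: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_index_loop(counts_by_gene, weights) -> dict[str, float]:
    """Eq-style translation-weighted codon proportions, normalized to 1."""
    raw: dict[str, float] = {}
    for gene, counts in counts_by_gene.items():
        sense = {c: n for c, n in counts.items() if c in _CODON_AA}
        total = sum(sense.values())
        if total == 0:
            continue
        for codon, n in sense.items():
            raw[codon] = raw.get(codon, 0.0) + (n / total) * weights[gene]
    grand = sum(raw.values())
    return {c: v / grand for c, v in raw.items()}


def weighted_rscu_loop(counts_by_gene, weights) -> dict[str, float]:
    weighted: dict[str, float] = {}
    for gene, counts in counts_by_gene.items():
        for codon, n in counts.items():
            if codon in _CODON_AA:
                weighted[codon] = weighted.get(codon, 0.0) + n * weights[gene]
    # n_i is the genetic-code family size, whether or not every codon occurs
    families: dict[str, list[str]] = {}
    for codon, aa in _CODON_AA.items():
        families.setdefault(aa, []).append(codon)
    out: dict[str, float] = {}
    for aa, codons in families.items():
        total = sum(weighted.get(c, 0.0) for c in codons)
        for c in codons:
            out[c] = (
                len(codons) * weighted.get(c, 0.0) / total
                if total > 0
                else float("nan")
            )
    return out


def rsu_loop(values: dict, family_of: dict) -> dict:
    """Relative synonymous usage: n_i * x / family total, NaN for zero totals."""
    members: dict = {}
    for key in values:
        members.setdefault(family_of[key], []).append(key)
    out = {}
    for fam, keys in members.items():
        total = sum(values[k] for k in keys)
        for k in keys:
            out[k] = len(keys) * values[k] / total if total > 0 else float("nan")
    return out


def aa_composition_loop(counts_by_gene, weights, normalize=True) -> dict[str, float]:
    comp: dict[str, float] = {}
    for gene, counts in counts_by_gene.items():
        for codon, n in counts.items():
            if codon in _CODON_AA:
                aa = _CODON_AA[codon]
                comp[aa] = comp.get(aa, 0.0) + n * weights[gene]
    if normalize:
        grand = sum(comp.values())
        comp = {a: v / grand for a, v in comp.items()}
    return comp


# --- tAI -------------------------------------------------------------------

_WOBBLE = {  # (anticodon position 34, codon position 3) -> penalty s
    ("A", "T"): 0.0,
    ("G", "T"): 0.41,
    ("G", "C"): 0.0,
    ("A", "C"): 0.28,
    ("T", "A"): 0.0,
    ("A", "A"): 0.9999,
    ("C", "G"): 0.0,
    ("T", "G"): 0.68,
}
_WOBBLE_PROK = dict(_WOBBLE)
_WOBBLE_PROK[("C", "A")] = 0.89


def adaptiveness_loop(pool: dict[str, float], eukaryote=True) -> dict[str, float]:
    """w per sense codon via exhaustive 64 x 64 codon-anticodon scan."""
    alphabet = "ACGT"
    anticodons = [a + b + c for a in alphabet for b in alphabet for c in alphabet]
    table = _WOBBLE if eukaryote else _WOBBLE_PROK
    W: dict[str, float] = {}
    for codon in _CODON_AA:
        total = 0.0
        for anticodon in anticodons:
            if anticodon[1] != _COMP[codon[1]] or anticodon[2] != _COMP[codon[0]]:
                continue
            s = table.get((anticodon[0], codon[2]))
            if s is None:
                continue
            total += (1.0 - s) * pool.get(anticodon, 0.0)
        W[codon] = total
    wmax = max(W.values())
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return {c: (v if v > 0 else gm) for c, v in w.items()}


def gene_tai_loop(codon_counts: dict[str, int], w: dict[str, float]) -> float:
    log_sum, n = 0.0, 0
    for codon, count in codon_counts.items():
        if codon in _CODON_AA and count > 0:
            log_sum += count * math.log(w[codon])
            n += count
    return math.exp(log_sum / n)


# --- statistics -------------------------------------------------------------


def cv_loop(values: list[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var) / mean


def pearson_loop(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)


def mean_cv_statistic_loop(rpm, anticodon_of, isotype_of, statistic) -> float:
    """Nested-loop mean-CV statistics on a {feature: {sample: rpm}} table.

    anticodon_of / isotype_of map feature -> group labels; the rsau_cv
    statistic needs both.
    """
    samples = sorted(next(iter(rpm.values())))

    def group_sums(label_of):
        sums: dict = {}
        for feat, per_sample in rpm.items():
            g = label_of[feat]
            if g not in sums:
                sums[g] = {s: 0.0 for s in samples}
            for s in samples:
                sums[g][s] += per_sample[s]
        return sums

    if statistic in ("isoacceptor_expression_cv", "isotype_expression_cv"):
        label_of = anticodon_of if statistic.startswith("isoacceptor") else isotype_of
        sums = group_sums(label_of)
        cvs = [cv_loop([v[s] for s in samples]) for v in sums.values()
               if sum(v.values()) > 0]
        return sum(cvs) / len(cvs)
    if statistic == "rsau_cv":
        ac_sums = group_sums(anticodon_of)
        aa_of_ac = {}
        for feat in rpm:
            aa_of_ac[anticodon_of[feat]] = isotype_of[feat]
        cvs = []
        for ac in ac_sums:
            aa = aa_of_ac[ac]
            siblings = [a for a in ac_sums if aa_of_ac[a] == aa]
            vals = []
            for s in samples:
                denom = sum(ac_sums[a][s] for a in siblings)
                if denom <= 0:
                    vals = None
                    break
                vals.append(len(siblings) * ac_sums[ac][s] / denom)
            if vals is not None and sum(vals) > 0:
                cvs.append(cv_loop(vals))
        return sum(cvs) / len(cvs)
    raise ValueError(statistic)
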