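"""Anticodon-permutation tests on mean-CV statistics.

Grouping isodecoders into isoacceptors reduces between-sample variation
simply because sums average out noise. To ask whether the *observed*
reduction (or a usage-bias statistic computed on the groups) is more than
that statistical effect, the anticodon labels of the cytosolic isodecoders
are randomly permuted, the features are regrouped by the permuted labels,
and the statistic is recomputed; the empirical p-value is the fraction of
permutations whose statistic is more extreme than the observed value in the
stated tail direction.

Three statistics are supported, each the mean across groups of a per-group
coefficient of variation across samples:

* ``isoacceptor_expression_cv`` — CV of anticodon-level summed RPM
  (tail ``greater``: is observed variation smaller than label-scrambled?)
* ``rsau_cv`` — CV of the relative synonymous anticodon usage values
  (tail ``smaller``: is observed usage bias *more* stable than scrambled?)
* ``isotype_expression_cv`` — CV of amino-acid-level summed RPM
  (tail ``greater``).

The p-value is the plain proportion with a strict inequality (ties count as
non-extreme); a ``(b+1)/(n+1)`` continuity-corrected variant is available. A
statistic that is invariant under permutation produces a constant null; the
result is then flagged degenerate instead of being reported as p = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .inventory import CYTOSOLIC, IsodecoderRecord

STATISTICS = ("isoacceptor_expression_cv", "rsau_cv", "isotype_expression_cv")
TAILS = ("greater", "smaller")


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null: np.ndarray
    tail: str
    p: float
    n_perm: int
    seed: int
    degenerate: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "statistic": self.statistic,
            "observed": self.observed,
            "p": self.p,
            "tail": self.tail,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def permute_anticodon_labels(labels, rng: np.random.Generator) -> list:
    """Uniform random permutation of a label vector (multiset preserved)."""
    labels = list(labels)
    return [labels[i] for i in rng.permutation(len(labels))]


def _setup(
    rpm: ExpressionMatrix,
    records: list[IsodecoderRecord],
    include_specials: bool = False,
):
    """Restrict to cytosolic isodecoders and encode their group labels.

    The permuted unit is the full isoacceptor key (isotype, anticodon), so
    regrouping at the amino-acid level follows the permuted anticodon through
    the genetic code, and special labels keep their declared isotype.
    """
    by_id = {r.id: r for r in records}
    ids = [
        f
        for f in rpm.features
        if f in by_id
        and by_id[f].compartment == CYTOSOLIC
        and (include_specials or not by_id[f].is_special)
    ]
    if len(ids) < 2:
        raise ValueError("need at least 2 cytosolic isodecoders")
    X = rpm.values.loc[ids].to_numpy(dtype=float)
    keys = [by_id[f].isoacceptor_key for f in ids]
    uniq = sorted(set(keys))
    code_of = {k: i for i, k in enumerate(uniq)}
    codes = np.array([code_of[k] for k in keys], dtype=np.int64)
    isotypes = sorted({k[0] for k in uniq})
    aa_code = {a: i for i, a in enumerate(isotypes)}
    aa_of_group = np.array([aa_code[k[0]] for k in uniq], dtype=np.int64)
    return X, codes, len(uniq), aa_of_group, len(isotypes)


def _group_sums(X: np.ndarray, codes2d: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-permutation group sums: (P, G, samples) from (P, n) label codes."""
    P, n = codes2d.shape
    n_samples = X.shape[1]
    flat = (codes2d + np.arange(P)[:, None] * n_groups).ravel()
    out = np.empty((P, n_groups, n_samples))
    for s in range(n_samples):
        w = np.broadcast_to(X[:, s], (P, n)).ravel()
        out[:, :, s] = np.bincount(flat, weights=w, minlength=P * n_groups).reshape(
            P, n_groups
        )
    return out


def _mean_cv(values: np.ndarray) -> np.ndarray:
    """Mean over groups of CV across samples; NaN groups excluded.

    ``values`` is (P, G, samples); a group's CV is sd(ddof=1)/mean and is
    missing when its mean is 0 or any sample value is missing.
    """
    mean = values.mean(axis=2)
    sd = values.std(axis=2, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return np.nanmean(cv, axis=1)


def _batch_statistic(
    X: np.ndarray,
    codes2d: np.ndarray,
    n_groups: int,
    aa_of_group: np.ndarray,
    n_aa: int,
    statistic: str,
) -> np.ndarray:
    S = _group_sums(X, codes2d, n_groups)
    if statistic == "isoacceptor_expression_cv":
        return _mean_cv(S)
    # amino-acid level sums, shared by the remaining statistics
    M = np.zeros((n_aa, n_groups))
    M[aa_of_group, np.arange(n_groups)] = 1.0
    T = np.einsum("ag,pgs->pas", M, S)
    if statistic == "isotype_expression_cv":
        return _mean_cv(T)
    if statistic == "rsau_cv":
        n_i = M.sum(axis=1)[aa_of_group]  # anticodons per amino acid
        denom = T[:, aa_of_group, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            rsau = np.where(denom > 0, n_i[None, :, None] * S / denom, np.nan)
        return _mean_cv(rsau)
    raise ValueError(f"unknown statistic {statistic!r}")


def mean_cv_statistic(
    rpm: ExpressionMatrix,
    records: list[IsodecoderRecord],
    statistic: str,
    include_specials: bool = False,
) -> float:
    """Observed mean-CV statistic on the true anticodon labels."""
    if rpm.values.shape[1] < 2:
        raise ValueError("CV statistics require at least 2 samples")
    X, codes, G, aa_of_group, A = _setup(rpm, records, include_specials)
    value = _batch_statistic(X, codes[None, :], G, aa_of_group, A, statistic)[0]
    if np.isnan(value):
        raise ValueError("no groups with a defined CV")
    return float(value)


def permutation_test(
    rpm: ExpressionMatrix,
    records: list[IsodecoderRecord],
    statistic: str,
    tail: str,
    n_perm: int = 10000,
    seed: int = 0,
    include_specials: bool = False,
    continuity_correction: bool = False,
) -> PermutationResult:
    """Empirical test of an observed mean-CV against anticodon permutations."""
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}; choose from {TAILS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, codes, G, aa_of_group, A = _setup(rpm, records, include_specials)
    observed = float(_batch_statistic(X, codes[None, :], G, aa_of_group, A, statistic)[0])
    if np.isnan(observed):
        raise ValueError("no groups with a defined CV")

    rng = np.random.default_rng(seed)
    n = len(codes)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, 2_000_000 // max(1, G * X.shape[1])))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perm_idx = np.array([rng.permutation(n) for _ in range(size)])
        codes2d = codes[perm_idx]
        null[done : done + size] = _batch_statistic(
            X, codes2d, G, aa_of_group, A, statistic
        )
        done += size

    if tail == "greater":
        b = int((null > observed).sum())
    else:
        b = int((null < observed).sum())
    p = (b + 1) / (n_perm + 1) if continuity_correction else b / n_perm
    degenerate = bool(np.all(np.isclose(null, observed)))
    return PermutationResult(
        statistic=statistic,
        observed=observed,
        null=null,
        tail=tail,
        p=float(p),
        n_perm=n_perm,
        seed=seed,
        degenerate=degenerate,
    )
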