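"""Translational efficiency (TE) and gene stratification.

TE is the ratio of ribosome-bound (IP) FPKM to input FPKM from a paired
RiboTag-style experiment. Genes are retained only when both FPKMs exceed a
floor (default: strictly greater than 1), which removes ratio instability at
low expression. Filtered genes per tissue are then ranked by TE and split
into highly / moderately / lowly translated genes (HTG / MTG / LTG): the top,
median-centered, and bottom 5% respectively.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "sample", "input_fpkm", "ip_fpkm")


def compute_te(table: pd.DataFrame, min_fpkm: float = 1.0) -> pd.DataFrame:
    """Add a ``te`` column (= ip/input) where both FPKMs pass the filter.

    The filter is strict: a gene/sample needs input_fpkm > min_fpkm AND
    ip_fpkm > min_fpkm; otherwise te is NaN (missing). Rows with IP but no
    input measurement are an inconsistency and raise.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"translatome table lacks column {col!r}")
    out = table.copy()
    orphan = out["input_fpkm"].isna() & out["ip_fpkm"].notna()
    if orphan.any():
        raise ValueError(
            f"genes with IP but no input FPKM: {sorted(out.loc[orphan, 'gene'].unique())}"
        )
    ok = (out["input_fpkm"] > min_fpkm) & (out["ip_fpkm"] > min_fpkm)
    out["te"] = np.where(ok, out["ip_fpkm"] / out["input_fpkm"], np.nan)
    return out


def tissue_mean_te(
    te_table: pd.DataFrame, sample_tissue: Mapping[str, str]
) -> dict[str, pd.Series]:
    """Per-tissue gene TE, averaging replicate TEs; NaN-filtered genes drop.

    A gene keeps a tissue TE only if it passed the FPKM filter in every
    replicate of that tissue.
    """
    t = te_table.copy()
    t["tissue"] = t["sample"].map(dict(sample_tissue))
    if t["tissue"].isna().any():
        bad = sorted(t.loc[t["tissue"].isna(), "sample"].unique())
        raise ValueError(f"samples without tissue label: {bad}")
    out: dict[str, pd.Series] = {}
    for tissue, grp in t.groupby("tissue"):
        wide = grp.pivot(index="gene", columns="sample", values="te")
        mean = wide.mean(axis=1)
        out[str(tissue)] = mean[wide.notna().all(axis=1)]
    return out


@dataclass
class TEStrata:
    """HTG/MTG/LTG gene sets for one tissue (top/medium/bottom fraction)."""

    tissue: str
    htg: tuple[str, ...]
    mtg: tuple[str, ...]
    ltg: tuple[str, ...]
    fraction: float = 0.05

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (self.tissue, stratum, g)
            for stratum, genes in (("HTG", self.htg), ("MTG", self.mtg), ("LTG", self.ltg))
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["tissue", "stratum", "gene"])


def stratify_te(
    te: pd.Series, fraction: float = 0.05, tissue: str = ""
) -> TEStrata:
    """Split genes into top / median-centered / bottom ``fraction`` by TE.

    Ties are broken by gene id so the strata are deterministic. MTG is the
    window of k genes centered on the median rank of the TE ordering.
    """
    te = te.dropna()
    n = len(te)
    k = math.ceil(fraction * n)
    if k < 1 or 3 * k > n:
        raise ValueError(
            f"too few genes ({n}) for three disjoint strata of fraction {fraction}"
        )
    order = sorted(te.index, key=lambda g: (te[g], g))  # ascending TE
    start = (n - k) // 2
    return TEStrata(
        tissue=tissue,
        htg=tuple(order[-k:]),
        mtg=tuple(order[start : start + k]),
        ltg=tuple(order[:k]),
        fraction=fraction,
    )


def select_longest_cds(
    isoforms_by_gene: Mapping[str, Mapping[str, str]]
) -> dict[str, str]:
    """Pick the longest valid CDS per gene (ties by isoform id).

    A valid CDS is non-empty with length divisible by 3; genes with none are
    excluded with a warning.
    """
    chosen: dict[str, str] = {}
    skipped: list[str] = []
    for gene, isoforms in isoforms_by_gene.items():
        valid = {
            iid: seq
            for iid, seq in isoforms.items()
            if seq and len(seq) % 3 == 0
        }
        if not valid:
            skipped.append(gene)
            continue
        best = min(valid, key=lambda iid: (-len(valid[iid]), iid))
        chosen[gene] = valid[best]
    if skipped:
        warnings.warn(f"genes with no valid CDS excluded: {sorted(skipped)}", stacklevel=2)
    return chosen


def read_fpkm_tsv(path) -> pd.DataFrame:
    """Read a long-format FPKM table (gene, sample, input_fpkm, ip_fpkm)."""
    table = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"FPKM table {path} lacks column {col!r}")
    return table
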