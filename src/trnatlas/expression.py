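"""Expression matrices: RPM normalization, aggregation, CV/Z summaries.

Counts are normalized to reads per million mapped reads (RPM). Because RPM is
compositional, the denominator matters: the default uses all mapped tRNA
reads (cytosolic + mitochondrial); a ct-only mode renormalizes over cytosolic
features, which is what the tissue analyses use after setting the
mitochondrial block aside.

Dispersion across samples is summarized by the coefficient of variation
(CV = sd/mean, sample sd with the n-1 denominator) and by per-feature
Z-scores; features whose statistic is undefined (zero mean, zero sd) are
flagged missing (NaN) rather than silently set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inventory import CYTOSOLIC, GroupingMap, IsodecoderRecord

ISODECODER = "isodecoder"
ISOACCEPTOR = "isoacceptor"
ISOTYPE = "isotype"


@dataclass
class ExpressionMatrix:
    """features x samples values with per-sample tissue metadata.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; ``sample_tissue`` maps sample id -> tissue label; ``level`` tags
    the feature resolution (isodecoder / isoacceptor / isotype).
    """

    values: pd.DataFrame
    sample_tissue: pd.Series
    level: str = ISODECODER
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.sample_tissue.index)
        if missing:
            raise ValueError(f"samples without a tissue label: {sorted(missing)}")
        self.sample_tissue = self.sample_tissue.loc[list(self.values.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def tissue_means(self) -> "ExpressionMatrix":
        """Average replicates within each tissue (columns become tissues)."""
        means = self.values.T.groupby(self.sample_tissue).mean().T
        tissues = pd.Series(means.columns, index=means.columns)
        return ExpressionMatrix(means, tissues, level=self.level, unit=self.unit)


def compute_rpm(
    counts: ExpressionMatrix,
    records: list[IsodecoderRecord] | None = None,
    denominator: str = "all_mapped",
) -> ExpressionMatrix:
    """Normalize counts to reads-per-million of the chosen denominator.

    ``all_mapped`` divides by each sample's total over all features (ct+mt);
    ``ct_only`` renormalizes over cytosolic features only (``records`` must
    then supply compartments). Per-sample RPM sums to 1e6 over the features in
    the denominator.
    """
    vals = counts.values
    if denominator == "all_mapped":
        totals = vals.sum(axis=0)
    elif denominator == "ct_only":
        if records is None:
            raise ValueError("ct_only denominator requires isodecoder records")
        comp = {r.id: r.compartment for r in records}
        unlabeled = [f for f in vals.index if f not in comp]
        if unlabeled:
            raise ValueError(f"features without compartment label: {unlabeled}")
        ct = [f for f in vals.index if comp[f] == CYTOSOLIC]
        totals = vals.loc[ct].sum(axis=0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    rpm = vals * (1e6 / totals)
    return ExpressionMatrix(rpm, counts.sample_tissue, level=counts.level, unit="rpm")


def compartment_fraction(
    matrix: ExpressionMatrix, records: list[IsodecoderRecord]
) -> pd.DataFrame:
    """Per-sample fraction of expression from each compartment (ct, mt)."""
    comp = {r.id: r.compartment for r in records}
    unlabeled = [f for f in matrix.features if f not in comp]
    if unlabeled:
        raise ValueError(f"features without compartment label: {unlabeled}")
    labels = pd.Series([comp[f] for f in matrix.features], index=matrix.values.index)
    sums = matrix.values.groupby(labels).sum()
    frac = (sums / sums.sum(axis=0)).T
    for col in (CYTOSOLIC, "mitochondrial"):
        if col not in frac.columns:
            frac[col] = 0.0
    return frac[[CYTOSOLIC, "mitochondrial"]]


def aggregate_expression(
    matrix: ExpressionMatrix, grouping: GroupingMap, level: str
) -> ExpressionMatrix:
    """Sum isodecoder values into isoacceptor or isotype groups."""
    mapping = grouping._mapping(level)
    missing = [f for f in matrix.features if f not in mapping]
    if missing:
        raise ValueError(f"features absent from grouping: {missing}")
    keys = pd.Series(
        ["-".join(mapping[f]) if isinstance(mapping[f], tuple) else mapping[f]
         for f in matrix.features],
        index=matrix.values.index,
    )
    agg = matrix.values.groupby(keys).sum()
    return ExpressionMatrix(agg, matrix.sample_tissue, level=level, unit=matrix.unit)


def feature_cv(matrix: ExpressionMatrix, tissue_mean: bool = False) -> pd.Series:
    """Coefficient of variation per feature across samples (sd/mean, ddof=1).

    ``tissue_mean=True`` first averages replicates within tissues, so the CV
    measures between-tissue variation only. Features with zero mean are NaN.
    """
    m = matrix.tissue_means() if tissue_mean else matrix
    if m.values.shape[1] < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean <= 0] = np.nan
    cv.name = "cv"
    return cv


def feature_zscore(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature Z-score across samples; constant features are NaN."""
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    z = matrix.values.sub(mean, axis=0).div(sd, axis=0)
    z[sd == 0] = np.nan
    return z


def sample_correlation(
    matrix: ExpressionMatrix, transform: str = "log2p1"
) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples.

    Expression spans orders of magnitude, so the default correlates
    log2(RPM+1); ``raw`` correlates untransformed values.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("sample correlation requires at least 2 features")
    if transform == "log2p1":
        vals = np.log2(matrix.values + 1.0)
    elif transform == "raw":
        vals = matrix.values
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return vals.corr(method="pearson")


def read_counts_tsv(counts_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a feature x sample count table plus its sample sheet."""
    vals = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for col in ("sample", "tissue"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet {sample_sheet_path} lacks column {col!r}")
    tissue = sheet.set_index("sample")["tissue"]
    missing = set(vals.columns) - set(tissue.index)
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
    return ExpressionMatrix(vals, tissue)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.10g")
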