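"""End-to-end pipeline: configuration, stage wiring, reproducible outputs.

A single YAML config names either real input files (tRNA FASTAs, count
table, sample sheet, CDS FASTA, FPKM table) or a ``simulate`` block that
generates them, plus the analysis parameters (RPM denominator, FPKM floor,
TE strata fraction, permutation count, seed). ``run_pipeline`` executes the
stages in dependency order and writes plain TSV/JSON results plus a manifest
recording the config hash and the SHA-256 of every output, so a rerun with
the same config is byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adaptation import build_pairing_rules, codon_adaptiveness, genes_tai
from .association import aa_coupling, pair_correlation_categories, tai_te_analysis
from .expression import (
    ExpressionMatrix,
    aggregate_expression,
    compartment_fraction,
    compute_rpm,
    feature_cv,
    read_counts_tsv,
    sample_correlation,
)
from .inventory import (
    CYTOSOLIC,
    build_grouping,
    load_reference,
    write_collapsed_fasta,
    write_grouping_tsv,
)
from .permutation import permutation_test
from .simulate import (
    SimTruth,
    TrnaSimConfig,
    simulate_coding_genes,
    simulate_translatome,
    simulate_trna_counts,
    write_cds_fasta,
    write_fpkm_tsv,
    write_sample_sheet,
)
from .translatome import (
    compute_te,
    read_fpkm_tsv,
    select_longest_cds,
    stratify_te,
    tissue_mean_te,
)
from .usage import (
    amino_acid_composition,
    codon_index,
    count_codons_table,
    rsau,
    rsiu,
    usage_long_table,
    weighted_rscu,
)

log = logging.getLogger("trnatlas")

#: tail direction of each permutation statistic, as the analysis asks it
PERMUTATION_TAILS = {
    "isoacceptor_expression_cv": "greater",
    "rsau_cv": "smaller",
    "isotype_expression_cv": "greater",
}


@dataclass
class PipelineConfig:
    seed: int
    simulate: dict | None = None
    inputs: dict | None = None
    min_fpkm: float = 1.0
    top_fraction: float = 0.05
    n_perm: int = 1000
    rpm_denominator: str = "all_mapped"
    transform: str = "log2p1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ValueError(f"config {path} must be a mapping with a 'seed' key")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if (cfg.simulate is None) == (cfg.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def read_cds_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a CDS FASTA into gene -> {isoform id -> sequence}.

    Headers are gene ids, optionally ``gene|isoform`` when several coding
    isoforms are present; the longest per gene is selected downstream.
    """
    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for sr in SeqIO.parse(str(path), "fasta"):
        gene, _, isoform = sr.id.partition("|")
        out.setdefault(gene, {})[isoform or gene] = str(sr.seq).upper()
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def _acquire_inputs(config: PipelineConfig, outdir: Path):
    """Load or simulate the four pipeline inputs; simulated ones are written."""
    if config.inputs is not None:
        paths = config.inputs
        for key in ("ct_fasta", "counts", "sample_sheet", "cds_fasta", "fpkm"):
            if key not in paths:
                raise ValueError(f"inputs block lacks {key!r}")
        records = load_reference(paths["ct_fasta"], paths.get("mt_fasta"))
        counts = read_counts_tsv(paths["counts"], paths["sample_sheet"])
        isoforms = read_cds_fasta(paths["cds_fasta"])
        cds_by_gene = select_longest_cds(isoforms)
        fpkm = read_fpkm_tsv(paths["fpkm"])
        return records, counts, cds_by_gene, fpkm

    sim = dict(config.simulate or {})
    n_genes = int(sim.pop("n_genes", 300))
    coupling = float(sim.pop("coupling_strength", 1.0))
    noise_sd = float(sim.pop("te_noise_sd", 0.5))
    cds_length = tuple(sim.pop("cds_length_codons", (100, 300)))
    trna_cfg = TrnaSimConfig(seed=config.seed, **sim)
    counts, records, _ = simulate_trna_counts(trna_cfg)
    cds_by_gene, codon_counts, _ = simulate_coding_genes(
        n_genes, cds_length_codons=cds_length, seed=config.seed + 1
    )
    rpm_ct = compute_rpm(counts, records, denominator="ct_only")
    pools = _anticodon_pools(rpm_ct, records)
    fpkm, _ = simulate_translatome(
        codon_counts, pools, coupling, seed=config.seed + 2, noise_sd=noise_sd
    )
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    counts.values.to_csv(inputs_dir / "trna_counts.tsv", sep="\t")
    write_sample_sheet(counts.sample_tissue, inputs_dir / "sample_sheet.tsv")
    write_cds_fasta(cds_by_gene, inputs_dir / "cds.fasta")
    write_fpkm_tsv(fpkm, inputs_dir / "fpkm.tsv")
    return records, counts, cds_by_gene, fpkm


def _anticodon_pools(
    rpm_ct: ExpressionMatrix, records
) -> dict[str, pd.Series]:
    """Tissue-mean anticodon-level RPM pools (ct, standard groups only)."""
    by_id = {r.id: r for r in records}
    ids = [
        f for f in rpm_ct.features
        if f in by_id and by_id[f].compartment == CYTOSOLIC and not by_id[f].is_special
    ]
    anticodons = pd.Series({f: by_id[f].anticodon for f in ids})
    summed = rpm_ct.values.loc[ids].groupby(anticodons).sum()
    means = summed.T.groupby(rpm_ct.sample_tissue).mean().T
    return {str(t): means[t] for t in means.columns}


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write results + manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, counts, cds_by_gene, fpkm = _acquire_inputs(config, outdir)
    grouping = build_grouping(records)
    write_grouping_tsv(records, outdir / "grouping.tsv")
    write_collapsed_fasta(records, outdir / "collapsed_reference.fasta")

    # --- expression: RPM, compartments, aggregation, summaries -------------
    rpm_all = compute_rpm(counts, records, denominator=config.rpm_denominator)
    frac = compartment_fraction(rpm_all, records)
    _write_tsv(frac.rename_axis("sample"), outdir / "compartment_fractions.tsv")
    log.info("compartment fractions written for %d samples", len(frac))

    rpm_ct = compute_rpm(counts, records, denominator="ct_only")
    ct_ids = [r.id for r in records if r.compartment == CYTOSOLIC]
    rpm_ct = ExpressionMatrix(
        rpm_ct.values.loc[[f for f in rpm_ct.features if f in set(ct_ids)]],
        rpm_ct.sample_tissue, level="isodecoder", unit="rpm",
    )
    iso_acc = aggregate_expression(rpm_ct, grouping, "isoacceptor")
    iso_typ = aggregate_expression(rpm_ct, grouping, "isotype")
    _write_tsv(rpm_ct.values.rename_axis("isodecoder"), outdir / "rpm_isodecoder.tsv")
    _write_tsv(iso_acc.values.rename_axis("isoacceptor"), outdir / "rpm_isoacceptor.tsv")
    _write_tsv(iso_typ.values.rename_axis("isotype"), outdir / "rpm_isotype.tsv")
    _write_tsv(
        sample_correlation(rpm_ct, config.transform).rename_axis("sample"),
        outdir / "sample_correlation.tsv",
    )
    cv = pd.concat(
        [
            feature_cv(m).rename_axis("feature").reset_index().assign(level=lvl)
            for m, lvl in ((rpm_ct, "isodecoder"), (iso_acc, "isoacceptor"),
                           (iso_typ, "isotype"))
        ]
    )
    _write_tsv(cv[["level", "feature", "cv"]], outdir / "expression_cv.tsv", index=False)

    # --- usage bias: RSIU / RSAU per sample --------------------------------
    rsiu_vals = rsiu(rpm_ct.values, grouping)
    _write_tsv(usage_long_table(rsiu_vals, "rsiu", "isodecoder"),
               outdir / "rsiu.tsv", index=False)
    key_of = {"-".join(k): k[0] for k in set(grouping.isoacceptor_of.values())}
    rsau_vals = rsau(iso_acc.values, key_of)
    _write_tsv(usage_long_table(rsau_vals, "rsau", "isoacceptor"),
               outdir / "rsau.tsv", index=False)

    # --- translatome: TE, strata -------------------------------------------
    te_table = compute_te(fpkm, min_fpkm=config.min_fpkm)
    n_pass = int(te_table["te"].notna().sum())
    log.info("TE filter: %d/%d gene-sample rows pass FPKM > %s",
             n_pass, len(te_table), config.min_fpkm)
    _write_tsv(te_table, outdir / "te.tsv", index=False)
    tissue_te = tissue_mean_te(te_table, counts.sample_tissue.to_dict())
    strata = {
        t: stratify_te(s, fraction=config.top_fraction, tissue=t)
        for t, s in sorted(tissue_te.items())
    }
    _write_tsv(
        pd.concat([st.as_frame() for st in strata.values()]),
        outdir / "te_strata.tsv", index=False,
    )

    # --- codon-usage metrics on the HTGs -----------------------------------
    codon_counts = count_codons_table(cds_by_gene)
    ip_by_sample = te_table.pivot(index="gene", columns="sample", values="ip_fpkm")
    metric_rows = []
    for tissue, st in strata.items():
        genes = [g for g in st.htg if g in codon_counts.index]
        for sample in [s for s in counts.samples if counts.sample_tissue[s] == tissue]:
            w = ip_by_sample[sample].reindex(genes).fillna(0.0)
            ci = codon_index(codon_counts, w, genes)
            rscu = weighted_rscu(codon_counts, w, genes)
            comp = amino_acid_composition(codon_counts, w, genes, normalize=True)
            for metric, series in (("codon_index", ci), ("weighted_rscu", rscu),
                                   ("aa_composition", comp)):
                for key, value in series.items():
                    metric_rows.append((tissue, sample, metric, key, value))
    _write_tsv(
        pd.DataFrame(metric_rows,
                     columns=["tissue", "sample", "metric", "key", "value"]),
        outdir / "usage_metrics.tsv", index=False,
    )

    # --- tAI under each tissue pool ----------------------------------------
    rules = build_pairing_rules(eukaryote=True)
    pools = _anticodon_pools(rpm_ct, records)
    tai_by_pool = pd.DataFrame(index=codon_counts.index, dtype=float)
    for tissue, pool in pools.items():
        w = codon_adaptiveness(pool, rules)["w"]
        tai_by_pool[tissue] = genes_tai(codon_counts, w)
    _write_tsv(tai_by_pool.rename_axis("gene"), outdir / "tai.tsv")
    within, matrix, cross = tai_te_analysis(tai_by_pool, strata)
    _write_tsv(matrix, outdir / "tai_htg_matrix.tsv")

    # --- permutation tests --------------------------------------------------
    perm_results = {}
    for statistic, tail in PERMUTATION_TAILS.items():
        res = permutation_test(
            rpm_ct, records, statistic, tail,
            n_perm=config.n_perm, seed=config.seed,
        )
        perm_results[statistic] = {
            "observed": res.observed, "p": res.p, "tail": res.tail,
            "n_perm": res.n_perm, "degenerate": res.degenerate,
        }
    (outdir / "permutation.json").write_text(
        json.dumps(perm_results, indent=2, sort_keys=True) + "\n"
    )

    # --- associations --------------------------------------------------------
    pairs, pair_cmp = pair_correlation_categories(rpm_ct, records, config.transform)
    _write_tsv(pairs, outdir / "pair_correlations.tsv", index=False)
    comp_rows = {}
    for tissue, st in strata.items():
        genes = [g for g in st.htg if g in codon_counts.index]
        w = (ip_by_sample[[s for s in counts.samples
                           if counts.sample_tissue[s] == tissue]]
             .mean(axis=1).reindex(genes).fillna(0.0))
        comp_rows[tissue] = amino_acid_composition(codon_counts, w, genes)
    compositions = pd.DataFrame(comp_rows).T
    isotype_expr = iso_typ.tissue_means().values.T
    coupling_within = aa_coupling(compositions, isotype_expr, "within_tissue")
    coupling_across = aa_coupling(compositions, isotype_expr, "across_tissue")
    _write_tsv(
        pd.concat([coupling_within.assign(mode="within_tissue"),
                   coupling_across.assign(mode="across_tissue")]),
        outdir / "aa_coupling.tsv", index=False,
    )

    tests_summary = {
        "pair_categories": [vars(c) for c in pair_cmp],
        "tai_te_within": [vars(c) for c in within],
        "tai_te_cross": [vars(c) for c in cross],
        "seed": config.seed,
        "n_samples": len(counts.samples),
    }
    (outdir / "comparisons.json").write_text(
        json.dumps(tests_summary, indent=2, sort_keys=True) + "\n"
    )

    # --- manifest ------------------------------------------------------------
    outputs = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": config.digest(),
        "config": json.loads(config.canonical_json()),
        "seed": config.seed,
        "version": __version__,
        "outputs": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in outputs
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
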