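"""Synthetic data with the statistical structure the analyses assume.

No public tRNA-seq/RiboTag count data ship with the package, so every
downstream stage is exercised on simulated inputs with known ground truth.
Three generators mirror the three data types of a paired tRNA-pool /
translatome study of a few tissues with biological replicates:

* tRNA counts — a hierarchical log-normal / negative-binomial model. Each
  isodecoder has a baseline log-abundance; each tissue perturbs it with
  independent Gaussian effects injected at three levels: amino acid
  (sigma_aa), anticodon (sigma_ac), and isodecoder (sigma_iso). These are
  exactly the three co-regulation strata the pair-correlation and
  permutation analyses probe. Effects act on a softmax composition (RPM is
  compositional), scaled to a library size, and counts are drawn
  negative-binomially. Mitochondrial tRNAs form a separate block with a
  per-tissue read fraction, mimicking the large mt-tRNA content differences
  between energetic tissues.
* coding genes — CDS sequences with controllable synonymous-codon bias:
  start codon, sense codons drawn from per-amino-acid profiles, stop codon.
* translatome — input/IP FPKM tables in which log TE is a controllable
  linear function of the gene's (pool-standardized) tAI plus noise, so the
  coupling between codon adaptation and translational efficiency can be
  switched on (coupling 1) or off (coupling 0).

Defaults emulate the three-tissue (brain, heart, testis), two-replicate
design with an inventory of roughly 47 standard isoacceptors, 4 special
groups, and ~220 cytosolic isodecoders. All generators are deterministic
given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import PairingRules, build_pairing_rules, codon_adaptiveness, genes_tai
from .expression import ExpressionMatrix
from .genetic_code import (
    AMINO_ACIDS,
    SENSE_ANTICODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    reverse_complement,
)
from .inventory import CYTOSOLIC, MITOCHONDRIAL, IsodecoderRecord

#: anticodons available per amino acid (reverse complements of the codons)
_ANTICODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(reverse_complement(c) for c in codons))
    for aa, codons in SYNONYMOUS_FAMILIES.items()
}

_SPECIALS: tuple[tuple[str, str], ...] = (
    ("iMet", "CAT"),
    ("SeC", "TCA"),
    ("Sup", "TTA"),
    ("Sup", "TCA"),
)

DEFAULT_TISSUES = ("brain", "heart", "testis")
# mt-tRNA read fractions observed in those tissues, in order
DEFAULT_MT_FRACTIONS = (0.389, 0.644, 0.111)


@dataclass
class TrnaSimConfig:
    """Knobs of the tRNA count simulator (log-scale effect sds)."""

    seed: int
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 2
    n_amino_acids: int = 20
    anticodons_per_aa: tuple[int, int] = (1, 4)
    isodecoders_per_anticodon: tuple[int, int] = (1, 9)
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    sigma_aa: float = 0.3
    sigma_ac: float = 0.1
    sigma_iso: float = 0.3
    dispersion: float = 0.05
    library_size: int = 1_000_000
    mt_fractions: tuple[float, ...] = DEFAULT_MT_FRACTIONS
    n_mt: int = 22
    include_specials: bool = True

    def __post_init__(self) -> None:
        if min(self.sigma_aa, self.sigma_ac, self.sigma_iso) < 0:
            raise ValueError("effect sds must be non-negative")
        if self.replicates_per_tissue < 1:
            raise ValueError("need at least one replicate per tissue")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 1 <= self.n_amino_acids <= len(AMINO_ACIDS):
            raise ValueError(f"n_amino_acids must be in [1, {len(AMINO_ACIDS)}]")
        if len(self.mt_fractions) != len(self.tissues):
            raise ValueError("one mt fraction per tissue required")
        if any(not 0 <= f < 1 for f in self.mt_fractions):
            raise ValueError("mt fractions must be in [0, 1)")
        for lo, hi in (self.anticodons_per_aa, self.isodecoders_per_anticodon):
            if lo < 1 or hi < lo:
                raise ValueError("count ranges must satisfy 1 <= lo <= hi")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    baseline: pd.Series | None = None
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)
    proportions: pd.DataFrame | None = None
    class_of_gene: pd.Series | None = None
    profiles: dict | None = None
    true_te: pd.DataFrame | None = None
    htg: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def ser(obj):
            if isinstance(obj, pd.Series):
                return obj.to_dict()
            if isinstance(obj, pd.DataFrame):
                return {str(c): obj[c].to_dict() for c in obj.columns}
            return obj

        payload = {
            "baseline": ser(self.baseline),
            "effects": {k: ser(v) for k, v in self.effects.items()},
            "proportions": ser(self.proportions),
            "class_of_gene": ser(self.class_of_gene),
            "profiles": {k: {c: float(x) for c, x in v.items()}
                         for k, v in (self.profiles or {}).items()} or None,
            "true_te": ser(self.true_te),
            "htg": {k: list(v) for k, v in self.htg.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _random_sequences(rng: np.random.Generator, n: int, length: int = 72) -> list[str]:
    """Distinct random tRNA-length sequences."""
    alphabet = np.array(list("ACGT"))
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(alphabet, size=length))
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def _build_inventory(config: TrnaSimConfig, rng: np.random.Generator):
    """Draw the isodecoder inventory: who exists, at which grouping keys."""
    records: list[IsodecoderRecord] = []
    aas = list(AMINO_ACIDS[: config.n_amino_acids])
    lo_ac, hi_ac = config.anticodons_per_aa
    lo_iso, hi_iso = config.isodecoders_per_anticodon
    for aa in aas:
        avail = _ANTICODONS_BY_AA[aa]
        k = min(int(rng.integers(lo_ac, hi_ac + 1)), len(avail))
        chosen = sorted(rng.choice(len(avail), size=k, replace=False))
        for ai in chosen:
            anticodon = avail[ai]
            m = int(rng.integers(lo_iso, hi_iso + 1))
            for j in range(m):
                records.append(
                    IsodecoderRecord(
                        id=f"{aa}-{anticodon}-{j + 1}-1",
                        member_names=[f"{aa}-{anticodon}-{j + 1}-1"],
                        sequence="",
                        isotype=aa,
                        anticodon=anticodon,
                        compartment=CYTOSOLIC,
                    )
                )
    if config.include_specials:
        for isotype, anticodon in _SPECIALS:
            records.append(
                IsodecoderRecord(
                    id=f"{isotype}-{anticodon}-1-1",
                    member_names=[f"{isotype}-{anticodon}-1-1"],
                    sequence="",
                    isotype=isotype,
                    anticodon=anticodon,
                    compartment=CYTOSOLIC,
                )
            )
    mt_pool = [ac for ac in SENSE_ANTICODONS]
    for j in range(config.n_mt):
        anticodon = mt_pool[int(rng.integers(0, len(mt_pool)))]
        from .genetic_code import ANTICODON_TO_AA

        records.append(
            IsodecoderRecord(
                id=f"mt-{ANTICODON_TO_AA[anticodon]}-{anticodon}-{j + 1}",
                member_names=[f"mt-{ANTICODON_TO_AA[anticodon]}-{anticodon}-{j + 1}"],
                sequence="",
                isotype=ANTICODON_TO_AA[anticodon],
                anticodon=anticodon,
                compartment=MITOCHONDRIAL,
            )
        )
    for rec, seq in zip(records, _random_sequences(rng, len(records))):
        rec.sequence = seq
    return records


def simulate_trna_counts(
    config: TrnaSimConfig,
) -> tuple[ExpressionMatrix, list[IsodecoderRecord], SimTruth]:
    """Simulate an isodecoder x sample count matrix with known structure.

    Counts for isodecoder d in a sample of tissue t are negative binomial
    with mean library_size * block_fraction * softmax_d(base_d + a_{AA(d),t}
    + b_{ac(d),t} + g_{d,t}), where a, b, g are Normal(0, sigma) tissue
    effects at the amino-acid, anticodon, and isodecoder level. Replicates
    of a tissue share the tissue effects and differ only by counting noise.
    """
    rng = np.random.default_rng(config.seed)
    records = _build_inventory(config, rng)
    if not records:
        raise ValueError("configuration produced an empty inventory")
    ids = [r.id for r in records]
    ct_mask = np.array([r.compartment == CYTOSOLIC for r in records])
    aa_keys = [r.isotype for r in records]
    ac_keys = [f"{r.isotype}-{r.anticodon}" for r in records]

    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(records))

    tissues = list(config.tissues)
    uniq_aa = sorted(set(aa_keys))
    uniq_ac = sorted(set(ac_keys))
    a_eff = pd.DataFrame(
        rng.normal(0.0, config.sigma_aa, (len(uniq_aa), len(tissues))) if config.sigma_aa > 0
        else np.zeros((len(uniq_aa), len(tissues))),
        index=uniq_aa, columns=tissues,
    )
    b_eff = pd.DataFrame(
        rng.normal(0.0, config.sigma_ac, (len(uniq_ac), len(tissues))) if config.sigma_ac > 0
        else np.zeros((len(uniq_ac), len(tissues))),
        index=uniq_ac, columns=tissues,
    )
    g_eff = pd.DataFrame(
        rng.normal(0.0, config.sigma_iso, (len(ids), len(tissues))) if config.sigma_iso > 0
        else np.zeros((len(ids), len(tissues))),
        index=ids, columns=tissues,
    )

    prop = pd.DataFrame(index=ids, columns=tissues, dtype=float)
    means = {}
    for ti, tissue in enumerate(tissues):
        log_abund = (
            base
            + a_eff.loc[aa_keys, tissue].to_numpy()
            + b_eff.loc[ac_keys, tissue].to_numpy()
            + g_eff.loc[ids, tissue].to_numpy()
        )
        mean_t = np.empty(len(ids))
        for mask, frac in (
            (ct_mask, 1.0 - config.mt_fractions[ti]),
            (~ct_mask, config.mt_fractions[ti]),
        ):
            if mask.any():
                e = np.exp(log_abund[mask] - log_abund[mask].max())
                mean_t[mask] = config.library_size * frac * e / e.sum()
        prop[tissue] = mean_t / config.library_size
        means[tissue] = mean_t

    samples, sample_tissue, columns = [], {}, []
    for tissue in tissues:
        for rep in range(1, config.replicates_per_tissue + 1):
            sample = f"{tissue}_rep{rep}"
            mean_t = means[tissue]
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, mean_t * config.dispersion)
            else:
                lam = mean_t
            columns.append(rng.poisson(lam))
            samples.append(sample)
            sample_tissue[sample] = tissue

    counts = pd.DataFrame(
        np.column_stack(columns), index=ids, columns=samples, dtype=int
    )
    em = ExpressionMatrix(counts, pd.Series(sample_tissue), level="isodecoder")
    truth = SimTruth(
        baseline=pd.Series(base, index=ids),
        effects={"aa": a_eff, "anticodon": b_eff, "isodecoder": g_eff},
        proportions=prop,
    )
    return em, records, truth


def uniform_profiles() -> dict[str, pd.Series]:
    """Per-amino-acid uniform synonymous-codon probability profiles."""
    return {
        aa: pd.Series(1.0 / len(codons), index=list(codons))
        for aa, codons in SYNONYMOUS_FAMILIES.items()
    }


def dirichlet_profiles(
    rng: np.random.Generator, concentration: float = 1.0
) -> dict[str, pd.Series]:
    """Random synonymous-codon profiles (smaller concentration = more bias)."""
    return {
        aa: pd.Series(rng.dirichlet([concentration] * len(codons)), index=list(codons))
        for aa, codons in SYNONYMOUS_FAMILIES.items()
    }


def _check_profiles(profiles: dict[str, pd.Series]) -> None:
    for aa, prof in profiles.items():
        if abs(float(prof.sum()) - 1.0) > 1e-9:
            raise ValueError(f"codon profile for {aa} does not sum to 1")
        if (prof < 0).any():
            raise ValueError(f"codon profile for {aa} has negative entries")
        if set(prof.index) != set(SYNONYMOUS_FAMILIES[aa]):
            raise ValueError(f"codon profile for {aa} does not cover its family")


def simulate_coding_genes(
    n_genes: int,
    cds_length_codons: tuple[int, int] = (150, 600),
    profiles: dict[str, pd.Series] | None = None,
    seed: int = 0,
    aa_frequencies: pd.Series | None = None,
) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Simulate CDS sequences with controlled synonymous-codon bias.

    Each CDS is ATG + (L - 2) sense codons + one stop codon, L drawn
    uniformly from ``cds_length_codons``. Amino acids are drawn iid from
    ``aa_frequencies`` (uniform by default) and codons from the per-amino-
    acid ``profiles`` (uniform by default). Returns (gene -> CDS, genes x 64
    codon count table, truth carrying the profiles).
    """
    from .usage import ALL_CODONS, count_codons_table

    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = uniform_profiles()
    _check_profiles(profiles)
    aas = list(AMINO_ACIDS)
    if aa_frequencies is None:
        aa_p = np.full(len(aas), 1.0 / len(aas))
    else:
        aa_p = aa_frequencies.reindex(aas).fillna(0.0).to_numpy(dtype=float)
        if abs(aa_p.sum() - 1.0) > 1e-9:
            raise ValueError("aa_frequencies must sum to 1")
    lo, hi = cds_length_codons
    if n_genes and (lo < 3 or hi < lo):
        raise ValueError("cds_length_codons must satisfy 3 <= lo <= hi")

    codons_by_aa = {aa: list(prof.index) for aa, prof in profiles.items()}
    p_by_aa = {aa: prof.to_numpy(dtype=float) for aa, prof in profiles.items()}
    stops = list(STOP_CODONS)

    cds_by_gene: dict[str, str] = {}
    width = max(4, len(str(max(n_genes, 1))))
    for gi in range(n_genes):
        L = int(rng.integers(lo, hi + 1))
        aa_seq = rng.choice(len(aas), size=L - 2, p=aa_p)
        codons = np.empty(L - 2, dtype=object)
        for ai in np.unique(aa_seq):
            aa = aas[ai]
            where = aa_seq == ai
            picks = rng.choice(len(codons_by_aa[aa]), size=int(where.sum()),
                               p=p_by_aa[aa])
            codons[where] = [codons_by_aa[aa][k] for k in picks]
        cds = "ATG" + "".join(codons) + stops[int(rng.integers(0, len(stops)))]
        cds_by_gene[f"gene{gi + 1:0{width}d}"] = cds

    table = (
        count_codons_table(cds_by_gene)
        if cds_by_gene
        else pd.DataFrame(columns=list(ALL_CODONS), dtype=int)
    )
    truth = SimTruth(profiles={aa: prof.to_dict() for aa, prof in profiles.items()})
    return cds_by_gene, table, truth


def simulate_translatome(
    codon_counts: pd.DataFrame,
    trna_pools: dict[str, pd.Series],
    coupling_strength: float,
    seed: int = 0,
    noise_sd: float = 0.5,
    replicates_per_tissue: int = 2,
    replicate_sd: float = 0.1,
    input_log_mean: float = 2.0,
    input_log_sd: float = 1.0,
    rules: PairingRules | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate input/IP FPKM tables with tunable tAI-TE coupling.

    For each tissue pool, gene tAI is computed and standardized; the
    tissue-level log TE is coupling_strength * standardized tAI +
    Normal(0, noise_sd). Input FPKM is log-normal per gene and tissue;
    IP FPKM = input * TE, with independent log-normal replicate noise
    (sd ``replicate_sd``) on both channels. Returns a long-format table
    (gene, sample, input_fpkm, ip_fpkm) and truth with per-tissue true TE
    and the top-5% gene sets by true TE.
    """
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must be in [0, 1]")
    if codon_counts.empty:
        raise ValueError("codon count table is empty")
    rng = np.random.default_rng(seed)
    if rules is None:
        rules = build_pairing_rules(eukaryote=True)
    genes = list(codon_counts.index)
    rows = []
    true_te = pd.DataFrame(index=genes, columns=list(trna_pools), dtype=float)
    htg: dict[str, tuple[str, ...]] = {}
    for tissue, pool in trna_pools.items():
        w = codon_adaptiveness(pool, rules)["w"]
        tai = genes_tai(codon_counts, w)
        z = (tai - tai.mean()) / tai.std(ddof=1)
        log_te = coupling_strength * z + rng.normal(0.0, noise_sd, len(genes))
        te = np.exp(log_te)
        true_te[tissue] = te
        k = max(1, int(np.ceil(0.05 * len(genes))))
        order = sorted(genes, key=lambda g: (-true_te.loc[g, tissue], g))
        htg[tissue] = tuple(order[:k])
        base_input = np.exp(rng.normal(input_log_mean, input_log_sd, len(genes)))
        for rep in range(1, replicates_per_tissue + 1):
            noise_in = np.exp(rng.normal(0.0, replicate_sd, len(genes)))
            noise_ip = np.exp(rng.normal(0.0, replicate_sd, len(genes)))
            inp = base_input * noise_in
            ip = base_input * te * noise_ip
            sample = f"{tissue}_rep{rep}"
            rows.extend(zip(genes, [sample] * len(genes), inp, ip))
    table = pd.DataFrame(rows, columns=["gene", "sample", "input_fpkm", "ip_fpkm"])
    truth = SimTruth(true_te=true_te, htg=htg)
    return table, truth


def write_cds_fasta(cds_by_gene: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in cds_by_gene.items():
            fh.write(f">{gene}\n{seq}\n")


def write_sample_sheet(sample_tissue: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": list(sample_tissue.index),
            "tissue": list(sample_tissue.values),
            "replicate": [s.rsplit("_rep", 1)[-1] for s in sample_tissue.index],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_fpkm_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
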