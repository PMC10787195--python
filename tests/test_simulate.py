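import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trnatlas import (
    TrnaSimConfig,
    compute_rpm,
    permutation_test,
    simulate_coding_genes,
    simulate_translatome,
    simulate_trna_counts,
    weighted_rscu,
)
from trnatlas.expression import read_counts_tsv
from trnatlas.simulate import (
    uniform_profiles,
    write_fpkm_tsv,
    write_sample_sheet,
)
from trnatlas.translatome import read_fpkm_tsv


def small_cfg(seed, **kw):
    defaults = dict(n_amino_acids=8, n_mt=3, library_size=300_000)
    defaults.update(kw)
    return TrnaSimConfig(seed=seed, **defaults)


class TestTrnaCounts:
    def test_seed_determinism(self):
        a, _, _ = simulate_trna_counts(small_cfg(1))
        b, _, _ = simulate_trna_counts(small_cfg(1))
        assert a.values.equals(b.values)
        assert not a.values.equals(simulate_trna_counts(small_cfg(2))[0].values)

    def test_zero_effects_leave_only_counting_noise(self):
        """With all tissue sds 0, feature CV matches analytic NB CV."""
        cfg = small_cfg(3, sigma_aa=0.0, sigma_ac=0.0, sigma_iso=0.0,
                        replicates_per_tissue=4, library_size=2_000_000,
                        dispersion=0.05, n_mt=0, mt_fractions=(0.0, 0.0, 0.0))
        counts, records, truth = simulate_trna_counts(cfg)
        for eff in truth.effects.values():
            assert (eff == 0).all().all()
        vals = counts.values.to_numpy(dtype=float)
        mu = vals.mean(axis=1)
        keep = mu > 500  # Poisson part negligible only at high counts
        empirical = (vals.std(axis=1, ddof=1) / mu)[keep]
        analytic = np.sqrt(1.0 / mu[keep] + cfg.dispersion)
        assert np.median(empirical) == pytest.approx(np.median(analytic), rel=0.2)

    def test_amino_acid_coregulation_detected_in_pair_pccs(self):
        """sigma_aa >> sigma_iso: same-AA pairs correlate more than diff-AA."""
        wins = 0
        for seed in range(20):
            cfg = small_cfg(seed, sigma_aa=0.5, sigma_ac=0.0, sigma_iso=0.05)
            counts, records, _ = simulate_trna_counts(cfg)
            rpm = compute_rpm(counts, records, denominator="ct_only")
            ct = [r for r in records if r.compartment == "cytosolic"
                  and not r.is_special]
            ids = [r.id for r in ct]
            logs = np.log2(rpm.values.loc[ids] + 1).to_numpy()
            corr = np.corrcoef(logs)
            same_aa, diff_aa = [], []
            for i in range(len(ct)):
                for j in range(i + 1, len(ct)):
                    if ct[i].isotype == ct[j].isotype:
                        if ct[i].anticodon != ct[j].anticodon:
                            same_aa.append(corr[i, j])
                    else:
                        diff_aa.append(corr[i, j])
            if np.median(same_aa) > np.median(diff_aa):
                wins += 1
        assert wins >= 18

    def test_library_size_marginals(self):
        cfg = small_cfg(5)
        counts, _, truth = simulate_trna_counts(cfg)
        for s in counts.samples:
            tissue = counts.sample_tissue[s]
            p = truth.proportions[tissue].to_numpy()
            mu = cfg.library_size * p
            sd_total = np.sqrt((mu + cfg.dispersion * mu**2).sum())
            assert abs(counts.values[s].sum() - cfg.library_size) < 3 * sd_total

    def test_round_trip_through_readers(self, tmp_path):
        counts, _, _ = simulate_trna_counts(small_cfg(7))
        counts.values.to_csv(tmp_path / "counts.tsv", sep="\t")
        write_sample_sheet(counts.sample_tissue, tmp_path / "sheet.tsv")
        back = read_counts_tsv(tmp_path / "counts.tsv", tmp_path / "sheet.tsv")
        assert back.values.equals(counts.values)
        assert back.sample_tissue.to_dict() == counts.sample_tissue.to_dict()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TrnaSimConfig(seed=0, sigma_aa=-1.0)
        with pytest.raises(ValueError, match="library"):
            TrnaSimConfig(seed=0, library_size=0)

    def test_truth_recovery_isodecoder_noise_is_null(self):
        """Pure isodecoder effects: anticodon permutation is non-significant."""
        calm = 0
        for seed in range(10):
            cfg = small_cfg(seed + 100, sigma_aa=0.0, sigma_ac=0.0, sigma_iso=0.8)
            counts, records, _ = simulate_trna_counts(cfg)
            rpm = compute_rpm(counts, records, denominator="ct_only")
            res = permutation_test(rpm, records, "isoacceptor_expression_cv",
                                   "greater", n_perm=300, seed=seed)
            if res.p > 0.1:
                calm += 1
        assert calm >= 8

    def test_truth_recovery_anticodon_effects_detected(self):
        hits = 0
        for seed in range(10):
            cfg = small_cfg(seed + 200, sigma_aa=0.0, sigma_ac=0.8,
                            sigma_iso=0.05)
            counts, records, _ = simulate_trna_counts(cfg)
            rpm = compute_rpm(counts, records, denominator="ct_only")
            res = permutation_test(rpm, records, "isoacceptor_expression_cv",
                                   "greater", n_perm=300, seed=seed)
            if res.p < 0.05:
                hits += 1
        assert hits >= 9


class TestCodingGenes:
    def test_uniform_profile_rscu_approaches_one(self):
        """Law of large numbers: per-gene RSCU -> 1 under uniform profiles."""
        cds, table, _ = simulate_coding_genes(
            1, cds_length_codons=(10_000, 10_000), seed=0
        )
        rscu = weighted_rscu(table, pd.Series({g: 1.0 for g in table.index}))
        assert (rscu - 1).abs().max() < 0.25  # includes 6-codon families
        big_families = [c for c in rscu.index]
        assert (rscu - 1).abs().median() < 0.05

    def test_empty(self):
        cds, table, _ = simulate_coding_genes(0, seed=1)
        assert cds == {} and table.empty

    def test_fasta_bytes_deterministic(self, tmp_path):
        from trnatlas.simulate import write_cds_fasta

        for name in ("a", "b"):
            cds, _, _ = simulate_coding_genes(5, cds_length_codons=(30, 60), seed=9)
            write_cds_fasta(cds, tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_structure_of_cds(self):
        cds, table, _ = simulate_coding_genes(10, cds_length_codons=(30, 60), seed=2)
        from trnatlas.genetic_code import STOP_CODONS

        for seq in cds.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert seq[-3:] in STOP_CODONS

    def test_bad_profile_rejected(self):
        profiles = uniform_profiles()
        profiles["Gly"] = profiles["Gly"] * 2
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_coding_genes(2, profiles=profiles, seed=0)


@pytest.fixture(scope="module")
def genes():
    _, table, _ = simulate_coding_genes(400, cds_length_codons=(100, 200), seed=3)
    return table


@pytest.fixture(scope="module")
def pools():
    from trnatlas.genetic_code import SENSE_ANTICODONS

    rng = np.random.default_rng(4)
    return {
        t: pd.Series(rng.uniform(1, 1000, 61), index=list(SENSE_ANTICODONS))
        for t in ("brain", "heart")
    }


class TestTranslatome:
    def test_zero_coupling_null_correlation(self, pools):
        """coupling=0: tAI and true TE are uncorrelated."""
        from trnatlas import build_pairing_rules, codon_adaptiveness, genes_tai

        _, big_table, _ = simulate_coding_genes(2000, cds_length_codons=(100, 150),
                                                seed=5)
        ok = 0
        for seed in range(10):
            fpkm, truth = simulate_translatome(big_table, pools, 0.0, seed=seed)
            w = codon_adaptiveness(pools["brain"],
                                   build_pairing_rules())["w"]
            tai = genes_tai(big_table, w)
            rho = sps.spearmanr(tai, truth.true_te["brain"]).statistic
            if abs(rho) < 0.1:
                ok += 1
        assert ok >= 9

    def test_full_coupling_separates_te_extremes(self, genes, pools):
        fpkm, truth = simulate_translatome(genes, pools, 1.0, seed=6,
                                           noise_sd=0.1)
        from trnatlas import build_pairing_rules, codon_adaptiveness, genes_tai

        w = codon_adaptiveness(pools["brain"], build_pairing_rules())["w"]
        tai = genes_tai(genes, w)
        te = truth.true_te["brain"].sort_values()
        k = 20
        low, high = te.index[:k], te.index[-k:]
        stat, p = sps.ranksums(tai[high], tai[low])
        assert p < 1e-3 and tai[high].median() > tai[low].median()

    def test_determinism_and_roundtrip(self, genes, pools, tmp_path):
        a, _ = simulate_translatome(genes, pools, 0.5, seed=8)
        b, _ = simulate_translatome(genes, pools, 0.5, seed=8)
        assert a.equals(b)
        write_fpkm_tsv(a, tmp_path / "fpkm.tsv")
        back = read_fpkm_tsv(tmp_path / "fpkm.tsv")
        assert np.allclose(back["input_fpkm"], a["input_fpkm"])
        assert np.array_equal(back["gene"], a["gene"])

    def test_htg_truth_is_top_five_percent(self, genes, pools):
        _, truth = simulate_translatome(genes, pools, 1.0, seed=10)
        te = truth.true_te["heart"]
        assert len(truth.htg["heart"]) == int(np.ceil(0.05 * len(te)))
        cutoff = te[list(truth.htg["heart"])].min()
        assert (te > cutoff).sum() < len(truth.htg["heart"])

    def test_invalid_coupling_rejected(self, genes, pools):
        with pytest.raises(ValueError, match="coupling"):
            simulate_translatome(genes, pools, 1.5, seed=0)
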