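import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnatlas import (
    amino_acid_composition,
    build_grouping,
    codon_index,
    count_codons,
    count_codons_table,
    relative_synonymous_usage,
    rsiu,
    weighted_rscu,
)
from trnatlas.genetic_code import CODON_TO_AA, SENSE_CODONS, SYNONYMOUS_FAMILIES

import oracles
from conftest import make_record


def random_codon_table(rng, n_genes=8, n_codons=120):
    genes = {}
    codons = list(SENSE_CODONS)
    for i in range(n_genes):
        picks = rng.choice(len(codons), size=n_codons)
        seq = "".join(codons[k] for k in picks)
        genes[f"g{i}"] = seq
    return genes, count_codons_table(genes)


class TestCountCodons:
    def test_stop_separated_from_sense(self):
        counts = count_codons("ATGGGGTAA")
        assert counts["ATG"] == 1 and counts["GGG"] == 1 and counts["TAA"] == 1
        from trnatlas.usage import sense_counts

        sense = sense_counts(counts.to_frame().T)
        assert "TAA" not in sense.columns
        assert sense.sum(axis=1).iloc[0] == 2

    def test_empty_sequence_all_zero(self):
        assert count_codons("").sum() == 0

    def test_matches_sliding_bruteforce(self, rng):
        codons = list(SENSE_CODONS)
        seq = "".join(codons[k] for k in rng.choice(61, size=300))
        counts = count_codons(seq)
        expected = oracles.count_codons_loop(seq)
        for codon, n in expected.items():
            assert counts[codon] == n
        assert counts.sum() == 300

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            count_codons("ATGG")

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            count_codons("ATGNNN")

    def test_internal_stop_warns_but_counts(self):
        with pytest.warns(UserWarning, match="internal stop"):
            counts = count_codons("ATGTAAGGG")
        assert counts["GGG"] == 1


class TestRelativeSynonymousUsage:
    def test_direct_evaluation(self):
        vals = pd.Series({"a": 30.0, "b": 10.0})
        out = relative_synonymous_usage(vals, {"a": "f", "b": "f"})
        assert out["a"] == pytest.approx(1.5)
        assert out["b"] == pytest.approx(0.5)

    def test_singleton_identity(self):
        out = relative_synonymous_usage(pd.Series({"a": 99.0}), {"a": "f"})
        assert out["a"] == 1.0

    def test_symmetry(self):
        vals = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0})
        out = relative_synonymous_usage(vals, dict.fromkeys("abc", "f"))
        assert (out == 1.0).all()

    def test_zero_total_family_missing(self):
        vals = pd.DataFrame({"s1": {"a": 0.0, "b": 0.0, "c": 4.0}})
        out = relative_synonymous_usage(vals, {"a": "f", "b": "f", "c": "g"})
        assert out["s1"][["a", "b"]].isna().all()
        assert out.loc["c", "s1"] == 1.0

    def test_rsiu_matches_loop_oracle(self, toy_records, toy_matrix):
        gm = build_grouping(toy_records)
        out = rsiu(toy_matrix.values, gm)
        fam = {r.id: r.isoacceptor_key for r in toy_records}
        for s in toy_matrix.samples:
            expected = oracles.rsu_loop(toy_matrix.values[s].to_dict(), fam)
            for f in toy_matrix.features:
                assert out.loc[f, s] == pytest.approx(expected[f], abs=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_family_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        vals = pd.Series(rng.uniform(0.1, 100, 9), index=list("abcdefghi"))
        fam = {k: i % 3 for i, k in enumerate(vals.index)}
        out = relative_synonymous_usage(vals, fam)
        for f in set(fam.values()):
            members = [k for k in vals.index if fam[k] == f]
            assert out[members].mean() == pytest.approx(1.0, abs=1e-12)


class TestWeightedRscu:
    def test_direct_evaluation(self):
        """2-codon family: weighted sums (7, 3) -> RSCU (1.4, 0.6)."""
        table = pd.DataFrame(
            {"GAT": {"A": 3, "B": 1}, "GAC": {"A": 1, "B": 1}}
        )  # Asp family
        w = pd.Series({"A": 2.0, "B": 1.0})
        out = weighted_rscu(table, w)
        assert out["GAT"] == pytest.approx(1.4)
        assert out["GAC"] == pytest.approx(0.6)

    def test_equal_usage_flat(self):
        table = pd.DataFrame({"GAT": {"A": 2}, "GAC": {"A": 2}})
        out = weighted_rscu(table, pd.Series({"A": 5.0}))
        assert out["GAT"] == out["GAC"] == 1.0

    def test_unit_weights_reduce_to_classic_rscu(self, rng):
        genes, table = random_codon_table(rng)
        w = pd.Series(1.0, index=table.index)
        out = weighted_rscu(table, w)
        counts_by_gene = {g: oracles.count_codons_loop(s) for g, s in genes.items()}
        expected = oracles.weighted_rscu_loop(counts_by_gene,
                                              dict.fromkeys(genes, 1.0))
        for codon, val in expected.items():
            assert out[codon] == pytest.approx(val, abs=1e-12)

    def test_empty_gene_set_raises(self, rng):
        _, table = random_codon_table(rng)
        with pytest.raises(ValueError, match="empty gene set"):
            weighted_rscu(table, pd.Series(1.0, index=table.index), [])


class TestCodonIndex:
    def test_single_gene_identity(self):
        table = pd.DataFrame({"AAA": {"g": 5}, "GGG": {"g": 5}})
        out = codon_index(table, pd.Series({"g": 3.0}))
        assert out["AAA"] == out["GGG"] == pytest.approx(0.5)

    def test_two_gene_weighted(self):
        """Gene A (0.5, 0.5) weight 3; gene B (1, 0) weight 1 -> (0.625, 0.375)."""
        table = pd.DataFrame({"AAA": {"A": 2, "B": 4}, "GGG": {"A": 2, "B": 0}})
        out = codon_index(table, pd.Series({"A": 3.0, "B": 1.0}))
        assert out["AAA"] == pytest.approx(0.625)
        assert out["GGG"] == pytest.approx(0.375)

    def test_sums_to_one(self, rng):
        _, table = random_codon_table(rng)
        w = pd.Series(rng.uniform(0.5, 20, len(table)), index=table.index)
        assert codon_index(table, w).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_codon_gene_excluded_with_warning(self):
        table = pd.DataFrame({"AAA": {"g": 2, "z": 0}, "GGG": {"g": 2, "z": 0}})
        with pytest.warns(UserWarning, match="zero counted"):
            out = codon_index(table, pd.Series({"g": 1.0, "z": 9.0}))
        assert out["AAA"] == pytest.approx(0.5)


class TestAminoAcidComposition:
    def test_direct_evaluation(self):
        table = pd.DataFrame({"GGA": {"g": 2}})  # 2 Gly codons
        out = amino_acid_composition(table, pd.Series({"g": 5.0}), normalize=False)
        assert out["Gly"] == 10.0

    def test_zero_weight_contributes_nothing(self):
        table = pd.DataFrame({"GGA": {"g": 2, "h": 50}, "AAA": {"g": 1, "h": 0}})
        out = amino_acid_composition(table, pd.Series({"g": 1.0, "h": 0.0}),
                                     normalize=False)
        assert out["Gly"] == 2.0 and out["Lys"] == 1.0

    def test_normalized_sums_to_one(self, rng):
        _, table = random_codon_table(rng)
        w = pd.Series(rng.uniform(0.5, 20, len(table)), index=table.index)
        out = amino_acid_composition(table, w, normalize=True)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_gene_matches_codon_index_aggregation(self):
        """On one gene both reduce to raw proportions, aggregated by family."""
        table = pd.DataFrame({"GGA": {"g": 3}, "GGC": {"g": 1}, "AAA": {"g": 4}})
        ci = codon_index(table, pd.Series({"g": 2.0}))
        comp = amino_acid_composition(table, pd.Series({"g": 2.0}), normalize=True)
        assert comp["Gly"] == pytest.approx(ci["GGA"] + ci["GGC"], abs=1e-12)
        assert comp["Lys"] == pytest.approx(ci["AAA"], abs=1e-12)


class TestOracleEquivalence:
    """Exact agreement with nested-loop references on random instances."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_metrics_match_loops(self, seed):
        rng = np.random.default_rng(seed)
        genes, table = random_codon_table(rng, n_genes=int(rng.integers(3, 12)))
        w = pd.Series(rng.uniform(0.1, 50, len(table)), index=table.index)
        counts_by_gene = {g: oracles.count_codons_loop(s) for g, s in genes.items()}
        weights = w.to_dict()

        ci = codon_index(table, w)
        for codon, val in oracles.codon_index_loop(counts_by_gene, weights).items():
            assert ci[codon] == pytest.approx(val, abs=1e-12)

        rscu = weighted_rscu(table, w)
        for codon, val in oracles.weighted_rscu_loop(counts_by_gene, weights).items():
            assert rscu[codon] == pytest.approx(val, abs=1e-12)

        comp = amino_acid_composition(table, w, normalize=False)
        for aa, val in oracles.aa_composition_loop(
            counts_by_gene, weights, normalize=False
        ).items():
            assert comp[aa] == pytest.approx(val, rel=1e-12)

    def test_weight_rescaling_invariance(self, rng):
        genes, table = random_codon_table(rng)
        w = pd.Series(rng.uniform(0.1, 50, len(table)), index=table.index)
        for metric in (weighted_rscu, codon_index):
            a = metric(table, w)
            b = metric(table, w * 1234.5)
            assert np.allclose(a, b, atol=1e-12, equal_nan=True)
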