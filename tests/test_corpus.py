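"""Corpus preparation: clustering, splits, nesting, chi-square, tokenizer."""

import numpy as np
import pytest

import ablmkit as ak
from ablmkit.corpus import (
    DegenerateTableError,
    chi2_independence,
    cluster_identity,
    gene_usage_chi2,
    nest_subsets,
    pair_identity,
    partition_corpus,
    round_half_up_frac,
)
from ablmkit.repertoire import PairedAntibody
from ablmkit.tokenizer import TokenizationError, detokenize_pair, get_vocabulary, tokenize_pair


def _pair(pid, heavy, light="DIQ"):
    return PairedAntibody(
        pair_id=pid, donor_id="d0", heavy_aa=heavy, light_aa=light,
        heavy_provenance="V" * len(heavy), light_provenance="V" * len(light),
        heavy_regions={}, light_regions={}, heavy_mut_count=0, light_mut_count=0,
        v_call="V1", j_call="J1", light_v_call="V1", light_j_call="J1",
    )


class TestClustering:
    def test_identical_pairs_collapse(self):
        pairs = [_pair("a", "QVQLVQSGAE"), _pair("b", "QVQLVQSGAE")]
        assert len(cluster_identity(pairs)) == 1

    def test_all_distant_pairs_kept(self):
        pairs = [_pair("a", "AAAAAAAAAA"), _pair("b", "CCCCCCCCCC"), _pair("c", "EEEEEEEEEE")]
        assert len(cluster_identity(pairs, threshold=0.9)) == 3

    def test_two_mismatches_in_ten_is_identity_080(self):
        # hand alignment: 10 columns, 8 matches, no gaps
        assert pair_identity("ACDEFGHIKL", "ACDEFGHIYV") == pytest.approx(0.8)

    def test_threshold_straddles_toy_identity(self):
        a = _pair("a", "ACDEFGHIKL", light="")
        b = _pair("b", "ACDEFGHIYV", light="")
        assert len(cluster_identity([a, b], threshold=0.9)) == 2
        assert len(cluster_identity([a, b], threshold=0.75)) == 1

    def test_permutation_stable(self, repertoire):
        subset = repertoire[:30]
        ids_fwd = {p.pair_id for p in cluster_identity(subset)}
        ids_rev = {p.pair_id for p in cluster_identity(subset[::-1])}
        assert ids_fwd == ids_rev

    def test_empty_input(self):
        assert cluster_identity([]) == []


class TestPartition:
    def test_exact_small_split(self):
        split = partition_corpus(list(range(100)), seed=0)
        assert (len(split.train), len(split.eval), len(split.test)) == (96, 2, 2)

    def test_study_scale_split_sizes(self):
        n = 1_717_423
        n_train = round_half_up_frac(n, 96, 100)
        assert n_train == 1_648_726
        remainder = n - n_train
        assert remainder == 68_697
        assert (remainder + 1) // 2 == 34_349  # eval gets the odd element

    def test_partition_is_exhaustive_and_disjoint(self):
        ids = [f"p{i}" for i in range(473)]
        split = partition_corpus(ids, seed=3)
        combined = split.train + split.eval + split.test
        assert sorted(combined) == sorted(ids)
        assert len(set(combined)) == len(ids)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            partition_corpus([1, 2], seed=0)


class TestNesting:
    def test_nested_sizes_follow_half_rule(self):
        nested = nest_subsets(list(range(1001)), seed=1)
        assert len(nested.H) == 501 and len(nested.Q) == 251

    def test_study_scale_nested_sizes(self):
        assert (1_648_726 + 1) // 2 == 824_363
        assert (824_363 + 1) // 2 == 412_182

    def test_subsets_are_nested(self):
        nested = nest_subsets([f"x{i}" for i in range(137)], seed=9)
        assert set(nested.Q) <= set(nested.H) <= set(nested.F)
        assert len(set(nested.H)) == len(nested.H)


class TestGeneUsageChi2:
    def test_hand_computed_table(self):
        chi2, dof, p = chi2_independence(np.array([[10, 20], [20, 10]]))
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)
        assert dof == 1
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_subset_against_itself_is_null(self, repertoire):
        ids = [p.pair_id for p in repertoire[:60]]
        chi2, dof, p = gene_usage_chi2(ids, ids, repertoire, feature="V", chain="heavy")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_nested_subsets_show_no_usage_drift(self, repertoire):
        ids = [p.pair_id for p in repertoire]
        nested = nest_subsets(ids, seed=2)
        for feature in ("V", "J", "VJ"):
            _, _, p = gene_usage_chi2(nested.F, nested.H, repertoire, feature=feature)
            assert p > 0.01

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi2_independence(np.array([[5, 0], [7, 0]]))

    def test_null_p_values_are_uniform(self, library):
        """Disjoint random halves of one corpus: gene-usage p-values should
        be uniform on [0, 1] (Kolmogorov-Smirnov over 200 replicates)."""
        from scipy import stats

        import ablmkit as ak

        cfg = ak.RepertoireConfig(n_donors=4, pairs_per_donor=100, seed=2)
        pairs = ak.generate_repertoire(cfg, library)
        ids = [p.pair_id for p in pairs]
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            perm = rng.permutation(len(ids))
            half = len(ids) // 2
            a = [ids[i] for i in perm[:half]]
            b = [ids[i] for i in perm[half:]]
            _, _, p = gene_usage_chi2(a, b, pairs, feature="V", chain="heavy")
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTokenizer:
    def test_vocabulary_size(self):
        assert len(get_vocabulary()) == 33

    def test_layout_and_special_positions(self):
        tok = tokenize_pair("QVQ", "DIQ")
        assert len(tok) == 10
        assert sorted(np.flatnonzero(tok.special_mask)) == [0, 4, 5, 9]
        vocab = get_vocabulary()
        assert tok.token_ids[0] == vocab.cls_id
        assert tok.token_ids[4] == tok.token_ids[5] == vocab.cls_id
        assert tok.token_ids[9] == vocab.eos_id

    def test_round_trip(self, repertoire):
        for p in repertoire[:10]:
            tok = tokenize_pair(p.heavy_aa, p.light_aa)
            assert detokenize_pair(tok) == (p.heavy_aa, p.light_aa)

    def test_out_of_alphabet_error_names_position(self):
        with pytest.raises(TokenizationError, match="position 2"):
            tokenize_pair("QV*Q", "DIQ")
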