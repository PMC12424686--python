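"""Region/provenance-resolved residue evaluation and its summaries."""

import numpy as np
import pytest
from scipy import stats

import ablmkit as ak
from ablmkit.regional import (
    DegenerateDifferencesError,
    SamplingError,
    iterative_mask_scan,
    median_ci,
    paired_ttest_by_donor,
    sample_eval_sequences,
    summarize_regions,
)
from ablmkit.tokenizer import get_vocabulary, tokenize_pair


class _UniformModel:
    """Assigns equal probability to all 33 tokens."""

    def forward(self, tokens, pad_mask=None):
        return np.zeros(tokens.shape + (33,)), None


class _RecallModel:
    """Knows the original sequence: always predicts the true token."""

    def __init__(self, pair):
        tok = tokenize_pair(pair.heavy_aa, pair.light_aa)
        self.truth = tok.token_ids

    def forward(self, tokens, pad_mask=None):
        logits = np.full(tokens.shape + (33,), -1e3)
        for b in range(tokens.shape[0]):
            logits[b, np.arange(tokens.shape[1]), self.truth] = 1e3
        return logits, None


class TestSampling:
    def test_per_donor_counts(self, repertoire):
        rng = np.random.default_rng(0)
        mutated, unmutated = sample_eval_sequences(repertoire, 5, rng)
        n_donors = len({p.donor_id for p in repertoire})
        assert len(mutated) == len(unmutated) == 5 * n_donors
        assert all(not p.is_unmutated for p in mutated)
        assert all(p.is_unmutated for p in unmutated)

    def test_insufficient_class_members_named(self, repertoire):
        with pytest.raises(SamplingError, match="donor_000"):
            sample_eval_sequences(repertoire, 10_000, np.random.default_rng(0))

    def test_seeded_sampling_reproducible(self, repertoire):
        a = sample_eval_sequences(repertoire, 3, np.random.default_rng(4))
        b = sample_eval_sequences(repertoire, 3, np.random.default_rng(4))
        assert [p.pair_id for p in a[0]] == [p.pair_id for p in b[0]]


class TestMaskScan:
    def test_one_record_per_heavy_position(self, repertoire):
        pair = repertoire[0]
        records = iterative_mask_scan(_UniformModel(), pair)
        assert len(records) == len(pair.heavy_aa)
        assert [r.position for r in records] == list(range(len(pair.heavy_aa)))

    def test_uniform_model_loss_is_log_vocab(self, repertoire):
        records = iterative_mask_scan(_UniformModel(), repertoire[1])
        assert all(r.loss == pytest.approx(np.log(33), rel=1e-9) for r in records)

    def test_perfect_recall_model_loss_is_zero(self, repertoire):
        pair = repertoire[2]
        records = iterative_mask_scan(_RecallModel(pair), pair)
        assert all(r.loss == pytest.approx(0.0, abs=1e-6) for r in records)

    def test_provenance_present_iff_cdr3(self, repertoire):
        for pair in repertoire[:5]:
            for r in iterative_mask_scan(_UniformModel(), pair):
                assert (r.provenance is not None) == (r.region == "CDR3")

    def test_cdr3_provenance_partition(self, repertoire):
        for pair in repertoire[:5]:
            records = iterative_mask_scan(_UniformModel(), pair)
            c3 = pair.heavy_regions["CDR3"]
            n_cdr3 = sum(1 for r in records if r.region == "CDR3")
            assert n_cdr3 == c3[1] - c3[0]


class TestSummaries:
    def test_simple_median(self):
        med, _ = median_ci([1.0, 2.0, 3.0], rng=np.random.default_rng(0))
        assert med == 2.0

    def test_degenerate_ci_collapses(self):
        med, (lo, hi) = median_ci([4.0] * 25)
        assert med == lo == hi == 4.0

    def test_ci_matches_binomial_rank_oracle(self):
        rng = np.random.default_rng(7)
        y = np.sort(rng.exponential(size=100))
        _, (lo, hi) = median_ci(y)
        # independent enumeration of the binomial(100, 1/2) cdf
        cdf = np.cumsum([stats.binom.pmf(k, 100, 0.5) for k in range(101)])
        l = max(k for k in range(1, 101) if cdf[k - 1] <= 0.025)
        assert lo == y[l - 1] and hi == y[100 - l]

    def test_region_groups_cover_all_positions(self, repertoire):
        records = []
        for pair in repertoire[:4]:
            records.extend(iterative_mask_scan(_UniformModel(), pair))
        summaries = summarize_regions(records, group_by="region")
        assert sum(s.n_positions for s in summaries) == sum(
            len(p.heavy_aa) for p in repertoire[:4]
        )
        for s in summaries:
            assert s.ci95[0] <= s.median_loss <= s.ci95[1]

    def test_uniform_model_medians_equal_log_vocab(self, repertoire):
        records = iterative_mask_scan(_UniformModel(), repertoire[0])
        for s in summarize_regions(records, group_by="region"):
            assert s.median_loss == pytest.approx(np.log(33), rel=1e-9)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p = paired_ttest_by_donor([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(DegenerateDifferencesError):
            paired_ttest_by_donor([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_hand_computed_statistic(self):
        b = np.array([1.0, 1.1, 0.9, 1.2, 1.0])
        a = b + np.array([0.2, 0.1, 0.3, 0.2, 0.2])
        t, p = paired_ttest_by_donor(a, b)
        assert t == pytest.approx(0.2 / (np.std([0.2, 0.1, 0.3, 0.2, 0.2], ddof=1) / np.sqrt(5)))
        assert t == pytest.approx(6.3246, abs=1e-3)
        assert 0 < p < 0.01


def test_trained_model_struggles_most_on_n_additions(trained_model, repertoire):
    """Non-templated residues are stochastic: their median loss should not
    fall below the V-templated CDR3 residues' after brief training."""
    model, _ = trained_model
    records = []
    for pair in repertoire[:25]:
        records.extend(iterative_mask_scan(model, pair))
    by_prov = {
        s.group: s.median_loss
        for s in summarize_regions(records, group_by="provenance")
        if s.mutated is False
    }
    assert by_prov["N"] >= by_prov["V"]
    by_region = {
        s.group: s.median_loss
        for s in summarize_regions(records, group_by="region")
        if s.mutated is False
    }
    assert by_region["CDR3"] > by_region["FWRs"]
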