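"""Corpus preparation: identity clustering, splits, nesting, gene-usage checks.

Turns a paired repertoire into pretraining artifacts: representatives after
greedy 90%-identity clustering, a 96/2/2 train/eval/test split, nested
full/half/quarter (F/H/Q) training subsets, and a chi-square check that the
nested subsets do not drift in V/J gene usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy import stats

__all__ = [
    "CorpusSplit",
    "NestedSubsets",
    "cluster_identity",
    "pair_identity",
    "partition_corpus",
    "nest_subsets",
    "gene_usage_chi2",
    "chi2_independence",
    "round_half_up_frac",
]

TRAIN_FRACTION_NUM, TRAIN_FRACTION_DEN = 96, 100


class DegenerateTableError(ValueError):
    pass


@dataclass
class CorpusSplit:
    train: list
    eval: list
    test: list
    seed: int
    fractions: tuple = (0.96, 0.02, 0.02)


@dataclass
class NestedSubsets:
    """Nested training subsets: Q is a subset of H, H a subset of F."""

    F: list
    H: list
    Q: list


def round_half_up_frac(n: int, num: int, den: int) -> int:
    """round-half-up of n * num / den, in exact integer arithmetic."""
    return (2 * n * num + den) // (2 * den)


def _make_aligner(threshold_irrelevant=None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # Gaps are free in the scoring scheme; the infinitesimal penalty only
    # breaks ties among equal-match alignments in favour of mismatch
    # columns over gap columns, making identity deterministic.
    aligner.open_gap_score = -1e-6
    aligner.extend_gap_score = -1e-6
    return aligner


def pair_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if seq_a == seq_b:
        return 1.0
    aligner = aligner or _make_aligner()
    aln = next(iter(aligner.align(seq_a, seq_b)))
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def cluster_identity(pairs, threshold: float = 0.90):
    """Greedy founder-representative clustering at an identity threshold.

    Sequences (heavy+light concatenated) are processed longest-first (ties
    by pair id); each joins the earliest-opened cluster whose founder it
    matches at >= threshold identity, else founds a new cluster. Returns
    the founders, in founding order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    items = sorted(
        pairs, key=lambda p: (-(len(p.heavy_aa) + len(p.light_aa)), p.pair_id)
    )
    aligner = _make_aligner()
    founders = []
    founder_seqs = []
    for p in items:
        seq = p.heavy_aa + p.light_aa
        for fs in founder_seqs:
            if pair_identity(seq, fs, aligner) >= threshold:
                break
        else:
            founders.append(p)
            founder_seqs.append(seq)
    return founders


def partition_corpus(ids, seed: int) -> CorpusSplit:
    """Uniformly shuffle and split 96/2/2 (train/eval/test).

    The train size is round-half-up of 0.96 N; the remainder is split
    between eval and test with eval receiving the extra element when the
    remainder is odd.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = round_half_up_frac(n, TRAIN_FRACTION_NUM, TRAIN_FRACTION_DEN)
    remainder = n - n_train
    n_eval = (remainder + 1) // 2
    return CorpusSplit(
        train=shuffled[:n_train],
        eval=shuffled[n_train : n_train + n_eval],
        test=shuffled[n_train + n_eval :],
        seed=seed,
    )


def nest_subsets(train_ids, seed: int) -> NestedSubsets:
    """Sample nested half (H) and quarter (Q) subsets of the training ids.

    |H| = round-half-up(|F|/2), |Q| = round-half-up(|H|/2); H is drawn
    uniformly without replacement from F, and Q from H.
    """
    F = list(train_ids)
    if not F:
        raise ValueError("train set must be non-empty")
    rng = np.random.default_rng(seed)
    n_h = (len(F) + 1) // 2
    H = [F[i] for i in rng.choice(len(F), size=n_h, replace=False)]
    n_q = (len(H) + 1) // 2
    Q = [H[i] for i in rng.choice(len(H), size=n_q, replace=False)]
    return NestedSubsets(F=F, H=H, Q=Q)


def chi2_independence(table: np.ndarray):
    """Pearson chi-square of independence on a 2 x k table (no Yates).

    Zero-total columns are dropped first; fewer than 2 surviving
    categories is a degenerate table.
    """
    table = np.asarray(table, dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty categories")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def gene_usage_chi2(subset_a, subset_b, pairs, feature: str = "V", chain: str = "heavy"):
    """Chi-square test of gene-usage independence between two id subsets.

    ``feature`` is V, J or VJ; ``chain`` selects heavy or light calls.
    Returns (chi2, dof, p) with dof = k - 1 over the k surviving usage
    categories.
    """
    if feature not in ("V", "J", "VJ"):
        raise ValueError(f"feature must be V, J or VJ, got {feature!r}")
    by_id = {p.pair_id: p for p in pairs}

    def category(p):
        if chain == "heavy":
            v, j = p.v_call, p.j_call
        else:
            v, j = p.light_v_call, p.light_j_call
        return {"V": v, "J": j, "VJ": f"{v}|{j}"}[feature]

    cats = sorted({category(p) for p in pairs})
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((2, len(cats)))
    for row, subset in enumerate((subset_a, subset_b)):
        if not subset:
            raise ValueError("subsets must be non-empty")
        for pid in subset:
            table[row, index[category(by_id[pid])]] += 1
    return chi2_independence(table)
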