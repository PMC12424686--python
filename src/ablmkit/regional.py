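"""Region- and provenance-resolved masked-residue evaluation.

Scores a trained MLM one heavy-chain position at a time: each residue is
masked in turn (all other tokens intact), and the cross-entropy of the
model's prediction at that position is recorded together with the
residue's antibody region (FWR1-4, CDR1-3) and, inside CDR3, its
provenance class (V/D/J-templated or non-templated N-addition). Summaries
are pooled medians across positions with order-statistic confidence
intervals, stratified by mutation status; models are compared by paired
t-tests over per-donor medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .mlm import EvaluationError
from .tokenizer import get_vocabulary, tokenize_pair
from .transformer import cross_entropy_from_logits, IGNORE_INDEX

__all__ = [
    "PositionLossRecord",
    "RegionSummary",
    "sample_eval_sequences",
    "iterative_mask_scan",
    "summarize_regions",
    "median_ci",
    "paired_ttest_by_donor",
]

FWR_REGIONS = ("FWR1", "FWR2", "FWR3", "FWR4")


class SamplingError(ValueError):
    pass


class DegenerateDifferencesError(ValueError):
    pass


@dataclass
class PositionLossRecord:
    pair_id: str
    donor_id: str
    chain: str
    position: int
    region: str
    provenance: Optional[str]  # set only for CDR3 positions
    mutated_sequence: bool
    loss: float


@dataclass
class RegionSummary:
    group: str  # region name, "FWRs", or provenance class
    mutated: bool
    median_loss: float
    ci95: tuple
    n_positions: int


def sample_eval_sequences(pairs, n_per_donor: int, rng: np.random.Generator):
    """Sample n_per_donor mutated and unmutated pairs from every donor.

    Sampling is without replacement; a donor lacking enough members of
    either class raises a SamplingError naming donor and class.
    """
    by_donor = {}
    for p in pairs:
        by_donor.setdefault(p.donor_id, []).append(p)
    mutated, unmutated = [], []
    for donor in sorted(by_donor):
        classes = {
            "mutated": [p for p in by_donor[donor] if not p.is_unmutated],
            "unmutated": [p for p in by_donor[donor] if p.is_unmutated],
        }
        for name, pool in classes.items():
            if len(pool) < n_per_donor:
                raise SamplingError(
                    f"donor {donor}: only {len(pool)} {name} pairs, "
                    f"need {n_per_donor}"
                )
            chosen = [pool[i] for i in rng.choice(len(pool), n_per_donor, replace=False)]
            (mutated if name == "mutated" else unmutated).extend(chosen)
    return mutated, unmutated


def _region_at(regions: dict, position: int) -> str:
    for name, (start, end) in regions.items():
        if start <= position < end:
            return name
    raise ValueError(f"position {position} outside all regions")


def iterative_mask_scan(model, pair, batch_size: int = 128):
    """One PositionLossRecord per heavy-chain residue.

    For residue i, a single forward pass is made with exactly that token
    replaced by the mask token; the loss is the cross-entropy of the
    model's distribution at that position against the true residue.
    Variants are batched for efficiency; each variant still masks exactly
    one position.
    """
    vocab = get_vocabulary()
    tok = tokenize_pair(pair.heavy_aa, pair.light_aa)
    n = len(pair.heavy_aa)
    base = tok.token_ids
    records = []
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        tokens = np.tile(base, (len(idx), 1))
        labels = np.full_like(tokens, IGNORE_INDEX)
        rows = np.arange(len(idx))
        cols = idx + 1  # +1 for the leading <cls>
        labels[rows, cols] = tokens[rows, cols]
        tokens[rows, cols] = vocab.mask_id
        logits, _ = model.forward(tokens)
        z = logits[rows, cols]
        z = z - z.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        losses = -logp[rows, labels[rows, cols]]
        for i, pos in enumerate(idx):
            region = _region_at(pair.heavy_regions, int(pos))
            records.append(
                PositionLossRecord(
                    pair_id=pair.pair_id,
                    donor_id=pair.donor_id,
                    chain="heavy",
                    position=int(pos),
                    region=region,
                    provenance=pair.heavy_provenance[pos] if region == "CDR3" else None,
                    mutated_sequence=not pair.is_unmutated,
                    loss=float(losses[i]),
                )
            )
    return records


def median_ci(values, alpha: float = 0.05, rng: Optional[np.random.Generator] = None):
    """Median and its 95% CI by exact binomial order statistics.

    Uses ranks l and n-l+1 where l is the largest rank whose cumulative
    binomial(n, 1/2) mass below it stays within alpha/2. For n < 10 the
    exact interval is vacuous, so a seeded bootstrap (2,000 resamples)
    over medians is used instead.
    """
    y = np.sort(np.asarray(values, dtype=float))
    n = len(y)
    if n == 0:
        raise ValueError("empty group")
    med = float(np.median(y))
    if n < 10:
        rng = rng or np.random.default_rng(0)
        meds = np.median(y[rng.integers(0, n, size=(2000, n))], axis=1)
        lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
        return med, (float(lo), float(hi))
    l = int(stats.binom.ppf(alpha / 2, n, 0.5))  # 1-based lower rank
    l = max(l, 1)
    return med, (float(y[l - 1]), float(y[n - l]))


def summarize_regions(records, group_by: str = "region", collapse_fwr: bool = True,
                      rng: Optional[np.random.Generator] = None):
    """Pooled per-group medians of position losses, stratified by mutation.

    ``group_by='region'`` groups FWRs (collapsed to one group by default)
    and CDR1-3; ``group_by='provenance'`` groups CDR3 positions by V/D/J/N
    origin. Empty groups are omitted.
    """
    groups = {}
    for r in records:
        if group_by == "region":
            key = "FWRs" if collapse_fwr and r.region in FWR_REGIONS else r.region
        elif group_by == "provenance":
            if r.provenance is None:
                continue
            key = r.provenance
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault((key, r.mutated_sequence), []).append(r.loss)

    summaries = []
    for (key, mutated), losses in sorted(groups.items()):
        med, ci = median_ci(losses, rng=rng)
        summaries.append(
            RegionSummary(
                group=key, mutated=mutated, median_loss=med, ci95=ci,
                n_positions=len(losses),
            )
        )
    return summaries


def paired_ttest_by_donor(losses_model_a, losses_model_b):
    """Two-sided paired t-test on per-donor median losses of two models."""
    a = np.asarray(losses_model_a, dtype=float)
    b = np.asarray(losses_model_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors of size >= 2")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0  # identical inputs: no evidence of any difference
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateDifferencesError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
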