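"""Masked-language-model pretraining for paired antibody sequences.

Implements the BERT-style dynamic masking collator (15% of non-special
positions selected; of those 80% masked, 10% replaced by a random residue
token, 10% left unchanged), a seeded miniature training loop with linear
warmup/decay, fixed-seed evaluation so losses are comparable across
models, and checkpoint selection at the onset of overfitting (the first
point where evaluation loss starts rising while training loss still
falls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tokenizer import TokenizedPair, get_vocabulary
from .transformer import (
    IGNORE_INDEX,
    Adam,
    ModelConfig,
    TinyTransformerLM,
    cross_entropy_from_logits,
)

__all__ = [
    "TrainSchedule",
    "MaskedBatch",
    "LossTrajectory",
    "collate",
    "mask_batch",
    "train_mlm",
    "evaluate_mlm_loss",
    "select_checkpoint",
]

SELECT_PROB = 0.15
MASK_FRAC, RANDOM_FRAC = 0.80, 0.10  # remaining 0.10 left unchanged
EVAL_MASK_SEED = 240817  # dedicated fixed seed for evaluation masking


class VocabularyMismatchError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass
class TrainSchedule:
    """Training hyper-parameters.

    Full-scale defaults are 500,000 steps, 30,000 warmup, peak LR 1e-4,
    batch 128, seed 42; desk-scale runs override total_steps, batch_size
    and eval_every downward.
    """

    total_steps: int = 500_000
    warmup_steps: int = 30_000
    peak_lr: float = 1e-4
    batch_size: int = 128
    seed: int = 42
    eval_every: int = 100

    def __post_init__(self):
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must not exceed total_steps")


@dataclass
class MaskedBatch:
    input_ids: np.ndarray  # (B, T)
    labels: np.ndarray  # (B, T), IGNORE_INDEX where unselected
    selected_mask: np.ndarray  # (B, T) bool
    pad_mask: np.ndarray  # (B, T) bool, True = real token


@dataclass
class LossTrajectory:
    records: list = field(default_factory=list)  # (step, train_loss, eval_loss)

    def append(self, step, train_loss, eval_loss):
        if self.records and step <= self.records[-1][0]:
            raise ValueError("steps must be strictly increasing")
        self.records.append((step, float(train_loss), float(eval_loss)))

    @property
    def steps(self):
        return [r[0] for r in self.records]


def collate(pairs):
    """Pad a list of TokenizedPair into (tokens, special, pad_mask) arrays.

    Padding positions are flagged special (never maskable) and excluded
    from attention via pad_mask.
    """
    vocab = get_vocabulary()
    B = len(pairs)
    T = max(len(p) for p in pairs)
    tokens = np.full((B, T), vocab.pad_id, dtype=np.int64)
    special = np.ones((B, T), dtype=bool)
    pad_mask = np.zeros((B, T), dtype=bool)
    for i, p in enumerate(pairs):
        L = len(p)
        tokens[i, :L] = p.token_ids
        special[i, :L] = p.special_mask
        pad_mask[i, :L] = True
    return tokens, special, pad_mask


def mask_batch(tokens, special_mask, rng, pad_mask=None) -> MaskedBatch:
    """Apply the MLM masking scheme to a collated batch.

    Each non-special position is independently selected with probability
    0.15; among selected positions 80% become the mask token, 10% a
    uniformly random canonical-residue token, and 10% keep their original
    token. Labels carry the original id at selected positions and
    IGNORE_INDEX elsewhere.
    """
    vocab = get_vocabulary()
    if pad_mask is None:
        pad_mask = np.ones_like(special_mask)
    selected = (~special_mask) & (rng.random(tokens.shape) < SELECT_PROB)
    action = rng.random(tokens.shape)
    residues = np.asarray(vocab.residue_ids)
    random_ids = residues[rng.integers(0, len(residues), size=tokens.shape)]

    input_ids = tokens.copy()
    input_ids[selected & (action < MASK_FRAC)] = vocab.mask_id
    rand_sel = selected & (action >= MASK_FRAC) & (action < MASK_FRAC + RANDOM_FRAC)
    input_ids[rand_sel] = random_ids[rand_sel]
    labels = np.where(selected, tokens, IGNORE_INDEX)
    return MaskedBatch(input_ids, labels, selected, pad_mask)


def _check_vocab(model: TinyTransformerLM):
    if model.config.vocab_size != len(get_vocabulary()):
        raise VocabularyMismatchError(
            f"model vocab_size {model.config.vocab_size} != "
            f"tokenizer vocabulary {len(get_vocabulary())}"
        )


def train_mlm(model_config: ModelConfig, schedule: TrainSchedule, train_pairs,
              eval_pairs, keep_checkpoints: bool = True):
    """Train a miniature MLM; fully seeded, deterministic given inputs.

    Returns (model, LossTrajectory, checkpoints) where checkpoints maps
    recorded step -> parameter snapshot.
    """
    model = TinyTransformerLM(model_config, seed=schedule.seed)
    _check_vocab(model)
    if not train_pairs or not eval_pairs:
        raise EvaluationError("train and eval sets must be non-empty")
    opt = Adam(
        model.params,
        peak_lr=schedule.peak_lr,
        warmup_steps=schedule.warmup_steps,
        total_steps=schedule.total_steps,
    )
    rng = np.random.default_rng(schedule.seed)
    n = len(train_pairs)
    trajectory = LossTrajectory()
    checkpoints = {}
    window = []
    for step in range(1, schedule.total_steps + 1):
        idx = rng.choice(n, size=min(schedule.batch_size, n), replace=n < schedule.batch_size)
        tokens, special, pad = collate([train_pairs[i] for i in idx])
        batch = mask_batch(tokens, special, rng, pad)
        if not batch.selected_mask.any():
            continue
        loss, grads, _ = model.loss_and_grads(batch.input_ids, batch.labels, batch.pad_mask)
        opt.step(model.params, grads)
        window.append(loss)
        if step % schedule.eval_every == 0 or step == schedule.total_steps:
            eval_loss = evaluate_mlm_loss(model, eval_pairs)
            trajectory.append(step, np.mean(window), eval_loss)
            window = []
            if keep_checkpoints:
                checkpoints[step] = {k: v.copy() for k, v in model.params.items()}
    return model, trajectory, checkpoints


def evaluate_mlm_loss(model: TinyTransformerLM, pairs, batch_size: int = 64,
                      by_donor: bool = False, eval_seed: int = EVAL_MASK_SEED):
    """Mean masked cross-entropy under a fixed evaluation masking seed.

    With ``by_donor=True``, pairs are grouped by donor_id and the function
    returns (per_donor dict, unweighted mean over donors).
    """
    _check_vocab(model)
    if not pairs:
        raise EvaluationError("empty evaluation set")
    if by_donor:
        donors = sorted({p.donor_id for p in pairs})
        per_donor = {
            d: evaluate_mlm_loss(model, [p for p in pairs if p.donor_id == d],
                                 batch_size, eval_seed=eval_seed)
            for d in donors
        }
        return per_donor, float(np.mean(list(per_donor.values())))

    rng = np.random.default_rng(eval_seed)
    total, count = 0.0, 0
    for start in range(0, len(pairs), batch_size):
        tokens, special, pad = collate(pairs[start : start + batch_size])
        batch = mask_batch(tokens, special, rng, pad)
        if not batch.selected_mask.any():
            continue
        loss, n = model.evaluate_loss(batch.input_ids, batch.labels, batch.pad_mask)
        total += loss * n
        count += n
    if count == 0:
        raise EvaluationError("no maskable positions in evaluation set")
    return total / count


def select_checkpoint(trajectory: LossTrajectory, patience: int = 3) -> int:
    """Pick the step where evaluation loss starts diverging from training loss.

    Returns the earliest recorded step after which eval loss is
    non-decreasing for ``patience`` consecutive evaluations while train
    loss is non-increasing over the same window; if no such step exists,
    the step of minimum eval loss.
    """
    recs = trajectory.records
    if len(recs) < 2:
        raise ValueError("need at least 2 evaluation points")
    for i in range(len(recs) - patience):
        evals = [recs[j][2] for j in range(i, i + patience + 1)]
        trains = [recs[j][1] for j in range(i, i + patience + 1)]
        if all(a <= b for a, b in zip(evals, evals[1:])) and all(
            a >= b for a, b in zip(trains, trains[1:])
        ):
            return recs[i][0]
    return min(recs, key=lambda r: r[2])[0]
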