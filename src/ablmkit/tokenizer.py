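"""Amino-acid tokenizer for paired heavy/light sequences.

The vocabulary is the 33-symbol ESM-2 token inventory (4 control tokens,
20 canonical residues, 5 non-canonical/ambiguity symbols, 2 gap symbols,
a null token and the mask token), shipped verbatim in
``data/vocab.txt``. A heavy/light pair is laid out as

    <cls> H1..Hn <cls> <cls> L1..Lm <eos>

i.e. the two chains are concatenated with two ``<cls>`` tokens as the
separator, giving ``n + m + 4`` tokens in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["Vocabulary", "TokenizedPair", "get_vocabulary", "tokenize_pair", "detokenize_pair"]

#: residues accepted in input sequences (canonical 20 plus ambiguity X)
INPUT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple

    def __post_init__(self):
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        return self._index[token]

    @property
    def cls_id(self) -> int:
        return self.id("<cls>")

    @property
    def pad_id(self) -> int:
        return self.id("<pad>")

    @property
    def eos_id(self) -> int:
        return self.id("<eos>")

    @property
    def mask_id(self) -> int:
        return self.id("<mask>")

    @property
    def residue_ids(self) -> tuple:
        """Token ids of the 20 canonical residues (random-replacement pool)."""
        return tuple(self.id(a) for a in "LAGVSERTIDPKQNFYMHWC")


_VOCAB = None


def get_vocabulary() -> Vocabulary:
    global _VOCAB
    if _VOCAB is None:
        text = resources.files("ablmkit.data").joinpath("vocab.txt").read_text()
        _VOCAB = Vocabulary(tuple(text.split()))
    return _VOCAB


@dataclass
class TokenizedPair:
    """Token ids plus a per-token flag marking special (never-masked) tokens."""

    token_ids: np.ndarray
    special_mask: np.ndarray  # bool, True = special token
    pair_id: str = ""
    donor_id: str = ""

    def __len__(self) -> int:
        return len(self.token_ids)


def tokenize_pair(heavy_aa: str, light_aa: str, pair_id: str = "", donor_id: str = "") -> TokenizedPair:
    vocab = get_vocabulary()
    for name, seq in (("heavy", heavy_aa), ("light", light_aa)):
        for pos, ch in enumerate(seq):
            if ch not in INPUT_ALPHABET:
                raise TokenizationError(
                    f"{name} chain: character {ch!r} at position {pos} "
                    "is outside the amino-acid alphabet"
                )
    n, m = len(heavy_aa), len(light_aa)
    ids = np.empty(n + m + 4, dtype=np.int64)
    cls = vocab.cls_id
    ids[0] = cls
    ids[1 : n + 1] = [vocab.id(a) for a in heavy_aa]
    ids[n + 1] = cls
    ids[n + 2] = cls
    ids[n + 3 : n + m + 3] = [vocab.id(a) for a in light_aa]
    ids[n + m + 3] = vocab.eos_id
    special = np.zeros(n + m + 4, dtype=bool)
    special[[0, n + 1, n + 2, n + m + 3]] = True
    return TokenizedPair(token_ids=ids, special_mask=special, pair_id=pair_id, donor_id=donor_id)


def detokenize_pair(pair: TokenizedPair) -> tuple:
    """Inverse of :func:`tokenize_pair`: recover (heavy_aa, light_aa)."""
    vocab = get_vocabulary()
    specials = np.flatnonzero(pair.special_mask)
    n = int(specials[1]) - 1
    heavy = "".join(vocab.tokens[i] for i in pair.token_ids[1 : n + 1])
    light = "".join(vocab.tokens[i] for i in pair.token_ids[n + 3 : len(pair.token_ids) - 1])
    return heavy, light
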