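"""Toy germline V/D/J segment libraries.

Real antibody variable regions are assembled from Variable (V), Diversity
(D, heavy chain only) and Joining (J) gene segments drawn from the germline
repertoire. This module builds small synthetic segment libraries with the
structural features the rest of the pipeline relies on:

* V segments carry in-frame, codon-aligned region boundaries for
  FWR1/CDR1/FWR2/CDR2/FWR3 plus a short CDR3 "stub" (germline V genes
  extend a few codons past the FWR3/CDR3 boundary);
* every J segment ends in a fixed-length FWR4 block (``J_FWR4_NT``
  nucleotides) preceded by a CDR3 tail, and is only ever trimmed from its
  5' end so FWR4 survives recombination intact;
* all segment lengths are multiples of 3, so an untrimmed, junction-free
  assembly is automatically in frame.

These are synthetic stand-ins for IMGT-style germline references, not real
gene sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: FWR4 occupies this many nucleotides at the 3' end of every J segment.
J_FWR4_NT = 33  # 11 codons

#: V-region layout in codons (region, length). The CDR3 stub is the part of
#: the germline V gene that extends past the FWR3 boundary into CDR3.
HEAVY_V_LAYOUT = (("FWR1", 25), ("CDR1", 8), ("FWR2", 17), ("CDR2", 8), ("FWR3", 38))
LIGHT_V_LAYOUT = (("FWR1", 23), ("CDR1", 6), ("FWR2", 15), ("CDR2", 3), ("FWR3", 32))
V_CDR3_STUB_CODONS = 2

# CDR3-tail length choices (nt, multiples of 3) for D and J segments.
_D_LENGTHS = (12, 15, 18, 21)
_HEAVY_J_TAILS = (9, 12, 15, 18)
_LIGHT_J_TAILS = (6, 9, 12)

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)


class LibraryConfigError(ValueError):
    """Raised when a segment-library request violates its preconditions."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment.

    ``region_boundaries`` is non-empty only for V segments and lists
    (region_name, start, end) nucleotide intervals, 0-based half-open,
    tiling a prefix of the segment.
    """

    id: str
    chain: str  # "heavy" | "light"
    segment_class: str  # "V" | "D" | "J"
    nt_sequence: str
    region_boundaries: tuple = ()

    def __post_init__(self) -> None:
        if not self.nt_sequence:
            raise ValueError(f"segment {self.id}: empty sequence")
        if set(self.nt_sequence) - set(NUCLEOTIDES):
            raise ValueError(f"segment {self.id}: non-ACGT characters")
        if self.segment_class == "D" and self.chain != "heavy":
            raise ValueError("D segments exist only for the heavy chain")
        if self.region_boundaries:
            pos = 0
            for _, start, end in self.region_boundaries:
                if start != pos or end <= start:
                    raise ValueError(f"segment {self.id}: boundaries must tile a prefix")
                pos = end
            if pos > len(self.nt_sequence):
                raise ValueError(f"segment {self.id}: boundaries exceed sequence")


@dataclass
class GermlineSegmentLibrary:
    """A collection of germline segments plus the seed that built it."""

    segments: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique")

    def by_class(self, chain: str, segment_class: str) -> list:
        return [
            s
            for s in self.segments
            if s.chain == chain and s.segment_class == segment_class
        ]


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """n_codons stop-free codons (uniform over the 61 sense codons)."""
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n)
    return "".join(NUCLEOTIDES[i] for i in idx)


def _make_v(rng, chain: str, name: str) -> GermlineSegment:
    layout = HEAVY_V_LAYOUT if chain == "heavy" else LIGHT_V_LAYOUT
    boundaries = []
    pos = 0
    parts = []
    for region, n_codons in layout:
        parts.append(_random_codons(rng, n_codons))
        boundaries.append((region, pos, pos + 3 * n_codons))
        pos += 3 * n_codons
    parts.append(_random_codons(rng, V_CDR3_STUB_CODONS))
    return GermlineSegment(
        id=name,
        chain=chain,
        segment_class="V",
        nt_sequence="".join(parts),
        region_boundaries=tuple(boundaries),
    )


def _make_d(rng, name: str) -> GermlineSegment:
    length = int(rng.choice(_D_LENGTHS))
    return GermlineSegment(
        id=name, chain="heavy", segment_class="D", nt_sequence=_random_nt(rng, length)
    )


def _make_j(rng, chain: str, name: str) -> GermlineSegment:
    tails = _HEAVY_J_TAILS if chain == "heavy" else _LIGHT_J_TAILS
    tail = _random_nt(rng, int(rng.choice(tails)))
    # FWR4 is generated as sense codons; because its 33 nt sit at the very
    # end of an in-frame assembly it is always read in this frame.
    fwr4 = _random_codons(rng, J_FWR4_NT // 3)
    return GermlineSegment(
        id=name, chain=chain, segment_class="J", nt_sequence=tail + fwr4
    )


def build_toy_library(
    seed: int,
    n_heavy_v: int = 4,
    n_heavy_d: int = 3,
    n_heavy_j: int = 3,
    n_light_v: int = 4,
    n_light_j: int = 3,
) -> GermlineSegmentLibrary:
    """Build a deterministic synthetic segment library.

    Every used (chain, class) combination needs at least 2 segments so
    that gene-usage statistics downstream are non-degenerate.
    """
    counts = {
        ("heavy", "V"): n_heavy_v,
        ("heavy", "D"): n_heavy_d,
        ("heavy", "J"): n_heavy_j,
        ("light", "V"): n_light_v,
        ("light", "J"): n_light_j,
    }
    for key, n in counts.items():
        if n < 2:
            raise LibraryConfigError(f"need >= 2 segments for {key}, got {n}")

    rng = np.random.default_rng(seed)
    segments = []
    for i in range(n_heavy_v):
        segments.append(_make_v(rng, "heavy", f"IGHV-{i + 1:02d}"))
    for i in range(n_heavy_d):
        segments.append(_make_d(rng, f"IGHD-{i + 1:02d}"))
    for i in range(n_heavy_j):
        segments.append(_make_j(rng, "heavy", f"IGHJ-{i + 1:02d}"))
    for i in range(n_light_v):
        segments.append(_make_v(rng, "light", f"IGKV-{i + 1:02d}"))
    for i in range(n_light_j):
        segments.append(_make_j(rng, "light", f"IGKJ-{i + 1:02d}"))
    return GermlineSegmentLibrary(segments=segments, seed=seed)
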