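"""Synthetic paired antibody repertoires.

Simulates the generative process behind natively paired heavy/light chain
sequences at the nucleotide level: V(D)J recombination with junctional
trimming and non-templated (N) nucleotide addition, followed by somatic
hypermutation (SHM) with correlated mutation loads between the two chains
of a pair. Sequences are then translated, and every amino-acid residue is
tagged with its provenance (V, D, J or N) and its region
(FWR1..FWR3, CDR1..CDR3, FWR4).

The simulation is nucleotide-native because trimming, N-addition and
mutation counts are nucleotide-level phenomena; residue-level labels are
derived from the nucleotide labels by codon majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .germline import (
    J_FWR4_NT,
    NUCLEOTIDES,
    GermlineSegmentLibrary,
    LibraryConfigError,
)

__all__ = [
    "RepertoireConfig",
    "PairedAntibody",
    "GenerationError",
    "recombine",
    "apply_shm",
    "generate_repertoire",
    "validate_pair",
]

REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3", "FWR4")
FWR4_AA = J_FWR4_NT // 3

# Codon-level provenance tie-break: junction-ward labels win (N over any
# templated label, D over V/J). J before V is arbitrary but fixed.
_PROVENANCE_PRIORITY = ("N", "D", "J", "V")


class GenerationError(RuntimeError):
    """A bounded resampling budget was exhausted."""


@dataclass
class RepertoireConfig:
    """Knobs of the repertoire simulator.

    Defaults emulate circulating B cells of healthy adult donors: a
    roughly 40% naive (unmutated) fraction, a 2% per-nucleotide SHM rate
    on mutated cells (~6-7 substitutions per chain), mean N-addition
    blocks of ~4.5 nt per junction, and strongly but imperfectly
    correlated heavy/light mutation loads within a native pair.
    """

    n_donors: int = 10
    pairs_per_donor: int = 100
    trim_max: int = 6
    n_addition_length_distribution: dict = field(
        default_factory=lambda: {"kind": "poisson", "mean": 4.5}
    )
    unmutated_fraction: float = 0.4
    shm_rate: float = 0.02
    pairing_correlation: float = 0.8
    seed: int = 0
    #: Dirichlet concentration for per-donor gene-usage weights; ``None``
    #: means all donors use segments uniformly.
    donor_usage_alpha: Optional[float] = None
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.pairs_per_donor < 1:
            raise LibraryConfigError("n_donors and pairs_per_donor must be >= 1")
        if self.trim_max < 0:
            raise LibraryConfigError("trim_max must be >= 0")
        for name in ("unmutated_fraction", "pairing_correlation", "shm_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise LibraryConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PairedAntibody:
    """One natively paired heavy/light antibody with full annotation."""

    pair_id: str
    donor_id: str
    heavy_aa: str
    light_aa: str
    heavy_provenance: str  # per-residue labels in {V, D, J, N}
    light_provenance: str  # per-residue labels in {V, J, N}
    heavy_regions: dict  # region -> (start, end), 0-based half-open in aa
    light_regions: dict
    heavy_mut_count: int
    light_mut_count: int
    v_call: str
    j_call: str
    d_call: Optional[str] = None  # heavy only
    light_v_call: str = ""
    light_j_call: str = ""

    @property
    def is_unmutated(self) -> bool:
        return self.heavy_mut_count == 0 and self.light_mut_count == 0


def sample_n_length(rng: np.random.Generator, dist: dict) -> int:
    kind = dist.get("kind", "poisson")
    if kind == "constant":
        return int(dist["value"])
    if kind == "poisson":
        return int(rng.poisson(dist["mean"]))
    raise LibraryConfigError(f"unknown N-length distribution kind: {kind!r}")


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _choose(rng, segments, weights=None):
    i = int(rng.choice(len(segments), p=weights))
    return segments[i]


def recombine(
    chain: str,
    library: GermlineSegmentLibrary,
    rng: np.random.Generator,
    *,
    trim_max: int = 6,
    n_length_distribution: Optional[dict] = None,
    max_retries: int = 100,
    usage_weights: Optional[dict] = None,
):
    """Assemble one recombined, in-frame, stop-free chain.

    Heavy chains are V' + N1 + D' + N2 + J'; light chains V' + N + J',
    where primes denote trimmed segments. V is trimmed only at its 3' end
    (never into FWR3) and J only at its 5' end (never into FWR4), so the
    region map of the product is always well defined. The reading frame is
    restored, when junctional edits break it, by extending the J (then V,
    then D) trim; sampled N-block lengths are never altered.

    Returns (nt_sequence, nt_provenance, calls) where calls maps
    v_call/d_call/j_call to segment ids.
    """
    if chain not in ("heavy", "light"):
        raise ValueError(f"chain must be 'heavy' or 'light', got {chain!r}")
    n_dist = n_length_distribution or {"kind": "poisson", "mean": 4.5}
    weights = usage_weights or {}

    for _ in range(max_retries):
        v = _choose(rng, library.by_class(chain, "V"), weights.get((chain, "V")))
        j = _choose(rng, library.by_class(chain, "J"), weights.get((chain, "J")))
        v_stub = len(v.nt_sequence) - v.region_boundaries[-1][2]
        j_tail = len(j.nt_sequence) - J_FWR4_NT

        v_trim = int(rng.integers(0, min(trim_max, v_stub) + 1))
        j_trim = int(rng.integers(0, min(trim_max, j_tail) + 1))

        if chain == "heavy":
            d = _choose(rng, library.by_class(chain, "D"), weights.get((chain, "D")))
            d_len = len(d.nt_sequence)
            d5 = int(rng.integers(0, min(trim_max, (d_len - 1) // 2) + 1))
            d3 = int(rng.integers(0, min(trim_max, d_len - d5 - 1) + 1))
            n_lens = [
                sample_n_length(rng, n_dist),
                sample_n_length(rng, n_dist),
            ]
            total_trim = v_trim + d5 + d3 + j_trim
            frame_shift = (sum(n_lens) - total_trim) % 3
        else:
            d = None
            d5 = d3 = 0
            n_lens = [sample_n_length(rng, n_dist)]
            frame_shift = (n_lens[0] - v_trim - j_trim) % 3

        # Restore the reading frame by deepening a templated trim.
        if frame_shift:
            if j_trim + frame_shift <= j_tail:
                j_trim += frame_shift
            elif v_trim + frame_shift <= v_stub:
                v_trim += frame_shift
            elif d is not None and d5 + d3 + frame_shift < len(d.nt_sequence):
                d3 += frame_shift
            else:
                continue  # no room; resample the draw

        v_part = v.nt_sequence[: len(v.nt_sequence) - v_trim]
        j_part = j.nt_sequence[j_trim:]
        parts = [v_part]
        prov = ["V" * len(v_part)]
        if chain == "heavy":
            d_part = d.nt_sequence[d5 : len(d.nt_sequence) - d3]
            n1 = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, n_lens[0]))
            n2 = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, n_lens[1]))
            parts += [n1, d_part, n2, j_part]
            prov += ["N" * len(n1), "D" * len(d_part), "N" * len(n2), "J" * len(j_part)]
        else:
            n1 = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, n_lens[0]))
            parts += [n1, j_part]
            prov += ["N" * len(n1), "J" * len(j_part)]

        nt = "".join(parts)
        assert len(nt) % 3 == 0
        if "*" in _translate(nt):
            continue

        calls = {"v_call": v.id, "j_call": j.id}
        if d is not None:
            calls["d_call"] = d.id
        return nt, "".join(prov), calls

    raise GenerationError(
        f"recombine({chain}): retry budget ({max_retries}) exhausted "
        "while sampling a stop-free junction"
    )


def apply_shm(
    nt_sequence: str,
    target_mut_count: int,
    rng: np.random.Generator,
    max_retries: int = 100,
):
    """Introduce exactly ``target_mut_count`` distinct point substitutions.

    Positions are uniform over the chain; a substitution never reinstates
    the original base. If a substitution creates a stop codon, that single
    substitution is resampled (position and base) rather than redrawing
    the whole set, up to ``max_retries`` repairs.
    """
    L = len(nt_sequence)
    if target_mut_count < 0 or target_mut_count > L:
        raise GenerationError(
            f"target mutation count {target_mut_count} outside [0, {L}]"
        )
    if target_mut_count == 0:
        return nt_sequence, 0

    original = list(nt_sequence)
    seq = list(nt_sequence)
    positions = set(int(p) for p in rng.choice(L, size=target_mut_count, replace=False))
    for p in positions:
        choices = [b for b in NUCLEOTIDES if b != original[p]]
        seq[p] = choices[int(rng.integers(0, 3))]

    for _ in range(max_retries):
        aa = _translate("".join(seq))
        stop = aa.find("*")
        if stop == -1:
            realized = sum(1 for a, b in zip(seq, original) if a != b)
            assert realized == target_mut_count
            return "".join(seq), realized
        # The original is stop-free, so the offending codon contains at
        # least one mutated position; move that mutation elsewhere.
        codon_range = range(3 * stop, 3 * stop + 3)
        p = next(q for q in codon_range if q in positions)
        positions.discard(p)
        seq[p] = original[p]
        candidates = [q for q in range(L) if q not in positions]
        q = candidates[int(rng.integers(0, len(candidates)))]
        choices = [b for b in NUCLEOTIDES if b != original[q]]
        seq[q] = choices[int(rng.integers(0, 3))]
        positions.add(q)

    raise GenerationError(
        f"apply_shm: repair budget ({max_retries}) exhausted avoiding stop codons"
    )


def _aa_provenance(nt_provenance: str) -> str:
    """Collapse per-nucleotide labels to per-residue labels.

    A codon's label is its majority nucleotide label; three-way ties go to
    the most junction-ward label (N over D over J over V).
    """
    out = []
    for i in range(0, len(nt_provenance), 3):
        codon = nt_provenance[i : i + 3]
        best = max(
            set(codon),
            key=lambda lab: (codon.count(lab), -_PROVENANCE_PRIORITY.index(lab)),
        )
        out.append(best)
    return "".join(out)


def _region_map(v_boundaries, aa_len: int) -> dict:
    regions = {}
    for name, start, end in v_boundaries:
        regions[name] = (start // 3, end // 3)
    fwr3_end = regions["FWR3"][1]
    regions["CDR3"] = (fwr3_end, aa_len - FWR4_AA)
    regions["FWR4"] = (aa_len - FWR4_AA, aa_len)
    return regions


def _sample_mut_counts(rng, rho, lam, max_h, max_l):
    """Common-shock Poisson pair: corr(heavy, light) == rho exactly."""
    shared = rng.poisson(rho * lam)
    h = shared + (rng.poisson((1.0 - rho) * lam) if rho < 1.0 else 0)
    l = shared + (rng.poisson((1.0 - rho) * lam) if rho < 1.0 else 0)
    return min(int(h), max_h), min(int(l), max_l)


def generate_repertoire(
    config: RepertoireConfig,
    library: GermlineSegmentLibrary,
    usage_weights: Optional[dict] = None,
) -> list:
    """Generate ``n_donors x pairs_per_donor`` annotated PairedAntibody objects.

    A pair is unmutated (both chains zero substitutions) with probability
    ``unmutated_fraction``; otherwise both chains draw mutation counts from
    a common-shock Poisson model whose Pearson correlation equals
    ``pairing_correlation`` and whose common mean is
    ``shm_rate x mean nucleotide chain length``.
    """
    rng = np.random.default_rng(config.seed)
    pairs = []
    n_v_h = len(library.by_class("heavy", "V"))
    n_v_l = len(library.by_class("light", "V"))

    for donor_idx in range(config.n_donors):
        donor_id = f"donor_{donor_idx:03d}"
        usage = usage_weights
        if usage is None and config.donor_usage_alpha is not None:
            usage = {
                ("heavy", "V"): rng.dirichlet([config.donor_usage_alpha] * n_v_h),
                ("light", "V"): rng.dirichlet([config.donor_usage_alpha] * n_v_l),
            }
        for k in range(config.pairs_per_donor):
            pair_id = f"{donor_id}_p{k:05d}"
            chains = {}
            for chain in ("heavy", "light"):
                nt, prov, calls = recombine(
                    chain,
                    library,
                    rng,
                    trim_max=config.trim_max,
                    n_length_distribution=config.n_addition_length_distribution,
                    max_retries=config.max_retries,
                    usage_weights=usage,
                )
                chains[chain] = {"nt": nt, "prov": prov, "calls": calls}

            if rng.random() < config.unmutated_fraction:
                mut_h = mut_l = 0
            else:
                lam = config.shm_rate * (
                    len(chains["heavy"]["nt"]) + len(chains["light"]["nt"])
                ) / 2.0
                mut_h, mut_l = _sample_mut_counts(
                    rng,
                    config.pairing_correlation,
                    lam,
                    len(chains["heavy"]["nt"]),
                    len(chains["light"]["nt"]),
                )
            for chain, target in (("heavy", mut_h), ("light", mut_l)):
                mutated, realized = apply_shm(
                    chains[chain]["nt"], target, rng, config.max_retries
                )
                chains[chain]["nt"] = mutated
                chains[chain]["mut"] = realized

            h, l = chains["heavy"], chains["light"]
            heavy_aa = _translate(h["nt"])
            light_aa = _translate(l["nt"])
            v_h = next(
                s for s in library.segments if s.id == h["calls"]["v_call"]
            )
            v_l = next(
                s for s in library.segments if s.id == l["calls"]["v_call"]
            )
            pairs.append(
                PairedAntibody(
                    pair_id=pair_id,
                    donor_id=donor_id,
                    heavy_aa=heavy_aa,
                    light_aa=light_aa,
                    heavy_provenance=_aa_provenance(h["prov"]),
                    light_provenance=_aa_provenance(l["prov"]),
                    heavy_regions=_region_map(v_h.region_boundaries, len(heavy_aa)),
                    light_regions=_region_map(v_l.region_boundaries, len(light_aa)),
                    heavy_mut_count=h["mut"],
                    light_mut_count=l["mut"],
                    v_call=h["calls"]["v_call"],
                    d_call=h["calls"].get("d_call"),
                    j_call=h["calls"]["j_call"],
                    light_v_call=l["calls"]["v_call"],
                    light_j_call=l["calls"]["j_call"],
                )
            )
    return pairs


def validate_pair(pair: PairedAntibody) -> None:
    """Assert the structural invariants of a PairedAntibody."""
    for aa, prov, regions, labels in (
        (pair.heavy_aa, pair.heavy_provenance, pair.heavy_regions, set("VDJN")),
        (pair.light_aa, pair.light_provenance, pair.light_regions, set("VJN")),
    ):
        assert len(prov) == len(aa), "provenance length mismatch"
        assert set(prov) <= labels, f"unexpected provenance labels {set(prov)}"
        covered = sorted(regions[r] for r in REGIONS)
        pos = 0
        for start, end in covered:
            assert start == pos, "regions must tile without gaps"
            assert end >= start
            pos = end
        assert pos == len(aa), "regions must cover the full chain"
        c3_start, c3_end = regions["CDR3"]
        for i, lab in enumerate(prov):
            if lab == "N":
                assert c3_start <= i < c3_end, "N residue outside CDR3"
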