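"""Reading and writing repertoires: AIRR-flavoured TSV and paired FASTA."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repertoire import PairedAntibody, RepertoireConfig

__all__ = [
    "write_repertoire_tsv",
    "read_repertoire_tsv",
    "write_paired_fasta",
    "read_config",
    "write_config",
]

_TSV_COLUMNS = [
    "pair_id", "donor_id",
    "heavy_sequence_aa", "light_sequence_aa",
    "heavy_provenance", "light_provenance",
    "heavy_regions", "light_regions",
    "heavy_v_call", "heavy_d_call", "heavy_j_call",
    "light_v_call", "light_j_call",
    "heavy_mut_count", "light_mut_count",
]


def _regions_to_str(regions: dict) -> str:
    return ";".join(f"{name}:{s}-{e}" for name, (s, e) in sorted(regions.items(), key=lambda kv: kv[1]))


def _regions_from_str(text: str) -> dict:
    out = {}
    for part in text.split(";"):
        name, span = part.split(":")
        s, e = span.split("-")
        out[name] = (int(s), int(e))
    return out


def write_repertoire_tsv(pairs, path) -> None:
    rows = [
        {
            "pair_id": p.pair_id,
            "donor_id": p.donor_id,
            "heavy_sequence_aa": p.heavy_aa,
            "light_sequence_aa": p.light_aa,
            "heavy_provenance": p.heavy_provenance,
            "light_provenance": p.light_provenance,
            "heavy_regions": _regions_to_str(p.heavy_regions),
            "light_regions": _regions_to_str(p.light_regions),
            "heavy_v_call": p.v_call,
            "heavy_d_call": p.d_call or "",
            "heavy_j_call": p.j_call,
            "light_v_call": p.light_v_call,
            "light_j_call": p.light_j_call,
            "heavy_mut_count": p.heavy_mut_count,
            "light_mut_count": p.light_mut_count,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repertoire_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            PairedAntibody(
                pair_id=row.pair_id,
                donor_id=row.donor_id,
                heavy_aa=row.heavy_sequence_aa,
                light_aa=row.light_sequence_aa,
                heavy_provenance=row.heavy_provenance,
                light_provenance=row.light_provenance,
                heavy_regions=_regions_from_str(row.heavy_regions),
                light_regions=_regions_from_str(row.light_regions),
                heavy_mut_count=int(row.heavy_mut_count),
                light_mut_count=int(row.light_mut_count),
                v_call=row.heavy_v_call,
                d_call=row.heavy_d_call or None,
                j_call=row.heavy_j_call,
                light_v_call=row.light_v_call,
                light_j_call=row.light_j_call,
            )
        )
    return pairs


def write_paired_fasta(pairs, path) -> None:
    """Two records per pair, ids '<pair_id>|H' and '<pair_id>|L'."""
    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.heavy_aa), id=f"{p.pair_id}|H", description=""))
        records.append(SeqRecord(Seq(p.light_aa), id=f"{p.pair_id}|L", description=""))
    SeqIO.write(records, str(path), "fasta")


def write_config(config: RepertoireConfig, path) -> None:
    Path(path).write_text(json.dumps(config.__dict__, indent=1))


def read_config(path) -> RepertoireConfig:
    return RepertoireConfig(**json.loads(Path(path).read_text()))
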