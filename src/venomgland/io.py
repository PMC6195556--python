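"""Plain-text IO: FASTQ (phred+33), FASTA, TSV matrices."""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import MergedRead, SequencingRead


def write_fastq(path, reads: Iterable) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path, sample_id: str = "", lane_id: str = "",
               mate: int = 1) -> List[SequencingRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            SequencingRead(
                id=rec.id,
                sequence=str(rec.seq),
                quality=tuple(rec.letter_annotations["phred_quality"]),
                sample_id=sample_id,
                lane_id=lane_id,
                mate=mate,
            )
        )
    return out


def read_merged_fastq(path, sample_id: str = "") -> List[MergedRead]:
    return [
        MergedRead(
            id=rec.id,
            sequence=str(rec.seq),
            quality=tuple(rec.letter_annotations["phred_quality"]),
            sample_id=sample_id,
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(path, records: Iterable[Tuple[str, str, str]]) -> None:
    """Write (id, description, sequence) triples."""
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=rid, description=desc)
            for rid, desc, seq in records
        ],
        str(path),
        "fasta",
    )


def read_fasta(path) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_tsv(path, df: pd.DataFrame, index_label: str = "id") -> None:
    df.to_csv(str(path), sep="\t", index_label=index_label)


def read_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=index_col)
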