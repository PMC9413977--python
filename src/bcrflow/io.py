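"""Reading and writing the package's on-disk formats.

Germline libraries travel as FASTA plus a sidecar anchor TSV (name, class,
chain, anchor, frame); reads as paired Phred+33 FASTQ; chain and clone
tables as TSV; processing reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import ReadPair
from .simulate import GermlineSegment, SimulatedReadPair

__all__ = [
    "write_germline",
    "read_germline",
    "write_fastq_pairs",
    "read_fastq_pairs",
    "write_tsv",
    "read_tsv",
    "write_report",
]


def write_germline(
    segments: Sequence[GermlineSegment], fasta_path: str | Path, anchors_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description="") for s in segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "name": s.name,
                "segment_class": s.segment_class,
                "chain": s.chain,
                "anchor": s.anchor,
                "frame": s.frame,
            }
            for s in segments
        ]
    ).to_csv(anchors_path, sep="\t", index=False)


def read_germline(
    fasta_path: str | Path, anchors_path: str | Path
) -> list[GermlineSegment]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    anchors = pd.read_csv(anchors_path, sep="\t")
    segments = []
    for row in anchors.itertuples():
        if row.name not in seqs:
            raise ValueError(f"anchor row {row.name} missing from FASTA")
        segments.append(
            GermlineSegment(
                name=row.name,
                segment_class=row.segment_class,
                chain=row.chain,
                sequence=seqs[row.name],
                anchor=int(row.anchor),
                frame=int(row.frame),
            )
        )
    return segments


def _phred_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_fastq_pairs(
    pairs: Sequence[SimulatedReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{_phred_string(p.qual1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{_phred_string(p.qual2)}\n")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    out = []
    r1 = SeqIO.parse(str(r1_path), "fastq")
    r2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(r1, r2):
        id1 = rec1.id.removesuffix("/1")
        id2 = rec2.id.removesuffix("/2")
        if id1 != id2:
            raise ValueError(f"unpaired reads: {rec1.id} vs {rec2.id}")
        out.append(
            ReadPair(
                id=id1,
                seq1=str(rec1.seq),
                seq2=str(rec2.seq),
                qual1=tuple(rec1.letter_annotations["phred_quality"]),
                qual2=tuple(rec2.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
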