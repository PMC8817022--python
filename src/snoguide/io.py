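"""FASTA and BED6 helpers (thin wrappers over Biopython / pandas)."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in BED6_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"BED6 frame lacks columns {missing}")
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
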