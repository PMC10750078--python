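"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Bio.SeqIO; BED6 (0-based half-open, score column carries peak
signal), GWAS/LD/eQTL TSVs and EMSA lane CSVs via pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(chromosomes: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in chromosomes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
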