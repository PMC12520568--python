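"""File formats: FASTA genomes, TSV pileups/tables, BED6 gene models,
bedGraph level tracks.

Coordinates are 0-based half-open throughout, matching the BED
ecosystem; TSV headers start with '#' and name every column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta", "read_fasta",
    "write_pileup", "read_pileup",
    "write_genes_bed", "read_genes_bed",
    "write_bedgraph", "write_table", "read_table",
]

PILEUP_COLUMNS = ["contig", "pos", "strand", "context", "count_C", "count_T"]


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_pileup(pileup: pd.DataFrame, path) -> None:
    """TSV with header '#contig pos strand context count_C count_T'
    (pos 0-based)."""
    out = pileup[PILEUP_COLUMNS].rename(columns={"contig": "#contig"})
    out.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"#contig": "contig"})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup {path} missing columns {sorted(missing)}")
    return df[PILEUP_COLUMNS]


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """BED6: contig, start, end, gene_id, score 0, strand."""
    bed = genes[["contig", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = genes["strand"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["contig", "start", "end", "gene_id", "score",
                             "strand"])
    bed["tss"] = bed["start"].where(bed["strand"] == "+", bed["end"])
    return bed[["gene_id", "contig", "start", "end", "strand", "tss"]]


def write_bedgraph(sites: pd.DataFrame, value_column: str, path) -> None:
    """Per-site level track (0-based half-open single-base intervals)."""
    bg = pd.DataFrame({"contig": sites["contig"], "start": sites["pos"],
                       "end": sites["pos"] + 1,
                       "value": sites[value_column]})
    bg.to_csv(path, sep="\t", index=False, header=False,
              float_format="%.6g")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
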