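"""Readers and writers for the standard flat formats the pipeline consumes.

BED is kept 0-based half-open as-is; GFF3 gene rows are converted from
1-based closed to 0-based half-open on read. FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from recfin import intervals as iv
from recfin.features import GenomeAnnotation


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ -> chrom/start/end (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return iv.sort_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end"])


def read_gff_genes(path: str | Path,
                   chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Gene rows from a GFF3 file as a GenomeAnnotation (no CGI/TE tracks)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), parts[6],
                         attrs.get("ID", f"gene{len(rows)}")))
    genes = iv.sort_intervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id"]))
    lengths = chrom_lengths or {
        c: int(s["end"].max()) for c, s in genes.groupby("chrom", sort=False)}
    return GenomeAnnotation(genes=genes, chrom_lengths=lengths)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_lift_table(path: str | Path) -> pd.DataFrame:
    """Paired-BED collinear block table: q_chrom q_start q_end t_chrom t_start t_end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["q_chrom", "q_start", "q_end",
                            "t_chrom", "t_start", "t_end"])
    return df
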