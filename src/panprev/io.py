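"""File-format helpers: FASTA collections, metadata and cluster tables.

Per-genome FASTA files use ``<genome_id>|<gene_id>`` headers; a collection
directory holds ``<genome_id>.faa`` (proteins), optional ``<genome_id>.fna``
(CDSs) and ``metadata.tsv`` (genome_id, species, niche).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .cluster import GeneFamily
from .records import GenomeRecord


def read_fasta_genes(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse ``genome|gene`` headed FASTA into (genome_id, gene_id, seq)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome_id, sep, gene_id = rec.id.partition("|")
        if not sep:
            raise ValueError(
                f"{path}: header {rec.id!r} is not in <genome_id>|<gene_id> form"
            )
        out.append((genome_id, gene_id, str(rec.seq).upper()))
    return out


def read_collection(indir: str | Path) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Load a collection directory written by :func:`simulate.write_collection`."""
    indir = Path(indir)
    meta_path = indir / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.tsv in {indir}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    records = []
    for _, row in meta.iterrows():
        gid = row["genome_id"]
        faa = indir / f"{gid}.faa"
        if not faa.exists():
            raise FileNotFoundError(f"missing protein FASTA for genome {gid}")
        proteins = [(g, s) for _, g, s in read_fasta_genes(faa)]
        fna = indir / f"{gid}.fna"
        cds: Optional[list[tuple[str, str]]] = None
        if fna.exists():
            cds = [(g, s) for _, g, s in read_fasta_genes(fna)]
        records.append(
            GenomeRecord(
                genome_id=gid,
                species=row.get("species", gid),
                niche=row["niche"],
                proteins=proteins,
                cds=cds,
            )
        )
    return records, meta


def collection_proteins(records: list[GenomeRecord]) -> list[tuple[str, str, str]]:
    """Flatten records into clustering input triples."""
    return [
        (rec.genome_id, gene_id, seq)
        for rec in records
        for gene_id, seq in rec.proteins
    ]


def write_cluster_table(families: list[GeneFamily], path: str | Path) -> None:
    """Tab-separated cluster table (one line per gene, retained or removed)."""
    with open(path, "w") as fh:
        fh.write("family_id\trepresentative\tgenome_id\tgene_id\tstatus\n")
        for fam in families:
            rep = f"{fam.representative[0]}|{fam.representative[1]}"
            for (genome_id, gene_id) in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{rep}\t{genome_id}\t{gene_id}\tretained\n")
            for (genome_id, gene_id) in sorted(fam.removed_paralogs):
                fh.write(
                    f"{fam.family_id}\t{rep}\t{genome_id}\t{gene_id}\tparalog_removed\n"
                )


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
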