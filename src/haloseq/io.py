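"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts are genes-by-samples TSVs with a ``feature_id`` index column; design
tables are sample-per-row TSVs with ``sample_id``, ``fraction`` (input or
pulldown), ``condition`` and ``replicate`` columns.  FASTA goes through
Biopython, genomes are read back through pyfaidx for random access.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import TranscriptModel

FRACTIONS = ("input", "pulldown")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def open_genome(path: str | Path):
    """Random-access genome handle (pyfaidx); builds the .fai index on demand."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Emit gene/transcript/exon (and three_prime_utr) rows, 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            span_s, span_e = m.span
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.gene_class}";'
            )
            gene_attrs = f'gene_id "{m.gene_id}"; gene_biotype "{m.gene_class}";'
            fh.write(
                f"{m.chrom}\thaloseq\tgene\t{span_s + 1}\t{span_e}\t.\t{m.strand}\t.\t{gene_attrs}\n"
            )
            fh.write(
                f"{m.chrom}\thaloseq\ttranscript\t{span_s + 1}\t{span_e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chrom}\thaloseq\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )
            if m.utr3 is not None:
                us, ue = m.utr3
                fh.write(
                    f"{m.chrom}\thaloseq\tthree_prime_utr\t{us + 1}\t{ue}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "fraction", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(design["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"design table has unknown fractions: {sorted(bad)}")
    return design
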