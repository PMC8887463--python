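"""Dual spliced/unspliced transcriptome construction and annotation-derived intervals.

Proximity-labeling experiments read out chromatin- and nucleus-associated RNA
through two sequence-level signatures: retained introns (unspliced pre-mRNA)
and promoter-proximal upstream antisense transcripts (uaRNAs).  This module
turns a genome plus GTF annotation into the reference objects those signatures
are quantified against:

* a dual transcriptome holding, for every transcript, a spliced entry
  (introns removed) and an unspliced entry (all introns retained);
* strand-aware windows immediately upstream of each gene's TSS, on the
  opposite strand, in which uaRNA abundance is counted;
* per-gene 3' UTR sequences (longest UTR per gene) for sequence-feature
  analyses.

Coordinates are 0-based half-open internally.  GTF is read and written as
1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SPLICED_SUFFIX = "|spliced"
UNSPLICED_SUFFIX = "|unspliced"
ANTISENSE_SUFFIX = "|ua"


@dataclass
class TranscriptModel:
    """Exon structure of one transcript, 0-based half-open genomic coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int] | None = None
    gene_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"malformed annotation: transcript {self.transcript_id} has "
                f"unknown strand {self.strand!r}"
            )
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.transcript_id}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span of the unspliced transcript: first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site (strand aware)."""
        return self.span[0] if self.strand == "+" else self.span[1] - 1

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def unspliced_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class AntisenseWindow:
    """Window upstream of a gene's TSS on the opposite strand (uaRNA territory)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def _genome_slice(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) from a dict of strings or a pyfaidx.Fasta."""
    record = genome[chrom]
    if isinstance(record, str):
        length = len(record)
    else:  # pyfaidx FastaRecord
        length = len(record)
    if start < 0 or end > length:
        raise ValueError(
            f"annotation/genome mismatch: interval [{start},{end}) outside "
            f"{chrom} (length {length})"
        )
    seq = record[start:end]
    return seq if isinstance(seq, str) else str(seq)


def chromosome_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def transcripts_from_gtf(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models (exons, 3' UTRs, biotypes).

    Uses an in-memory gffutils database; ``three_prime_utr`` features, when
    present, supply the UTR interval (the widest one per transcript).
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for tr in db.features_of_type("transcript", order_by=("seqid", "start")):
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(tr, featuretype="exon", order_by="start")
        ]
        utrs = [
            (u.start - 1, u.end)
            for u in db.children(tr, featuretype="three_prime_utr", order_by="start")
        ]
        utr3 = None
        if utrs:
            utr3 = (min(s for s, _ in utrs), max(e for _, e in utrs))
        biotype = tr.attributes.get("gene_biotype", ["protein_coding"])[0]
        models.append(
            TranscriptModel(
                transcript_id=tr.attributes["transcript_id"][0],
                gene_id=tr.attributes["gene_id"][0],
                chrom=tr.seqid,
                strand=tr.strand,
                exons=exons,
                utr3=utr3,
                gene_class=biotype,
            )
        )
    return models


def spliced_sequence(genome, model: TranscriptModel) -> str:
    """Concatenated exon sequence in transcript orientation."""
    seq = "".join(_genome_slice(genome, model.chrom, s, e) for s, e in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def unspliced_sequence(genome, model: TranscriptModel) -> str:
    """Full genomic span (introns retained) in transcript orientation."""
    s, e = model.span
    seq = _genome_slice(genome, model.chrom, s, e)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def build_dual_transcriptome(
    genome, annotation: Iterable[TranscriptModel]
) -> dict[str, str]:
    """Build the two-entry-per-transcript reference.

    Every transcript contributes ``<id>|spliced`` (introns removed) and
    ``<id>|unspliced`` (introns retained); both are reported in transcript
    orientation, i.e. minus-strand entries are reverse-complemented.
    """
    out: dict[str, str] = {}
    for model in annotation:
        out[model.transcript_id + SPLICED_SUFFIX] = spliced_sequence(genome, model)
        out[model.transcript_id + UNSPLICED_SUFFIX] = unspliced_sequence(genome, model)
    return out


def define_antisense_windows(
    annotation: Iterable[TranscriptModel],
    window_length: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[AntisenseWindow]:
    """One promoter-proximal upstream window per gene, on the opposite strand.

    The window abuts the gene's 5'-most TSS and extends ``window_length``
    nucleotides upstream (in gene orientation), clipped at chromosome
    boundaries.  By construction it never overlaps its own gene body.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    # 5'-most TSS and gene body extent per gene
    genes: dict[str, list[TranscriptModel]] = {}
    for m in annotation:
        genes.setdefault(m.gene_id, []).append(m)
    windows: list[AntisenseWindow] = []
    for gene_id, models in genes.items():
        chrom = models[0].chrom
        strand = models[0].strand
        body_start = min(m.span[0] for m in models)
        body_end = max(m.span[1] for m in models)
        if strand == "+":
            start, end = body_start - window_length, body_start
        else:
            start, end = body_end, body_end + window_length
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[chrom])
        windows.append(
            AntisenseWindow(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=max(start, end),
                strand="-" if strand == "+" else "+",
            )
        )
    return windows


def extract_3utrs(genome, annotation: Iterable[TranscriptModel]) -> dict[str, str]:
    """Per-gene 3' UTR sequences in transcript orientation.

    Transcripts without an annotated 3' UTR are skipped (count logged).  When
    a gene has several UTR-bearing transcripts, the longest UTR represents the
    gene, so each gene contributes exactly one background unit to downstream
    Fisher tests.
    """
    best: dict[str, tuple[int, TranscriptModel]] = {}
    skipped = 0
    for m in annotation:
        if m.utr3 is None:
            skipped += 1
            continue
        length = m.utr3[1] - m.utr3[0]
        if m.gene_id not in best or length > best[m.gene_id][0]:
            best[m.gene_id] = (length, m)
    if skipped:
        logger.info("extract_3utrs: skipped %d transcripts without 3' UTR", skipped)
    out: dict[str, str] = {}
    for gene_id, (_, m) in best.items():
        s, e = m.utr3  # type: ignore[misc]
        seq = _genome_slice(genome, m.chrom, s, e)
        if m.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[gene_id] = seq
    return out


def windows_to_bed(windows: Iterable[AntisenseWindow], path: str | Path) -> None:
    """Write antisense windows as 6-column BED (0-based half-open, strand-aware)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}{ANTISENSE_SUFFIX}\t0\t{w.strand}\n")
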