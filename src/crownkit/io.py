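"""File I/O helpers: FASTA, gzipped FASTQ, BED/GTF, TSV tables.

All text formats; FASTQ is written gzip-compressed as sequencers deliver
it.  Reads are handled as plain tuples ``(read_id, seq1, qual1, seq2,
qual2)`` to keep large simulated libraries cheap in memory.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ReadPair = tuple[str, str, str, str, str]


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(reads: Iterable[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write paired reads to <prefix>_R1.fastq.gz / <prefix>_R2.fastq.gz."""
    p1 = Path(f"{prefix}_R1.fastq.gz")
    p2 = Path(f"{prefix}_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for rid, s1, q1, s2, q2 in reads:
            f1.write(f"@{rid}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{q2}\n")
    return p1, p2


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pair(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    with _open_maybe_gz(path1) as f1, _open_maybe_gz(path2) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            yield rec1.id, str(rec1.seq), q1, str(rec2.seq), q2


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    """BED6 of annotated TSS positions (0-based, half-open)."""
    with open(path, "w") as fh:
        for row in tss.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.gene_id}\t0\t{row.strand}\n")


def write_tss_gtf(tss: pd.DataFrame, path: str | Path) -> None:
    """Minimal GTF transcript records; the strand-aware 5' end is the TSS."""
    with open(path, "w") as fh:
        for i, row in enumerate(tss.itertuples(index=False)):
            # nominal 50-nt transcript body downstream of the TSS
            if row.strand == "+":
                start, end = row.pos + 1, row.pos + 50  # GTF is 1-based inclusive
            else:
                start, end = max(1, row.pos + 1 - 49), row.pos + 1
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}.t{i}"; '
                f'gene_type "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\tcrownkit\ttranscript\t{start}\t{end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_tss_annotation(path: str | Path) -> pd.DataFrame:
    """Read TSS annotation from BED6 or GTF (transcript records).

    Returns columns chrom, pos (0-based TSS), strand, gene_id, biotype.
    """
    path = str(path)
    rows = []
    if path.endswith((".gtf", ".gff")):
        with _open_maybe_gz(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "transcript":
                    continue
                chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
                pos = start - 1 if strand == "+" else end - 1
                gene_id = _gtf_attr(attrs, "gene_id")
                biotype = _gtf_attr(attrs, "gene_type") or "other"
                rows.append((chrom, pos, strand, gene_id, biotype))
    else:
        with _open_maybe_gz(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, name = f[0], int(f[1]), f[3] if len(f) > 3 else "."
                strand = f[5] if len(f) > 5 else "+"
                rows.append((chrom, start, strand, name, "other"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id", "biotype"])


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return ""


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
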