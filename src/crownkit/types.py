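"""Shared domain types.

Coordinates are 0-based throughout; intervals are half-open.  Strand is
"+" or "-".  A transcription-start nucleotide (TSN) position always refers
to the genomic coordinate of the transcript's first template base, and base
identities attached to a TSN are in transcript (mRNA) sense.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


class ConfigurationError(ValueError):
    """Raised for invalid simulator / pipeline configuration."""


VALID_UMI_LENGTHS = (8, 11)
SPACER = "ATAT"


@dataclass
class SimConfig:
    """Parameters of one simulated library.

    conversion_efficiency is the probability that an unmethylated A on the
    transcript is deaminated (and hence read as G); methylated positions
    (m6Am at the TSN, internal m6A) always resist conversion.
    background_rate is the fraction of reads whose 5' end is a
    uniform-random genomic position rather than a true TSN, emulating
    residual uncapped fragments that survive the cap enrichment.
    """

    umi_len: int = 11
    spacer: str = SPACER
    read_len: int = 50
    depth: int = 10_000
    conversion_efficiency: float = 1.0
    background_rate: float = 0.07
    seq_error_rate: float = 0.001
    fragment_len: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.umi_len not in VALID_UMI_LENGTHS:
            raise ConfigurationError(f"umi_len must be one of {VALID_UMI_LENGTHS}")
        if self.spacer != SPACER:
            raise ConfigurationError(f"spacer must be exactly {SPACER!r}")
        for name in ("conversion_efficiency", "background_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.read_len <= self.umi_len + len(self.spacer):
            raise ConfigurationError(
                "read_len must exceed umi_len + spacer length "
                f"({self.umi_len} + {len(self.spacer)})"
            )
        if self.fragment_len < 1:
            raise ConfigurationError("fragment_len must be >= 1")


@dataclass
class IsoformTruth:
    """Ground truth for one simulated 5' isoform."""

    gene_id: str
    chrom: str
    tsn_pos: int
    strand: str
    tsn_base: str
    relative_abundance: float
    stoichiometry: Optional[float] = None  # m6Am fraction; A TSNs only
    internal_m6a: tuple[tuple[int, float], ...] = ()  # (offset from TSN, fraction)

    def __post_init__(self) -> None:
        if self.tsn_base != "A":
            self.stoichiometry = None


@dataclass
class ReferencePack:
    """Genome + annotation + simulation ground truth.

    genome maps chromosome name to sequence.  tss is a table of annotated
    TSS positions (chrom, pos, strand, gene_id, biotype).  truth is the
    per-isoform ground-truth table mirroring IsoformTruth.
    """

    genome: dict[str, str]
    tss: pd.DataFrame
    truth: pd.DataFrame

    def isoforms(self) -> list[IsoformTruth]:
        out = []
        for row in self.truth.itertuples(index=False):
            out.append(
                IsoformTruth(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    tsn_pos=int(row.tsn_pos),
                    strand=row.strand,
                    tsn_base=row.tsn_base,
                    relative_abundance=float(row.relative_abundance),
                    stoichiometry=None if pd.isna(row.stoichiometry) else float(row.stoichiometry),
                    internal_m6a=tuple(row.internal_m6a),
                )
            )
        return out


@dataclass
class ReadRecord:
    """One read pair after UMI/spacer extraction."""

    read_id: str
    umi: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class AlignmentRecord:
    """One (candidate or accepted) paired alignment, in original base space.

    five_prime_pos is the genomic coordinate of read 1's first base (the
    TSN if the read starts at a transcription start).  score is the summed
    converted-space alignment score of both mates (higher is better);
    second_best_score is the score of the runner-up candidate or None.
    restored_seq holds read 1's original (pre-in-silico-conversion) bases
    in transcript sense.
    """

    read_id: str
    chrom: str
    strand: str
    five_prime_pos: int
    score: float
    second_best_score: Optional[float] = None
    softclip5: int = 0
    restored_seq: str = ""
    umi: str = ""

    def replace(self, **kw) -> "AlignmentRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class TSNRecord:
    """Deduplicated 5'-end pileup at one (chrom, pos, strand)."""

    chrom: str
    pos: int
    strand: str
    depth: int
    a_count: int
    c_count: int
    g_count: int
    t_count: int
    nonconversion: Optional[float] = None
    gene_id: Optional[str] = None
    annotation_class: str = "unassigned"


@dataclass
class TSSAnnotation:
    """One annotated transcription-start site."""

    chrom: str
    pos: int
    strand: str
    gene_id: str
    biotype: str  # snRNA, snoRNA, protein_coding, lncRNA, other


@dataclass
class GeneSummary:
    """Per-gene aggregation of TSN usage and methylation.

    pct_m6Am / pct_Am / pct_nonA partition 100% of the gene's TSN reads
    into m6Am-initiated, Am-initiated and non-A-initiated transcripts.
    """

    gene_id: str
    frac_A: float
    mean_methylation: float
    pct_m6Am: float
    pct_Am: float
    pct_nonA: float
    m6am_gene_index: float = field(default=float("nan"))
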