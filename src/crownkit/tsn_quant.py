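"""UMI deduplication, 5'-end pileup and m6Am stoichiometry.

A transcription-start nucleotide (TSN) is an observed (chrom, pos, strand)
5'-end after deduplication.  Methylation stoichiometry at an A-TSN is the
non-conversion rate A/(A+G): reads retaining A carry m6Am, converted reads
(read as G) carried unmethylated Am.  C/T observations (sequencing errors)
count toward depth but are excluded from the A/(A+G) denominator.

Identification requires 20 deduplicated reads summed across replicates;
quantification additionally requires 50 reads at the site.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from crownkit.types import AlignmentRecord

IDENT_MIN_READS = 20
QUANT_MIN_READS = 50

PILEUP_COLUMNS = [
    "chrom", "pos", "strand", "depth",
    "a_count", "c_count", "g_count", "t_count", "nonconversion",
]


def dedup_umis(alignments: Iterable[AlignmentRecord]) -> tuple[list[AlignmentRecord], int]:
    """Collapse PCR duplicates: one record per (chrom, pos, strand, UMI).

    Retention is deterministic: highest alignment score, then smallest
    read_id.  Records without a UMI are skipped; their count is returned
    alongside the deduplicated list.
    """
    best: dict[tuple[str, int, str, str], AlignmentRecord] = {}
    n_missing = 0
    for a in alignments:
        if not a.umi:
            n_missing += 1
            continue
        key = (a.chrom, a.five_prime_pos, a.strand, a.umi)
        cur = best.get(key)
        if cur is None or (-a.score, a.read_id) < (-cur.score, cur.read_id):
            best[key] = a
    ordered = sorted(best.values(), key=lambda a: (a.chrom, a.five_prime_pos, a.strand, a.umi))
    return ordered, n_missing


def nonconversion(a_count: int, g_count: int) -> Optional[float]:
    """A/(A+G); None (undefined) when no A or G was observed."""
    total = a_count + g_count
    if total == 0:
        return None
    return a_count / total


def pileup_tsn(alignments: Sequence[AlignmentRecord]) -> pd.DataFrame:
    """One row per observed (chrom, pos, strand) 5' end.

    Base counts come from the restored (original) read-1 first base, which
    is already in transcript sense; total depth over the table equals the
    number of input records.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in alignments:
        key = (a.chrom, a.five_prime_pos, a.strand)
        vec = counts.setdefault(key, [0, 0, 0, 0, 0])
        vec[4] += 1
        b = a.restored_seq[:1]
        if b in base_idx:
            vec[base_idx[b]] += 1
    rows = []
    for (chrom, pos, strand), (na, nc, ng, nt, depth) in sorted(counts.items()):
        rows.append((chrom, pos, strand, depth, na, nc, ng, nt, nonconversion(na, ng)))
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return df


def call_tsns(
    tables: pd.DataFrame | Sequence[pd.DataFrame], min_reads: int = IDENT_MIN_READS
) -> pd.DataFrame:
    """Identify TSNs with summed depth >= min_reads across replicates.

    Accepts one pileup table or a list of replicate tables; replicate
    depths and base counts are summed before thresholding.
    """
    if isinstance(tables, pd.DataFrame):
        merged = tables.copy()
    else:
        merged = (
            pd.concat(tables, ignore_index=True)
            .groupby(["chrom", "pos", "strand"], as_index=False)[
                ["depth", "a_count", "c_count", "g_count", "t_count"]
            ]
            .sum()
        )
        merged["nonconversion"] = [
            nonconversion(a, g) for a, g in zip(merged["a_count"], merged["g_count"])
        ]
    merged["identified"] = merged["depth"] >= min_reads
    return merged


def quantify_m6am(table: pd.DataFrame, min_reads: int = QUANT_MIN_READS) -> pd.DataFrame:
    """Report stoichiometry (= non-conversion) only at depth >= min_reads.

    Sites below the depth threshold are flagged low_coverage and carry no
    stoichiometry estimate."""
    out = table.copy()
    out["low_coverage"] = out["depth"] < min_reads
    stoich = []
    for row in out.itertuples(index=False):
        if row.depth >= min_reads and (row.a_count + row.g_count) > 0:
            stoich.append(row.a_count / (row.a_count + row.g_count))
        else:
            stoich.append(np.nan)
    out["stoichiometry"] = stoich
    return out


def tpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalized expression: TPM_i = depth_i / sum(depth) * 1e6."""
    total = table["depth"].sum()
    if total <= 0:
        raise ValueError("zero total depth; cannot normalize")
    out = table.copy()
    out["tpm"] = out["depth"] / total * 1e6
    return out


def pileup_internal(
    alignments: Sequence[AlignmentRecord], genome: dict[str, str]
) -> pd.DataFrame:
    """Pile up read bodies at internal (non-5'-end) adenosine positions.

    Counts transcript-sense A/G observations at every covered genomic
    position whose transcript-sense reference base is A, skipping each
    read's first base (that is the TSN).  Used for 5'-proximal internal
    m6A detection."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    counts: dict[tuple[str, int, str], list[int]] = {}
    for a in alignments:
        seq = a.restored_seq
        chrom_seq = genome[a.chrom]
        step = 1 if a.strand == "+" else -1
        for i in range(1, len(seq)):
            gpos = a.five_prime_pos + step * i
            if not 0 <= gpos < len(chrom_seq):
                continue
            ref_fwd = chrom_seq[gpos]
            ref_ts = ref_fwd if a.strand == "+" else comp.get(ref_fwd, "N")
            if ref_ts != "A":
                continue
            obs = seq[i]
            if obs not in ("A", "G"):
                continue
            vec = counts.setdefault((a.chrom, gpos, a.strand), [0, 0])
            vec[0 if obs == "A" else 1] += 1
    rows = [
        (chrom, pos, strand, na + ng, na, ng, nonconversion(na, ng))
        for (chrom, pos, strand), (na, ng) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "depth", "a_count", "g_count", "nonconversion"]
    )
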