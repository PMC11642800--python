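"""Downstream statistics on quantified TSN tables.

Per-gene composition partitions a gene's transcript starts into
m6Am-initiated, Am-initiated and non-A-initiated fractions; the m6Am gene
index is the read-weighted fraction of all of a gene's TSN reads that are
m6Am.  Promoter analyses classify each A-TSN by its initiator-like TSS
motif (SSCA+1GC, BBCA+1BW, VA+1RR, BA+1) and scan for a TATAWAWR TATA-box
in the -36..-19 window.  Calibration against barcoded standards, per-site
condition deltas (writer/eraser knockouts) and 5'-proximal internal m6A
calling complete the module.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crownkit.simulate import reverse_complement
from crownkit.types import GeneSummary

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

# TSS motifs at fixed offsets relative to the start nucleotide (+1).
# Precedence: longer/more specific motifs first.
TSS_MOTIFS = (
    ("SSCA+1GC", ((-3, "S"), (-2, "S"), (-1, "C"), (1, "A"), (2, "G"), (3, "C"))),
    ("BBCA+1BW", ((-3, "B"), (-2, "B"), (-1, "C"), (1, "A"), (2, "B"), (3, "W"))),
    ("VA+1RR", ((-1, "V"), (1, "A"), (2, "R"), (3, "R"))),
    ("BA+1", ((-1, "B"), (1, "A"))),
)

TATA_MOTIF = "TATAWAWR"
TATA_WINDOW = (-36, -19)


def _offset_index(tsn_index: int, offset: int) -> int:
    """Map a biological offset (no zero; +1 is the TSN) to a string index."""
    return tsn_index + offset - 1 if offset > 0 else tsn_index + offset


def _matches(base: str, code: str) -> bool:
    return base in IUPAC[code]


def classify_tss_motif(context: str, tsn_index: int = 4) -> str:
    """Classify the TSS motif of a promoter context.

    `context` holds the promoter sequence with the start nucleotide at
    `tsn_index` (default 4, i.e. an 8-mer covering -4..+4).  Returns the
    first matching motif label by precedence, or "none".  Any N among the
    examined positions yields "none".
    """
    for label, spec in TSS_MOTIFS:
        ok = True
        for off, code in spec:
            i = _offset_index(tsn_index, off)
            if not 0 <= i < len(context):
                ok = False
                break
            b = context[i]
            if b == "N" or not _matches(b, code):
                ok = False
                break
        if ok:
            return label
    return "none"


def scan_tata(
    promoter: str, tsn_index: int, window: tuple[int, int] = TATA_WINDOW
) -> tuple[bool, Optional[int]]:
    """TATA-box (TATAWAWR) search fully contained in the window.

    Offsets are biological (upstream negative, no zero).  Returns
    (present, offset of the most upstream match or None); a motif
    straddling the window boundary does not count.
    """
    lo, hi = window
    m = len(TATA_MOTIF)
    for off in range(lo, hi - m + 2):  # 8-mer must end at or before `hi`
        start = _offset_index(tsn_index, off)
        if start < 0 or start + m > len(promoter):
            continue
        if all(_matches(promoter[start + j], TATA_MOTIF[j]) for j in range(m)):
            return True, off
    return False, None


def promoter_context(
    genome: dict[str, str], chrom: str, pos: int, strand: str,
    upstream: int = 40, downstream: int = 41,
) -> Optional[str]:
    """Transcript-sense window -upstream..+downstream around a TSN.

    The returned string has the TSN at index `upstream`.  Returns None
    when the window runs off the contig."""
    seq = genome[chrom]
    if strand == "+":
        lo, hi = pos - upstream, pos + downstream
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]
    lo, hi = pos - downstream + 1, pos + upstream + 1
    if lo < 0 or hi > len(seq):
        return None
    return reverse_complement(seq[lo:hi])


def composition_from_fractions(
    gene_id: str, frac_A: float, mean_methylation: float
) -> GeneSummary:
    """Percent m6Am / Am / non-A transcripts from the two gene fractions."""
    pct_m6am = 100.0 * frac_A * mean_methylation
    pct_am = 100.0 * frac_A * (1.0 - mean_methylation)
    pct_nona = 100.0 * (1.0 - frac_A)
    return GeneSummary(
        gene_id=gene_id,
        frac_A=frac_A,
        mean_methylation=mean_methylation,
        pct_m6Am=pct_m6am,
        pct_Am=pct_am,
        pct_nonA=pct_nona,
        m6am_gene_index=frac_A * mean_methylation,
    )


def gene_composition(gene_table: pd.DataFrame) -> GeneSummary:
    """Per-gene composition from its TSN pileup rows.

    The table needs columns depth, a_count, g_count, tsn_base (the
    transcript-sense reference base at the site) and gene_id.  frac_A is
    the read fraction of A-TSNs; mean methylation is the read-weighted
    non-conversion over A-TSNs.
    """
    if gene_table.empty or gene_table["depth"].sum() == 0:
        raise ValueError("gene has no reads; composition undefined")
    gene_id = str(gene_table["gene_id"].iloc[0]) if "gene_id" in gene_table else ""
    total = gene_table["depth"].sum()
    a_rows = gene_table[gene_table["tsn_base"] == "A"]
    frac_a = a_rows["depth"].sum() / total
    ag = (a_rows["a_count"] + a_rows["g_count"]).to_numpy(dtype=float)
    if ag.sum() > 0:
        meth = float(a_rows["a_count"].sum() / ag.sum())
    else:
        meth = float("nan")
    if frac_a == 0:
        meth = 0.0
    return composition_from_fractions(gene_id, float(frac_a), meth)


def m6am_gene_index(gene_table: pd.DataFrame, weighted: bool = True) -> float:
    """Fraction of a gene's TSN signal attributable to m6Am starts.

    Read-weighted (default): sum over A-TSNs of depth * non-conversion,
    over the summed depth of all TSNs.  Unweighted: mean non-conversion of
    A-TSNs scaled by the fraction of TSN positions that are A.
    """
    a_rows = gene_table[gene_table["tsn_base"] == "A"]
    if weighted:
        total = gene_table["depth"].sum()
        if total == 0:
            return float("nan")
        num = 0.0
        for row in a_rows.itertuples(index=False):
            if row.nonconversion is not None and not pd.isna(row.nonconversion):
                num += row.depth * row.nonconversion
        return num / total
    n_all = len(gene_table)
    if n_all == 0:
        return float("nan")
    ncs = a_rows["nonconversion"].dropna()
    if len(a_rows) == 0:
        return 0.0
    return float(ncs.sum() / n_all)


def stoichiometry_bins(table: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Quantile-bin A-TSNs by stoichiometry into n_bins equal groups.

    Bin sizes differ by at most one; ties are broken by (chrom, pos) so
    the binning is deterministic.  Bin 0 holds the lowest stoichiometry.
    """
    if len(table) < n_bins:
        raise ValueError(f"need at least {n_bins} sites for {n_bins} bins")
    order = table.sort_values(
        ["stoichiometry", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    sizes = np.full(n_bins, len(order) // n_bins)
    sizes[: len(order) % n_bins] += 1
    order["stoich_bin"] = np.repeat(np.arange(n_bins), sizes)
    return order


def positional_base_freq(
    binned: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = 40,
    downstream: int = 41,
) -> tuple[pd.DataFrame, int]:
    """Per-bin, per-position A/C/G/T frequencies around binned A-TSNs.

    Positions are labelled with biological offsets (-upstream..-1, +1..
    +downstream).  Sites whose window runs off the contig are skipped;
    the skip count is returned.  Frequencies at each (bin, position) sum
    to 1.
    """
    n_pos = upstream + downstream
    offsets = list(range(-upstream, 0)) + list(range(1, downstream + 1))
    bins = sorted(binned["stoich_bin"].unique())
    counts = {b: np.zeros((n_pos, 4), dtype=float) for b in bins}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    skipped = 0
    for row in binned.itertuples(index=False):
        ctx = promoter_context(genome, row.chrom, row.pos, row.strand, upstream, downstream)
        if ctx is None:
            skipped += 1
            continue
        mat = counts[row.stoich_bin]
        for i, b in enumerate(ctx):
            if b in idx:
                mat[i, idx[b]] += 1
    rows = []
    for b in bins:
        mat = counts[b]
        totals = mat.sum(axis=1)
        for i, off in enumerate(offsets):
            t = totals[i]
            freqs = mat[i] / t if t > 0 else np.zeros(4)
            rows.append((b, off, *freqs))
    return (
        pd.DataFrame(rows, columns=["stoich_bin", "offset", "A", "C", "G", "T"]),
        skipped,
    )


def standards_calibration(
    expected: Sequence[float], observed: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of observed non-conversion on expected stoichiometry.

    Returns (slope, intercept, Pearson r).  Requires >= 3 points and
    non-degenerate expected values."""
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(expected) < 3:
        raise ValueError("calibration requires at least 3 standards")
    if np.allclose(expected.var(), 0):
        raise ValueError("expected stoichiometries have zero variance")
    res = stats.linregress(expected, observed)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def delta_stoichiometry(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_reads: int = 50
) -> tuple[pd.DataFrame, float, float]:
    """Per-site non-conversion difference (b - a) with a paired t-test.

    Only sites with depth >= min_reads and a defined non-conversion rate
    in both tables enter; returns (table, t statistic, p-value).  Fewer
    than 2 shared sites, or all-zero deltas, give (table, nan, nan).
    """
    key = ["chrom", "pos", "strand"]
    a = table_a[table_a["depth"] >= min_reads].dropna(subset=["nonconversion"])
    b = table_b[table_b["depth"] >= min_reads].dropna(subset=["nonconversion"])
    merged = a[key + ["depth", "nonconversion"]].merge(
        b[key + ["depth", "nonconversion"]], on=key, suffixes=("_a", "_b")
    )
    merged["delta"] = merged["nonconversion_b"] - merged["nonconversion_a"]
    if len(merged) < 2 or np.allclose(merged["delta"].var(), 0.0):
        return merged, float("nan"), float("nan")
    t, p = stats.ttest_rel(merged["nonconversion_b"], merged["nonconversion_a"])
    return merged, float(t), float(p)


def fold_change_stoich(stoich_a: float, stoich_b: float) -> float:
    """Fold difference between two stoichiometries (max over min)."""
    if stoich_a <= 0 or stoich_b <= 0:
        raise ValueError("fold change undefined for non-positive stoichiometry")
    return max(stoich_a, stoich_b) / min(stoich_a, stoich_b)


DRACH = ("D", "R", "A", "C", "H")


def is_drach(genome: dict[str, str], chrom: str, pos: int, strand: str) -> bool:
    """True if the transcript-sense 5-mer centred on `pos` matches DRACH."""
    seq = genome[chrom]
    if strand == "+":
        lo, hi = pos - 2, pos + 3
        if lo < 0 or hi > len(seq):
            return False
        ctx = seq[lo:hi]
    else:
        lo, hi = pos - 2, pos + 3
        if lo < 0 or hi > len(seq):
            return False
        ctx = reverse_complement(seq[lo:hi])
    return all(_matches(ctx[i], DRACH[i]) for i in range(5))


def internal_m6a_sites(
    table_wt: pd.DataFrame,
    table_ko: pd.DataFrame,
    genome: dict[str, str],
    min_reads: int = 50,
    min_rate: float = 0.2,
) -> pd.DataFrame:
    """Call 5'-proximal internal m6A sites from internal-position pileups.

    A site is reported when covered by >= min_reads in both genotypes and
    its non-conversion rate is >= min_rate in either; a DRACH-context flag
    is attached from the genome."""
    key = ["chrom", "pos", "strand"]
    merged = table_wt[key + ["depth", "nonconversion"]].merge(
        table_ko[key + ["depth", "nonconversion"]], on=key, suffixes=("_wt", "_ko")
    )
    merged = merged[
        (merged["depth_wt"] >= min_reads)
        & (merged["depth_ko"] >= min_reads)
        & (
            (merged["nonconversion_wt"] >= min_rate)
            | (merged["nonconversion_ko"] >= min_rate)
        )
    ].reset_index(drop=True)
    merged["drach"] = [
        is_drach(genome, r.chrom, r.pos, r.strand) for r in merged.itertuples(index=False)
    ]
    return merged


def spike_in_scaling(
    spike_tables: dict[str, pd.DataFrame], design: dict[str, int]
) -> pd.DataFrame:
    """Per-library scale factors and false-positive thresholds from spike-ins.

    `spike_tables` maps library name to a pileup restricted to spike
    contigs; `design` maps spike contig to its single true 5'-terminus
    position.  The scale factor is the library's spike total over the
    mean spike total; the false-positive threshold is the maximum, over
    spikes, of the read fraction mapping off the known terminus.
    """
    if not spike_tables:
        raise ValueError("no spike tables given")
    totals = {}
    thresholds = {}
    for lib, tab in spike_tables.items():
        tab = tab[tab["chrom"].isin(design)]
        total = tab["depth"].sum()
        totals[lib] = total
        worst = 0.0
        for spike, true_pos in design.items():
            sub = tab[tab["chrom"] == spike]
            n = sub["depth"].sum()
            if n == 0:
                continue
            on = sub.loc[sub["pos"] == true_pos, "depth"].sum()
            worst = max(worst, 1.0 - on / n)
        thresholds[lib] = worst
    mean_total = np.mean(list(totals.values())) if totals else float("nan")
    rows = [
        (lib, totals[lib], totals[lib] / mean_total if mean_total else float("nan"),
         thresholds[lib])
        for lib in spike_tables
    ]
    return pd.DataFrame(rows, columns=["library", "spike_total", "scale_factor", "fp_threshold"])


def naive_log2fc(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Depth-normalized log2 fold change per site (smoke-test grade only).

    A deliberately simple normalized ratio for pipeline smoke tests; real
    differential expression belongs to a dedicated count-model engine fed
    with the exported count tables."""
    key = ["chrom", "pos", "strand"]
    m = counts_a[key + ["depth"]].merge(counts_b[key + ["depth"]], on=key,
                                        suffixes=("_a", "_b"), how="outer").fillna(0)
    ta, tb = m["depth_a"].sum(), m["depth_b"].sum()
    m["log2fc"] = np.log2(
        ((m["depth_b"] + pseudocount) / tb) / ((m["depth_a"] + pseudocount) / ta)
    )
    return m
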