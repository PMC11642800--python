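"""Synthetic references and libraries emulating conversion-based 5'-end sequencing.

The simulator produces (i) a random genome carrying multi-TSN genes with
known per-isoform m6Am stoichiometry and optional internal m6A sites, and
(ii) paired FASTQ reads that reproduce the library chemistry: read 1 begins
with a UMI and a fixed ATAT spacer, followed by the transcript 5' end;
unmethylated adenosines on the transcript are deaminated and read as G with
probability ``conversion_efficiency``, while methylated positions always
stay A.  A configurable fraction of reads starts at uniform-random genomic
positions, emulating uncapped fragments that survive the enrichment.

All randomness is driven by a single numpy Generator per call, so outputs
are byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from crownkit.types import ConfigurationError, ReferencePack, SimConfig

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Gene-locus layout (all in nt).  Each gene owns one locus; TSNs cluster in
# a 100-nt window positioned so that 40 nt of promoter and up to ~250 nt of
# transcript body stay inside the locus.
LOCUS_LEN = 600
GENES_PER_CHROM = 25
TSN_WINDOW = 100


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_tsn_dist(spec) -> dict:
    """Normalize a TSN-multiplicity distribution spec.

    Accepts an int (fixed count), or a dict {"kind": "fixed", "value": k} /
    {"kind": "negbin", "mean": m, "sd": s} (shifted negative binomial with
    minimum 1, matching the heavy-tailed TSN-per-gene counts seen in 5'-end
    data, mean ~9.5 and s.d. ~9).
    """
    if isinstance(spec, (int, np.integer)):
        spec = {"kind": "fixed", "value": int(spec)}
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigurationError(f"invalid TSN distribution spec: {spec!r}")
    kind = spec["kind"]
    if kind == "fixed":
        v = int(spec.get("value", 0))
        if v < 1:
            raise ConfigurationError("fixed TSN count must be >= 1")
        return {"kind": "fixed", "value": v}
    if kind == "negbin":
        mean = float(spec.get("mean", 9.5))
        sd = float(spec.get("sd", 9.0))
        if mean <= 1 or sd <= 0 or sd * sd <= mean - 1:
            raise ConfigurationError("negbin spec needs mean > 1 and sd^2 > mean - 1")
        return {"kind": "negbin", "mean": mean, "sd": sd}
    raise ConfigurationError(f"unknown TSN distribution kind: {kind!r}")


def _draw_tsn_counts(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist["kind"] == "fixed":
        return np.full(n, dist["value"], dtype=int)
    # shifted: Y = 1 + NB, so that the minimum is one TSN per gene
    m = dist["mean"] - 1.0
    var = dist["sd"] ** 2
    r = m * m / (var - m)
    p = r / (r + m)
    counts = 1 + rng.negative_binomial(r, p, size=n)
    return np.minimum(counts, TSN_WINDOW)  # a gene cannot host more TSNs than window positions


DEFAULT_TSN_DIST = {"kind": "negbin", "mean": 9.5, "sd": 9.0}


def make_reference(
    n_genes: int,
    tsns_per_gene=None,
    seed: int = 0,
    a_fraction: float = 0.5,
    stoich_beta: tuple[float, float] = (9.0, 1.0),
    internal_m6a_rate: float = 0.1,
    equal_abundance: bool = False,
    biotype: str = "protein_coding",
) -> ReferencePack:
    """Build a random genome with annotated multi-TSN genes and truth table.

    a_fraction is the probability that a TSN initiates with A (and hence
    carries an m6Am stoichiometry, drawn from Beta(*stoich_beta*), centred
    high as observed for mRNA starts).  internal_m6a_rate is the fraction
    of isoforms carrying one internal m6A site within the fragment.
    With equal_abundance, a gene's isoforms are used uniformly; otherwise
    relative abundances are Dirichlet(1)-distributed.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    dist = _parse_tsn_dist(DEFAULT_TSN_DIST if tsns_per_gene is None else tsns_per_gene)
    rng = np.random.default_rng(seed)

    n_chroms = math.ceil(n_genes / GENES_PER_CHROM)
    genome_arr: dict[str, np.ndarray] = {}
    for c in range(n_chroms):
        n_on = min(GENES_PER_CHROM, n_genes - c * GENES_PER_CHROM)
        length = 200 + n_on * LOCUS_LEN + 200
        genome_arr[f"chr{c + 1}"] = rng.integers(0, 4, size=length, dtype=np.int8)

    tsn_counts = _draw_tsn_counts(dist, n_genes, rng)
    truth_rows = []
    tss_rows = []
    for g in range(n_genes):
        chrom = f"chr{g // GENES_PER_CHROM + 1}"
        local = g % GENES_PER_CHROM
        locus = 200 + local * LOCUS_LEN
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            window_start = locus + 100
        else:
            window_start = locus + 400
        n_tsn = int(tsn_counts[g])
        offsets = rng.choice(TSN_WINDOW, size=n_tsn, replace=False)
        positions = np.sort(window_start + offsets)
        gene_id = f"G{g + 1:04d}"
        arr = genome_arr[chrom]

        if equal_abundance:
            abund = np.full(n_tsn, 1.0 / n_tsn)
        else:
            abund = rng.dirichlet(np.ones(n_tsn))

        tsn_set = set(int(p) for p in positions)
        for i, pos in enumerate(positions):
            pos = int(pos)
            if rng.random() < a_fraction:
                base = "A"
                stoich = float(rng.beta(*stoich_beta))
            else:
                base = _BASES[1 + rng.integers(0, 3)]  # C, G or T
                stoich = np.nan
            # write the transcript-sense base into the (forward) genome
            fwd = base if strand == "+" else base.translate(_COMPLEMENT)
            arr[pos] = _BASES.index(fwd)

            internal: list[tuple[int, float]] = []
            if rng.random() < internal_m6a_rate:
                for _ in range(20):  # avoid clobbering a sibling TSN
                    off = int(rng.integers(10, 70))
                    gpos = pos + off if strand == "+" else pos - off
                    if gpos not in tsn_set:
                        break
                frac = float(rng.uniform(0.2, 0.8))
                fwd_a = "A" if strand == "+" else "T"
                arr[gpos] = _BASES.index(fwd_a)
                internal.append((off, frac))

            truth_rows.append(
                (gene_id, chrom, pos, strand, base, float(abund[i]), stoich, tuple(internal))
            )
            tss_rows.append((chrom, pos, strand, gene_id, biotype))

    genome = {c: "".join(_BASES[i] for i in a) for c, a in genome_arr.items()}
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "chrom", "tsn_pos", "strand", "tsn_base",
            "relative_abundance", "stoichiometry", "internal_m6a",
        ],
    )
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene_id", "biotype"])
    return ReferencePack(genome=genome, tss=tss, truth=truth)


def knockout(ref: ReferencePack) -> ReferencePack:
    """Writer-knockout emulation: m6Am stoichiometry of every A-TSN set to 0.

    Internal m6A sites are left untouched (they are written by a different
    enzyme than the cap-adjacent methyltransferase)."""
    truth = ref.truth.copy()
    truth.loc[truth["tsn_base"] == "A", "stoichiometry"] = 0.0
    return ReferencePack(genome=ref.genome, tss=ref.tss, truth=truth)


def transcript_sequence(genome: dict[str, str], chrom: str, pos: int, strand: str,
                        length: int) -> str:
    """Transcript-sense sequence of `length` nt starting at the 5' position.

    Truncated at contig edges."""
    seq = genome[chrom]
    if strand == "+":
        return seq[pos: pos + length]
    start = max(0, pos - length + 1)
    return reverse_complement(seq[start: pos + 1])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alt = _BASES.replace(out[i], "") if out[i] in _BASES else _BASES
        out[i] = alt[rng.integers(0, len(alt))]
    return "".join(out)


def _emit_read(
    frag: str,
    tsn_is_a: bool,
    stoich: float,
    internal: Sequence[tuple[int, float]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, str, str, bool]:
    """Apply per-molecule chemistry to a transcript fragment.

    Returns (read1, read2, umi, tsn_methylated)."""
    chars = list(frag)
    meth = np.zeros(len(chars), dtype=bool)
    tsn_meth = False
    if tsn_is_a and chars and chars[0] == "A":
        tsn_meth = bool(rng.random() < stoich)
        meth[0] = tsn_meth
    for off, frac in internal:
        if 0 < off < len(chars) and chars[off] == "A":
            meth[off] = rng.random() < frac
    conv = rng.random(len(chars)) < cfg.conversion_efficiency
    for i, ch in enumerate(chars):
        if ch == "A" and not meth[i] and conv[i]:
            chars[i] = "G"
    converted = "".join(chars)
    umi = _random_seq(rng, cfg.umi_len)
    genomic_len = cfg.read_len - cfg.umi_len - len(cfg.spacer)
    read1 = umi + cfg.spacer + converted[:genomic_len]
    read2 = reverse_complement(converted)[: cfg.read_len]
    read1 = _apply_errors(read1, cfg.seq_error_rate, rng)
    read2 = _apply_errors(read2, cfg.seq_error_rate, rng)
    return read1, read2, umi, tsn_meth


def simulate_library(
    ref: ReferencePack, cfg: SimConfig
) -> tuple[list[tuple[str, str, str, str, str]], pd.DataFrame]:
    """Simulate one paired-end library from a reference pack.

    Returns (reads, truth) where reads are tuples
    (read_id, seq1, qual1, seq2, qual2) and truth records, per read, the
    source isoform, its 5'-end genomic position and whether the TSN A of
    this molecule was methylated.  Genes are sampled uniformly; isoforms
    within a gene by their relative abundance.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = ref.truth
    n_iso = len(truth)
    if n_iso == 0:
        raise ConfigurationError("reference contains no isoforms")

    gene_ids = truth["gene_id"].to_numpy()
    genes = pd.unique(gene_ids)
    weights = truth["relative_abundance"].to_numpy() / len(genes)
    weights = weights / weights.sum()

    is_bg = rng.random(cfg.depth) < cfg.background_rate
    iso_idx = rng.choice(n_iso, size=cfg.depth, p=weights)

    chrom_names = list(ref.genome)
    chrom_lens = np.array([len(ref.genome[c]) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    rows = truth.to_dict("records")
    reads = []
    truth_rows = []
    qual = "I" * cfg.read_len
    for i in range(cfg.depth):
        rid = f"r{i:07d}"
        if is_bg[i]:
            ci = rng.choice(len(chrom_names), p=chrom_p)
            chrom = chrom_names[ci]
            clen = len(ref.genome[chrom])
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                pos = int(rng.integers(0, max(1, clen - cfg.fragment_len)))
            else:
                pos = int(rng.integers(min(cfg.fragment_len, clen - 1), clen))
            frag = transcript_sequence(ref.genome, chrom, pos, strand, cfg.fragment_len)
            r1, r2, umi, _ = _emit_read(frag, False, 0.0, (), cfg, rng)
            truth_rows.append((rid, chrom, pos, strand, "", "", False, True))
        else:
            row = rows[int(iso_idx[i])]
            chrom, pos, strand = row["chrom"], int(row["tsn_pos"]), row["strand"]
            frag = transcript_sequence(ref.genome, chrom, pos, strand, cfg.fragment_len)
            stoich = row["stoichiometry"]
            tsn_is_a = row["tsn_base"] == "A"
            r1, r2, umi, meth = _emit_read(
                frag, tsn_is_a, 0.0 if pd.isna(stoich) else float(stoich),
                row["internal_m6a"], cfg, rng,
            )
            truth_rows.append((rid, chrom, pos, strand, row["gene_id"], row["tsn_base"], meth, False))
        reads.append((rid, r1, qual[: len(r1)], r2, qual[: len(r2)]))

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["read_id", "chrom", "tsn_pos", "strand", "gene_id", "tsn_base",
                 "tsn_methylated", "background"],
    )
    return reads, truth_df


# --- barcoded standards -------------------------------------------------

# A-free barcodes (pairwise Hamming distance >= 3 even after A->G read
# conversion), inserted 42 nt downstream of the start nucleotide.
STANDARD_BARCODES = ("CCGGTT", "GGTTCC", "TTCCGG", "CGTCGT", "GCTGCT")
STANDARD_TSN_OFFSET = 10
_BARCODE_OFFSET = 42


def make_standards_reference(n: int, seed: int = 0) -> ReferencePack:
    """Reference for `n` barcoded standards with identical 5' ends.

    Each standard lives on its own contig; transcripts start with A at
    position STANDARD_TSN_OFFSET and differ only in a 6-nt barcode 42 nt
    downstream of the start."""
    if n > len(STANDARD_BARCODES):
        raise ConfigurationError(f"at most {len(STANDARD_BARCODES)} standards supported")
    rng = np.random.default_rng(seed)
    pad = _random_seq(rng, STANDARD_TSN_OFFSET)
    body = "AG" + _random_seq(rng, 140)  # CleanCap-style AG start
    genome = {}
    tss_rows = []
    truth_rows = []
    for i in range(n):
        name = f"std{i + 1}"
        bc = STANDARD_BARCODES[i]
        seq = body[:_BARCODE_OFFSET] + bc + body[_BARCODE_OFFSET + len(bc):]
        genome[name] = pad + seq
        tss_rows.append((name, STANDARD_TSN_OFFSET, "+", f"STD{i + 1}", "other"))
        truth_rows.append((f"STD{i + 1}", name, STANDARD_TSN_OFFSET, "+", "A", 1.0, np.nan, ()))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene_id", "biotype"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "chrom", "tsn_pos", "strand", "tsn_base",
                 "relative_abundance", "stoichiometry", "internal_m6a"],
    )
    return ReferencePack(genome=genome, tss=tss, truth=truth)


def simulate_standards(
    stoichiometries: Sequence[float],
    depth: int,
    seed: int = 0,
    cfg: Optional[SimConfig] = None,
) -> tuple[ReferencePack, list[tuple[str, str, str, str, str]], pd.DataFrame]:
    """Simulate the barcoded standard mixture.

    `depth` reads are emitted per standard at the requested m6Am fraction.
    Read length defaults to 80 nt so that read 1 spans the discriminating
    barcode.  Returns (reference, reads, per-read truth).
    """
    for s in stoichiometries:
        if not 0.0 <= s <= 1.0:
            raise ConfigurationError("stoichiometries must lie in [0, 1]")
    if cfg is None:
        cfg = SimConfig(read_len=80, fragment_len=100, seed=seed, background_rate=0.0)
    ref = make_standards_reference(len(stoichiometries), seed=seed)
    ref.truth["stoichiometry"] = list(stoichiometries)
    rng = np.random.default_rng(seed)
    reads = []
    truth_rows = []
    qual = "I" * cfg.read_len
    k = 0
    for i, stoich in enumerate(stoichiometries):
        row = ref.truth.iloc[i]
        frag = transcript_sequence(ref.genome, row.chrom, int(row.tsn_pos), "+", cfg.fragment_len)
        for _ in range(depth):
            rid = f"s{k:07d}"
            k += 1
            r1, r2, umi, meth = _emit_read(frag, True, float(stoich), (), cfg, rng)
            reads.append((rid, r1, qual[: len(r1)], r2, qual[: len(r2)]))
            truth_rows.append((rid, row.chrom, int(row.tsn_pos), "+", row.gene_id, "A", meth, False))
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["read_id", "chrom", "tsn_pos", "strand", "gene_id", "tsn_base",
                 "tsn_methylated", "background"],
    )
    return ref, reads, truth_df
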