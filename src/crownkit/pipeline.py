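"""End-to-end orchestration: prep -> align -> dedup -> pileup -> quantify.

Also hosts the run-level configuration (all pipeline thresholds with their
standard defaults) and the manifest machinery used by the CLI: every run
records its configuration hash so that identical configs are verifiably
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from crownkit import align as align_mod
from crownkit import analysis, annotate, readprep, tsn_quant
from crownkit.simulate import simulate_standards
from crownkit.types import ReferencePack, SimConfig


@dataclass
class RunConfig:
    """All tunable thresholds with their standard defaults.

    min_score / min_gap gate alignment uniqueness; ident_reads and
    quant_reads are the TSN identification and quantification depth
    cutoffs; tss_window bounds gene assignment; m6a_rate is the internal
    m6A non-conversion floor; qcov / identity / bitscore / word_size
    govern the snRNA/snoRNA-like similarity call; tata_window is the
    TATA-box search region.
    """

    min_score: float = align_mod.MIN_SCORE
    min_gap: float = align_mod.MIN_GAP
    ident_reads: int = tsn_quant.IDENT_MIN_READS
    quant_reads: int = tsn_quant.QUANT_MIN_READS
    tss_window: int = annotate.TSS_WINDOW
    m6a_rate: float = 0.2
    qcov: float = annotate.MIN_QCOV
    identity: float = annotate.MIN_IDENTITY
    bitscore: float = annotate.MIN_BITSCORE
    word_size: int = annotate.WORD_SIZE
    tata_window: tuple[int, int] = analysis.TATA_WINDOW
    seed_k: int = 16
    umi_len: int = 11
    adapters: tuple[str, str] = ("", "")
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def process_library(
    reads: Sequence[tuple[str, str, str, str, str]],
    genome: dict[str, str],
    config: Optional[RunConfig] = None,
    index: Optional[align_mod.ConvertedIndex] = None,
) -> dict:
    """Raw read pairs -> quantified TSN table.

    Returns a dict with the prep stats, alignment stats, deduplicated
    alignments and the quantified pileup table (with TPM).
    """
    cfg = config or RunConfig()
    prepped, prep_stats = readprep.prepare_reads(reads, cfg.umi_len, cfg.adapters)
    if index is None:
        index = align_mod.ConvertedIndex(genome, k=cfg.seed_k)
    alignments, aln_stats = align_mod.align_library(
        index, prepped, min_score=cfg.min_score, min_gap=cfg.min_gap
    )
    deduped, n_no_umi = tsn_quant.dedup_umis(alignments)
    pileup = tsn_quant.pileup_tsn(deduped)
    called = tsn_quant.call_tsns(pileup, cfg.ident_reads)
    quant = tsn_quant.quantify_m6am(called, cfg.quant_reads)
    if quant["depth"].sum() > 0:
        quant = tsn_quant.tpm_normalize(quant)
    return {
        "prep_stats": prep_stats,
        "align_stats": aln_stats,
        "n_missing_umi": n_no_umi,
        "alignments": deduped,
        "table": quant,
    }


def add_reference_base(table: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Attach the transcript-sense genomic base at each TSN (tsn_base)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    bases = []
    for row in table.itertuples(index=False):
        b = genome[row.chrom][row.pos]
        bases.append(b if row.strand == "+" else comp.get(b, "N"))
    out = table.copy()
    out["tsn_base"] = bases
    return out


def run_standards_calibration(
    stoichiometries: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    depth: int = 1000,
    seeds: Sequence[int] = (1, 2, 3),
    sim_cfg: Optional[SimConfig] = None,
    config: Optional[RunConfig] = None,
) -> dict:
    """Simulate the barcoded standards and calibrate end to end.

    One library per seed is simulated, processed through prep/align/quant,
    and the mean observed non-conversion per standard (across replicates)
    is regressed on the expected stoichiometry.  Returns slope, intercept,
    Pearson r and the per-replicate observation table.
    """
    cfg = config or RunConfig()
    per_rep = []
    for seed in seeds:
        scfg = sim_cfg
        if scfg is None:
            scfg = SimConfig(read_len=80, fragment_len=100, seed=seed, background_rate=0.0)
        else:
            scfg = dataclasses.replace(scfg, seed=seed)
        ref, reads, _ = simulate_standards(stoichiometries, depth, seed=seed, cfg=scfg)
        res = process_library(reads, ref.genome, cfg)
        tab = res["table"]
        for i, chrom in enumerate(ref.genome):
            row = tab[(tab["chrom"] == chrom) & (tab["pos"] == int(ref.truth["tsn_pos"].iloc[i]))]
            obs = float(row["nonconversion"].iloc[0]) if len(row) else float("nan")
            per_rep.append((seed, chrom, stoichiometries[i], obs))
    obs_df = pd.DataFrame(per_rep, columns=["seed", "standard", "expected", "observed"])
    mean_obs = obs_df.groupby("expected", as_index=False)["observed"].mean()
    slope, intercept, r = analysis.standards_calibration(
        mean_obs["expected"], mean_obs["observed"]
    )
    return {"slope": slope, "intercept": intercept, "pearson_r": r, "observations": obs_df}


def run_pipeline(
    ref: ReferencePack,
    reads: Sequence[tuple[str, str, str, str, str]],
    config: Optional[RunConfig] = None,
    outdir: Optional[str | Path] = None,
) -> dict:
    """Full pipeline over one library with gene annotation and manifest.

    Processes the library, annotates TSNs against the reference TSS table
    and, if `outdir` is given, writes the TSN table, identified-TSN BED
    and a JSON manifest carrying the configuration hash.
    """
    cfg = config or RunConfig()
    res = process_library(reads, ref.genome, cfg)
    table = annotate.annotate_tsns(res["table"], ref.tss, cfg.tss_window)
    table = add_reference_base(table, ref.genome)
    res["table"] = table
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "tsn_table.tsv", sep="\t", index=False)
        with open(outdir / "identified_tsns.bed", "w") as fh:
            for row in table[table["identified"]].itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.gene_id}\t{row.depth}\t{row.strand}\n")
        manifest = {
            "config": dataclasses.asdict(cfg),
            "config_hash": cfg.config_hash(),
            "n_input_reads": res["prep_stats"].n_input,
            "n_accepted_reads": res["prep_stats"].n_accepted,
            "n_rejected_reads": res["prep_stats"].n_rejected,
            "align_stats": res["align_stats"],
            "n_tsns": int(len(table)),
            "n_identified": int(table["identified"].sum()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        res["manifest"] = manifest
    return res
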