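"""Gene assignment of TSNs and snRNA/snoRNA-like classification.

A TSN is assigned to the gene of a same-strand annotated TSS at most
100 nt away; when several candidates exist, biotype priority
snRNA > snoRNA > protein_coding > lncRNA > others wins, then smallest
distance, then lexicographic gene id.  A 51-nt 5'-end context (TSN plus
50 nt downstream) can additionally be screened against a database of
snRNA/snoRNA/pseudogene sequences with a local (Smith-Waterman) search;
a hit with query coverage >= 50%, identity >= 50%, a shared 10-nt word
and bit score >= 50 marks the TSN as snRNA/snoRNA-like.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import Align

TSS_WINDOW = 100

BIOTYPE_PRIORITY = {"snRNA": 0, "snoRNA": 1, "protein_coding": 2, "lncRNA": 3}
_OTHER_PRIORITY = 4

# Karlin-Altschul parameters for the classic +1/-2 nucleotide scoring
KA_LAMBDA = 1.33
KA_K = 0.621

MIN_QCOV = 0.5
MIN_IDENTITY = 0.5
WORD_SIZE = 10
MIN_BITSCORE = 50.0


def _priority(biotype: str) -> int:
    return BIOTYPE_PRIORITY.get(biotype, _OTHER_PRIORITY)


def nearest_tss(
    chrom: str,
    pos: int,
    strand: str,
    annotation: pd.DataFrame,
    window: int = TSS_WINDOW,
) -> tuple[Optional[int], pd.DataFrame]:
    """Distance to the nearest same-strand annotated TSS and all candidates
    within `window` nt.

    Returns (nearest distance or None if the chromosome/strand is absent,
    candidate rows with a `distance` column).
    """
    sel = annotation[(annotation["chrom"] == chrom) & (annotation["strand"] == strand)]
    if sel.empty:
        return None, sel.assign(distance=pd.Series(dtype=int))
    dist = (sel["pos"] - pos).abs()
    cands = sel.assign(distance=dist)
    cands = cands[cands["distance"] <= window].sort_values(
        ["distance", "gene_id"], kind="mergesort"
    )
    return int(dist.min()), cands


def assign_gene(candidates: pd.DataFrame) -> tuple[str, str]:
    """Pick (gene_id, annotation_class) from TSS candidates within window.

    Highest-priority biotype first, then smallest distance, then
    lexicographic gene id; empty candidates yield ("", "unassigned").
    """
    if candidates.empty:
        return "", "unassigned"
    ranked = sorted(
        candidates.itertuples(index=False),
        key=lambda r: (_priority(r.biotype), r.distance, r.gene_id),
    )
    top = ranked[0]
    cls = top.biotype if top.biotype in BIOTYPE_PRIORITY else "other"
    return top.gene_id, cls


def annotate_tsns(
    table: pd.DataFrame, annotation: pd.DataFrame, window: int = TSS_WINDOW
) -> pd.DataFrame:
    """Add gene_id / annotation_class / tss_distance columns to a TSN table."""
    gene_ids, classes, dists = [], [], []
    for row in table.itertuples(index=False):
        dist, cands = nearest_tss(row.chrom, row.pos, row.strand, annotation, window)
        gid, cls = assign_gene(cands)
        gene_ids.append(gid)
        classes.append(cls)
        dists.append(dist if dist is not None else np.nan)
    out = table.copy()
    out["gene_id"] = gene_ids
    out["annotation_class"] = classes
    out["tss_distance"] = dists
    return out


def bit_score(raw_score: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul normalized bit score: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(k)) / math.log(2)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.5
    return aligner


@dataclass
class SimilarityHit:
    subject: str
    raw_score: float
    bitscore: float
    identity: float
    query_coverage: float
    has_word: bool


def _shares_word(a: str, b: str, w: int = WORD_SIZE) -> bool:
    words = {a[i: i + w] for i in range(len(a) - w + 1)}
    return any(b[i: i + w] in words for i in range(len(b) - w + 1))


def local_alignment_stats(query: str, subject: str) -> tuple[float, float, float]:
    """Best local alignment of query vs subject.

    Returns (raw score, identity over alignment columns, query coverage).
    """
    aligner = _make_aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qstart, qend = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    coverage = (qend - qstart) / len(query) if query else 0.0
    return float(score), identity, coverage


def pseudogene_like(
    context: str,
    db: dict[str, str],
    min_qcov: float = MIN_QCOV,
    min_identity: float = MIN_IDENTITY,
    word_size: int = WORD_SIZE,
    min_bitscore: float = MIN_BITSCORE,
) -> tuple[bool, Optional[SimilarityHit]]:
    """Classify a TSN 5'-end context as snRNA/snoRNA-like.

    `context` is the TSN base plus downstream sequence (51 nt in the
    standard analysis).  Returns (classified, best hit).  An empty
    database disables classification with a warning.
    """
    if len(context) < word_size:
        raise ValueError(f"context must be at least {word_size} nt")
    if not db:
        warnings.warn("empty similarity database; snRNA/snoRNA-like classification disabled")
        return False, None
    best: Optional[SimilarityHit] = None
    for name in sorted(db):
        subject = db[name]
        raw, ident, qcov = local_alignment_stats(context, subject)
        hit = SimilarityHit(
            subject=name,
            raw_score=raw,
            bitscore=bit_score(raw),
            identity=ident,
            query_coverage=qcov,
            has_word=_shares_word(context, subject, word_size),
        )
        if best is None or hit.bitscore > best.bitscore:
            best = hit
    assert best is not None
    ok = (
        best.bitscore >= min_bitscore
        and best.identity >= min_identity
        and best.query_coverage >= min_qcov
        and best.has_word
    )
    return ok, best
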