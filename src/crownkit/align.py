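"""Conversion-aware ("three-letter") read alignment.

Reads from a deaminated library are aligned in converted space: read 1 is
A->G converted in silico and compared against an A->G-converted forward
genome (plus strand) and, reverse-complemented, against a T->C-converted
genome (minus strand); read 2 is T->C converted.  After alignment the
original bases are restored so that methylation appears as A over a
converted-G background.

The aligner is seed-and-extend with exact k-mer seeds in converted space
and full-length ungapped extension (the converted alphabet has three
effective letters, so seeds are kept moderately long; substitutions are
the only error mode modelled).  Scoring is match 0 / mismatch -6, and the
paired score is the sum over both mates.  A paired alignment is kept only
if its score exceeds -10 and it beats the runner-up candidate by more
than 9 -- rank-1 ties therefore count as secondary alignments and are
rejected.  Read-1 alignments with 5' softclips are dropped, since a
clipped first base means the start nucleotide was not observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from crownkit.simulate import reverse_complement
from crownkit.types import AlignmentRecord, ConfigurationError, ReadRecord

_A2G = str.maketrans("A", "G")
_T2C = str.maketrans("T", "C")

MIN_SCORE = -10  # best paired score must exceed this
MIN_GAP = 9      # and beat the second best by more than this


def convert_sequence(seq: str, mode: str) -> str:
    """Apply the in-silico base conversion (A2G or T2C)."""
    if mode == "A2G":
        return seq.translate(_A2G)
    if mode == "T2C":
        return seq.translate(_T2C)
    raise ConfigurationError(f"unknown conversion mode {mode!r}")


@dataclass
class AlignScoring:
    match: int = 0
    mismatch: int = -6
    max_candidates: int = 5
    max_fragment: int = 1000


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ConvertedIndex:
    """Exact k-mer lookup over both converted strands of a genome."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ConfigurationError("empty genome")
        if k < 4:
            raise ConfigurationError("seed length k must be >= 4")
        self.k = k
        self.chroms = list(genome)
        self.genome = genome
        self.plus = {c: convert_sequence(genome[c], "A2G") for c in self.chroms}
        self.minus = {c: convert_sequence(genome[c], "T2C") for c in self.chroms}
        self.plus_arr = {c: _to_arr(s) for c, s in self.plus.items()}
        self.minus_arr = {c: _to_arr(s) for c, s in self.minus.items()}
        self._plus_idx = self._build(self.plus)
        self._minus_idx = self._build(self.minus)

    def _build(self, strings: dict[str, str]) -> dict[str, list[tuple[str, int]]]:
        idx: dict[str, list[tuple[str, int]]] = {}
        k = self.k
        for c, s in strings.items():
            for i in range(len(s) - k + 1):
                idx.setdefault(s[i: i + k], []).append((c, i))
        return idx

    def lookup(self, kmer: str, strand: str) -> list[tuple[str, int]]:
        idx = self._plus_idx if strand == "+" else self._minus_idx
        return idx.get(kmer, [])

    def candidate_starts(self, query: str, strand: str) -> set[tuple[str, int]]:
        """Candidate alignment start positions for a converted-space query.

        Seeds are taken at the two ends and the middle of the query so that
        a single substitution can never break every seed."""
        L = len(query)
        k = self.k
        if L < k:
            return set()
        offsets = sorted({0, (L - k) // 2, L - k})
        out: set[tuple[str, int]] = set()
        genome = self.plus if strand == "+" else self.minus
        for off in offsets:
            for chrom, hit in self.lookup(query[off: off + k], strand):
                start = hit - off
                if 0 <= start and start + L <= len(genome[chrom]):
                    out.add((chrom, start))
        return out


def _score_at(index: ConvertedIndex, strand: str, chrom: str, start: int,
              qarr: np.ndarray, scoring: AlignScoring) -> float:
    g = index.plus_arr[chrom] if strand == "+" else index.minus_arr[chrom]
    window = g[start: start + len(qarr)]
    mism = int(np.count_nonzero(window != qarr))
    return scoring.match * (len(qarr) - mism) + scoring.mismatch * mism


def align_single(
    index: ConvertedIndex, converted_query: str, strand: str,
    scoring: AlignScoring = AlignScoring(),
) -> list[tuple[str, int, float]]:
    """Score all seeded candidate placements of one converted query.

    Returns (chrom, start, score) sorted by descending score with a
    deterministic positional tie-break."""
    qarr = _to_arr(converted_query)
    cands = []
    for chrom, start in index.candidate_starts(converted_query, strand):
        cands.append((chrom, start, _score_at(index, strand, chrom, start, qarr, scoring)))
    cands.sort(key=lambda t: (-t[2], t[0], t[1]))
    return cands


def align_pair(
    index: ConvertedIndex,
    read: ReadRecord,
    scoring: AlignScoring = AlignScoring(),
) -> list[AlignmentRecord]:
    """Candidate paired alignments of one read pair (both mates required).

    Returns at most ``scoring.max_candidates`` records sorted by paired
    score (mate 1 + mate 2) descending.  ``five_prime_pos`` is the genomic
    coordinate of read 1's first base.
    """
    q1 = convert_sequence(read.seq1, "A2G")
    q2 = convert_sequence(read.seq2, "T2C") if read.seq2 else ""
    candidates: list[tuple[float, str, str, int]] = []  # score, chrom, strand, five_prime

    for strand in "+-":
        if strand == "+":
            r1_query, r2_query = q1, reverse_complement(q2) if q2 else ""
        else:
            r1_query, r2_query = reverse_complement(q1), q2
        L1 = len(r1_query)
        r1arr = _to_arr(r1_query)
        r1_hits = index.candidate_starts(r1_query, strand)
        if not r1_hits:
            continue
        if r2_query:
            r2arr = _to_arr(r2_query)
            mate_hits = sorted(index.candidate_starts(r2_query, strand))
        else:
            r2arr = None
            mate_hits = []
        for chrom, start in r1_hits:
            s1 = _score_at(index, strand, chrom, start, r1arr, scoring)
            if r2arr is not None:
                # FR orientation: the mate lies within the fragment window
                if strand == "+":
                    lo, hi = start - 5, start + scoring.max_fragment
                else:
                    lo, hi = start - scoring.max_fragment, start + L1 + 5
                best2 = None
                for mc, ms in mate_hits:
                    if mc != chrom or not lo <= ms <= hi:
                        continue
                    s2 = _score_at(index, strand, chrom, ms, r2arr, scoring)
                    if best2 is None or s2 > best2:
                        best2 = s2
                if best2 is None:
                    continue  # --no-mixed: both mates must align
                score = s1 + best2
            else:
                score = s1
            five_prime = start if strand == "+" else start + L1 - 1
            candidates.append((score, chrom, strand, five_prime))

    candidates.sort(key=lambda t: (-t[0], t[1], t[3], t[2]))
    out = []
    for score, chrom, strand, five_prime in candidates[: scoring.max_candidates]:
        out.append(
            AlignmentRecord(
                read_id=read.read_id,
                chrom=chrom,
                strand=strand,
                five_prime_pos=five_prime,
                score=score,
                softclip5=0,
                umi=read.umi,
            )
        )
    return out


def select_unique(
    candidates: Sequence[AlignmentRecord],
    min_score: float = MIN_SCORE,
    min_gap: float = MIN_GAP,
) -> Optional[AlignmentRecord]:
    """Uniqueness filter on score-sorted candidates.

    Keeps the best candidate iff its score exceeds ``min_score`` and
    either no secondary alignment exists or best - second > ``min_gap``.
    """
    if not candidates:
        return None
    best = candidates[0]
    if not best.score > min_score:
        return None
    if len(candidates) > 1:
        second = candidates[1]
        if not best.score - second.score > min_gap:
            return None
        return best.replace(second_best_score=second.score)
    return best


def restore_and_filter(
    aln: AlignmentRecord, original_seq1: str
) -> Optional[AlignmentRecord]:
    """Attach the original (pre-conversion) read-1 bases; drop 5' softclips."""
    if aln.softclip5 > 0:
        return None
    return aln.replace(restored_seq=original_seq1)


def align_library(
    index: ConvertedIndex,
    records: Iterable[ReadRecord],
    scoring: AlignScoring = AlignScoring(),
    min_score: float = MIN_SCORE,
    min_gap: float = MIN_GAP,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """align_pair + select_unique + restore_and_filter over a library."""
    kept: list[AlignmentRecord] = []
    stats = {"n_input": 0, "n_unaligned": 0, "n_multi": 0, "n_softclip": 0, "n_kept": 0}
    for rec in records:
        stats["n_input"] += 1
        cands = align_pair(index, rec, scoring)
        if not cands:
            stats["n_unaligned"] += 1
            continue
        best = select_unique(cands, min_score, min_gap)
        if best is None:
            stats["n_multi"] += 1
            continue
        restored = restore_and_filter(best, rec.seq1)
        if restored is None:
            stats["n_softclip"] += 1
            continue
        stats["n_kept"] += 1
        kept.append(restored)
    return kept, stats


def read_sam(path) -> list[AlignmentRecord]:
    """Read alignments back from a SAM produced by write_sam."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            L = rec.query_length
            seq = rec.query_sequence or ""
            if strand == "+":
                five_prime = rec.reference_start
                restored = seq
            else:
                five_prime = rec.reference_start + L - 1
                restored = reverse_complement(seq)
            tags = dict(rec.get_tags())
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand=strand,
                    five_prime_pos=five_prime,
                    score=float(tags.get("AS", 0)),
                    second_best_score=float(tags["XS"]) if "XS" in tags else None,
                    softclip5=0,
                    restored_seq=restored,
                    umi=str(tags.get("RX", "")),
                )
            )
    return out


def write_sam(
    path, alignments: Iterable[AlignmentRecord], genome: dict[str, str]
) -> None:
    """Write read-1 alignments as SAM with AS/XS/RX tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for a in alignments:
            L = len(a.restored_seq)
            if a.strand == "+":
                flag, pos, seq = 0, a.five_prime_pos, a.restored_seq
            else:
                flag, pos, seq = 16, a.five_prime_pos - L + 1, reverse_complement(a.restored_seq)
            tags = [f"AS:i:{int(a.score)}"]
            if a.second_best_score is not None:
                tags.append(f"XS:i:{int(a.second_best_score)}")
            if a.umi:
                tags.append(f"RX:Z:{a.umi}")
            fh.write(
                f"{a.read_id}\t{flag}\t{a.chrom}\t{pos + 1}\t60\t{L}M\t*\t0\t0\t"
                f"{seq}\t{'I' * L}\t" + "\t".join(tags) + "\n"
            )
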