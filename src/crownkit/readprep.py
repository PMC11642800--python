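"""Read preprocessing: UMI + spacer extraction, adapter and quality trimming.

Read 1 of a library begins with an 8- or 11-nt UMI followed by the fixed
spacer ATAT; the base immediately after the spacer is the transcript's
first nucleotide.  Spacer matching is exact: the spacer anchors the
single-nucleotide start position, and tolerating slippage there would
corrupt the start-site coordinate by construction.

Adapter removal is a semi-global suffix match allowing a 25% error rate,
and 3'-quality trimming uses the running-sum rule (cut at the position
minimising the partial sum of ``cutoff - q`` from the 3' end), i.e. the
standard behaviour of read-trimming tools at ``-q 20``.  Reads shorter
than 32 nt after trimming are rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from crownkit.types import ReadRecord, SPACER

DEFAULT_MIN_LEN = 32
DEFAULT_QUAL_CUTOFF = 20
DEFAULT_MAX_ERROR_RATE = 0.25


@dataclass
class PrepStats:
    """Read-accounting: every input pair is either accepted or rejected."""

    n_input: int = 0
    n_accepted: int = 0
    rejections: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejections[reason] += 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())


def extract_umi_and_spacer(
    read_id: str,
    seq1: str,
    qual1: str,
    seq2: str,
    qual2: str,
    umi_len: int,
) -> tuple[Optional[ReadRecord], Optional[str]]:
    """Move the UMI to metadata and strip UMI+spacer from read 1.

    Returns (record, None) on success or (None, reason) on rejection.
    The spacer must match ATAT exactly at positions umi_len..umi_len+3.
    """
    header = umi_len + len(SPACER)
    if len(seq1) < header + 1:
        return None, "truncated"
    if seq1[umi_len:header] != SPACER:
        return None, "spacer_mismatch"
    umi = seq1[:umi_len]
    return (
        ReadRecord(
            read_id=read_id,
            umi=umi,
            seq1=seq1[header:],
            qual1=qual1[header:],
            seq2=seq2,
            qual2=qual2,
        ),
        None,
    )


def _adapter_trim_point(seq: str, adapter: str, max_error_rate: float) -> int:
    """Leftmost position where a prefix of `adapter` matches the read suffix.

    Semi-global: the adapter may run off the 3' end of the read.  A match
    of length L tolerates floor(L * max_error_rate) mismatches.  Ties are
    broken toward the longest trim (smallest position).  Returns len(seq)
    if no acceptable match exists.
    """
    n = len(seq)
    for i in range(n):
        L = min(len(adapter), n - i)
        if L < 3:  # require a minimally informative overlap
            break
        allowed = int(max_error_rate * L)
        mism = 0
        ok = True
        for a, b in zip(seq[i: i + L], adapter[:L]):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return i
    return n


def _trim_adapter_fixpoint(
    seq: str, qual: str, adapter: str, max_error_rate: float
) -> tuple[str, str]:
    """Apply adapter trimming until stable.

    Removing an error-tolerant match can expose a shorter residual match
    at the new 3' end; iterating to a fixpoint makes trimming idempotent.
    """
    while True:
        cut = _adapter_trim_point(seq, adapter, max_error_rate)
        if cut == len(seq):
            return seq, qual
        seq, qual = seq[:cut], qual[:cut]


def _quality_trim_point(qual: str, cutoff: int) -> int:
    """3' cut position by the running-sum rule (BWA/cutadapt -q semantics).

    Let S(i) = sum over j >= i of (q_j - cutoff).  The read is cut at the
    i minimising S(i) when that minimum is negative; otherwise it is kept
    whole.  A single high-quality base inside a low-quality tail therefore
    does not stop the trim.
    """
    best_pos = len(qual)
    best_sum = 0
    total = 0
    for i in range(len(qual) - 1, -1, -1):
        total += (ord(qual[i]) - 33) - cutoff
        if total < best_sum:
            best_sum = total
            best_pos = i
    return best_pos


def trim_and_filter(
    rec: ReadRecord,
    adapters: tuple[str, str] = ("", ""),
    min_len: int = DEFAULT_MIN_LEN,
    qual_cutoff: int = DEFAULT_QUAL_CUTOFF,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> tuple[Optional[ReadRecord], Optional[str]]:
    """Adapter- and quality-trim both mates; reject if read 1 gets short.

    adapters = (adapter for read 1, adapter for read 2); empty strings
    disable adapter matching for that mate.
    """
    seq1, qual1 = rec.seq1, rec.qual1
    seq2, qual2 = rec.seq2, rec.qual2
    if adapters[0]:
        seq1, qual1 = _trim_adapter_fixpoint(seq1, qual1, adapters[0], max_error_rate)
    if adapters[1] and seq2:
        seq2, qual2 = _trim_adapter_fixpoint(seq2, qual2, adapters[1], max_error_rate)
    cut = _quality_trim_point(qual1, qual_cutoff)
    seq1, qual1 = seq1[:cut], qual1[:cut]
    if seq2:
        cut = _quality_trim_point(qual2, qual_cutoff)
        seq2, qual2 = seq2[:cut], qual2[:cut]
    if len(seq1) < min_len:
        return None, "too_short"
    return (
        ReadRecord(rec.read_id, rec.umi, seq1, qual1, seq2, qual2),
        None,
    )


def prepare_reads(
    reads: Iterable[tuple[str, str, str, str, str]],
    umi_len: int,
    adapters: tuple[str, str] = ("", ""),
    min_len: int = DEFAULT_MIN_LEN,
    qual_cutoff: int = DEFAULT_QUAL_CUTOFF,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> tuple[list[ReadRecord], PrepStats]:
    """Run extraction + trimming over a library; conserve read accounting."""
    stats = PrepStats()
    out: list[ReadRecord] = []
    for rid, s1, q1, s2, q2 in reads:
        stats.n_input += 1
        rec, reason = extract_umi_and_spacer(rid, s1, q1, s2, q2, umi_len)
        if rec is None:
            stats.reject(reason)
            continue
        rec, reason = trim_and_filter(rec, adapters, min_len, qual_cutoff, max_error_rate)
        if rec is None:
            stats.reject(reason)
            continue
        stats.n_accepted += 1
        out.append(rec)
    return out, stats
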