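"""k-mer counting, greedy tail extension, and the extension-confirmed
merge modes.

A first pass over the input builds a table of canonical k-mer counts; a
second pass merges.  For each pair, both reads are extended on the tail
end only by walking the k-mer graph greedily; extension halts at a branch
k-mer (more than one plausible successor), at low depth, or at the
requested length.  The overlap engine is then re-run on the extended pair
and its insert size S1 compared with the original pair's S0:

* REM ("require extension match") accepts S0 when S1 confirms it, and can
  rescue initially non-overlapping pairs by accepting S1 when there was no
  S0 — producing merged reads longer than the summed read lengths.
* RSEM ("require strict extension match") accepts only a confirmed S0, so
  its merges are a subset of default mode's and always shorter than L1+L2.

Because extension is tail-only, read start positions are fixed and the
extended pair's implied insert size is directly comparable to S0.
Extended bases are used only to determine S1; accepted merges are built
from the original reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .consensus_merge import Q_CAP_DEFAULT, MergedRead, build_merged_read
from .io_formats import Read, ReadPair
from .overlap_engine import (
    DEFAULT_PROFILE,
    MergeDecision,
    MergeStatus,
    SensitivityProfile,
    encode_bases,
    find_overlap,
    reverse_complement,
)

DEFAULT_K = 31
#: Quality assigned to synthetic extension bases.
EXTENSION_QUALITY = 20
_BASES = "ACGT"


def _powers(k: int) -> np.ndarray:
    return 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)


def encode_kmer(seq: str) -> int:
    """2-bit big-endian encoding of an N-free k-mer."""
    code = 0
    for ch in seq:
        code = (code << 2) | _BASES.index(ch)
    return code


def revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def canonical_code(code: int, k: int) -> int:
    return min(code, revcomp_code(code, k))


@dataclass(slots=True)
class KmerTable:
    """Counts of canonical (strand-neutral) k-mers, keyed by 2-bit code."""

    k: int
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not (1 < self.k < 32) or self.k % 2 == 0:
            raise ValueError("k must be odd and in (1, 32)")

    def get(self, canonical: int) -> int:
        return self.counts.get(canonical, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def count_seq(self, seq: str) -> int:
        """Count of the canonical form of an explicit k-mer string."""
        if len(seq) != self.k or "N" in seq:
            return 0
        return self.get(canonical_code(encode_kmer(seq), self.k))


def _window_canonicals(seq: str, k: int) -> np.ndarray:
    """Canonical codes of all N-free k-mer windows of *seq*."""
    codes = encode_bases(seq).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    pw = _powers(k)
    fwd = sliding_window_view(codes, k) @ pw
    rc_codes = np.where(codes[::-1] >= 0, 3 - codes[::-1], -1)
    rev = (sliding_window_view(rc_codes, k) @ pw)[::-1]
    valid = sliding_window_view(codes >= 0, k).all(axis=1)
    return np.minimum(fwd, rev)[valid]


def add_read_kmers(table: KmerTable, read: Read) -> None:
    windows = _window_canonicals(read.seq, table.k)
    if len(windows):
        table.counts.update(windows.tolist())


def build_kmer_table(pairs: Iterable[ReadPair], k: int = DEFAULT_K) -> KmerTable:
    """Count canonical k-mers over every read of *pairs*; N-containing
    windows contribute nothing."""
    table = KmerTable(k)
    for pair in pairs:
        add_read_kmers(table, pair.r1)
        add_read_kmers(table, pair.r2)
    return table


@dataclass(slots=True)
class ExtensionResult:
    extended: Read
    added: int
    stop_reason: str  # max_length | branch | low_depth | no_seed


def extend_tail(
    read: Read,
    table: KmerTable,
    max_ext: int = 50,
    min_depth: int = 2,
    branch_min: int = 2,
    branch_ratio: float = 8.0,
    ext_quality: int = EXTENSION_QUALITY,
) -> ExtensionResult:
    """Greedily extend the 3' tail of *read* by up to *max_ext* bases.

    From the terminal k-mer, the four possible successors are looked up;
    the best is appended when its depth reaches *min_depth* and the
    runner-up stays below max(branch_min, best / branch_ratio) — otherwise
    the walk stops at a branch.  A terminal k-mer that is absent from the
    table (or N-containing, or a read shorter than k) cannot seed a walk.
    """
    k = table.k
    if max_ext <= 0:
        return ExtensionResult(read, 0, "max_length")
    tail = read.seq[-k:]
    if len(read.seq) < k or "N" in tail:
        return ExtensionResult(read, 0, "no_seed")
    fwd = encode_kmer(tail)
    rev = revcomp_code(fwd, k)
    if table.get(min(fwd, rev)) < 1:
        return ExtensionResult(read, 0, "no_seed")

    mask = (1 << (2 * (k - 1))) - 1
    shift = 2 * (k - 1)
    added: list[str] = []
    reason = "max_length"
    for _ in range(max_ext):
        stem = (fwd & mask) << 2
        rstem = rev >> 2
        depths = []
        for b in range(4):
            fn = stem | b
            rn = ((3 - b) << shift) | rstem
            depths.append(table.get(fn if fn <= rn else rn))
        order = sorted(range(4), key=depths.__getitem__, reverse=True)
        best_b, second_b = order[0], order[1]
        best, second = depths[best_b], depths[second_b]
        if best < min_depth:
            reason = "low_depth"
            break
        if second >= max(branch_min, best / branch_ratio):
            reason = "branch"
            break
        added.append(_BASES[best_b])
        fwd = stem | best_b
        rev = ((3 - best_b) << shift) | rstem
    extended = read
    if added:
        extended = Read(
            read.id,
            read.seq + "".join(added),
            read.qual + bytes([ext_quality]) * len(added),
        )
    return ExtensionResult(extended, len(added), reason)


def merge_with_extension(
    pair: ReadPair,
    table: KmerTable,
    mode: str = "rem",
    profile: SensitivityProfile = DEFAULT_PROFILE,
    adapters: Optional[tuple[Optional[str], Optional[str]]] = None,
    max_ext: int = 50,
    min_depth: int = 2,
    branch_min: int = 2,
    branch_ratio: float = 8.0,
    q_cap: int = Q_CAP_DEFAULT,
) -> MergeDecision:
    """Extension-confirmed merging of one pair (REM or RSEM logic)."""
    if mode not in ("rem", "rsem"):
        raise ValueError(f"mode must be 'rem' or 'rsem', got {mode!r}")
    d0 = find_overlap(pair, profile, adapters)
    s0 = (
        d0.candidate.insert_size
        if d0.status is MergeStatus.MERGED and d0.candidate is not None
        else None
    )
    e1 = extend_tail(pair.r1, table, max_ext, min_depth, branch_min, branch_ratio)
    e2 = extend_tail(pair.r2, table, max_ext, min_depth, branch_min, branch_ratio)
    if e1.added == 0 and e2.added == 0:
        # Extension failed outright: the overlap-only insert size stands.
        return _finalize(d0, pair, s0, q_cap)

    # No adapter gate here: the extended tails are k-mer walk output, so an
    # overhang past the insert end is genomic continuation, not adapter.
    # Adapter agreement was already enforced on the original reads for S0.
    dx = find_overlap(ReadPair(e1.extended, e2.extended), profile)
    s1 = (
        dx.candidate.insert_size
        if dx.status is MergeStatus.MERGED and dx.candidate is not None
        else None
    )

    if mode == "rem":
        if s0 is not None and s1 == s0:
            return _finalize(d0, pair, s0, q_cap)
        if s0 is None and s1 is not None:
            return _finalize(dx, pair, s1, q_cap)
        if s0 is None and s1 is None:
            return MergeDecision(d0.status, candidate=d0.candidate)
        return MergeDecision(MergeStatus.AMBIGUOUS, candidate=d0.candidate)
    # rsem
    if s0 is not None and s1 == s0:
        return _finalize(d0, pair, s0, q_cap)
    if s0 is None:
        return MergeDecision(d0.status, candidate=d0.candidate)
    return MergeDecision(MergeStatus.AMBIGUOUS, candidate=d0.candidate)


def _finalize(
    decision: MergeDecision, pair: ReadPair, s: Optional[int], q_cap: int
) -> MergeDecision:
    """Attach the consensus built from the ORIGINAL reads at insert *s*."""
    if decision.status is not MergeStatus.MERGED or s is None:
        return MergeDecision(decision.status, candidate=decision.candidate)
    merged = build_merged_read(
        pair.r1, reverse_complement(pair.r2), s, q_cap=q_cap, allow_gap=True
    )
    return MergeDecision(MergeStatus.MERGED, decision.candidate, merged)


def kfilter_gate(
    merged: Read, table: KmerTable, min_depth: int = 1
) -> bool:
    """Post-merge sanity check: every N-free k-mer of the merged read must
    have been seen in the input at *min_depth* or more; a junction k-mer
    absent from the input marks the overlap as wrong.  Reads shorter than
    k pass vacuously.
    """
    windows = _window_canonicals(merged.seq, table.k)
    for code in windows.tolist():
        if table.counts.get(code, 0) < min_depth:
            return False
    return True
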