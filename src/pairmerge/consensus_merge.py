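"""Consensus construction for accepted overlaps.

The merged read has length exactly equal to the accepted insert size S.
For tail-only overlaps it is the non-overlapping head of read 1, the
base-by-base consensus of the overlap, and the non-overlapping tail of
reverse-complemented read 2.  For read-through inserts (S shorter than a
read) it is pure consensus trimmed to S.  Matching bases get a boosted
quality (sum of parents, capped); mismatching bases keep the higher-quality
base at the quality difference, falling to N/0 on an exact quality tie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import Read, ReadPair
from .overlap_engine import (
    DEFAULT_PROFILE,
    MergeDecision,
    MergeStatus,
    SensitivityProfile,
    decode_bases,
    encode_bases,
    find_overlap,
    reverse_complement,
)

#: Conventional Illumina quality ceiling for boosted matching bases.
Q_CAP_DEFAULT = 41


@dataclass(frozen=True, slots=True)
class MergedRead(Read):
    """A merged read annotated with the insert size it was built at."""

    source_insert: int = 0


def consensus_base(
    b1: str, q1: int, b2: str, q2: int, q_cap: int = Q_CAP_DEFAULT
) -> tuple[str, int]:
    """Consensus of two aligned bases.

    Agreement boosts the quality to min(q1+q2, q_cap); disagreement keeps
    the higher-quality base at quality |q1-q2|, or N at 0 on a tie.  An N
    defers to the other base.
    """
    if b1 == "N" and b2 == "N":
        return "N", 0
    if b1 == "N":
        return b2, q2
    if b2 == "N":
        return b1, q1
    if b1 == b2:
        return b1, min(q1 + q2, q_cap)
    if q1 > q2:
        return b1, q1 - q2
    if q2 > q1:
        return b2, q2 - q1
    return "N", 0


def _consensus_arrays(b1, q1, b2, q2, q_cap: int):
    n1, n2 = b1 < 0, b2 < 0
    match = (b1 == b2) & ~n1
    conds = [
        n1 & n2,
        n1,
        n2,
        match,
        q1 > q2,
        q2 > q1,
    ]
    base = np.select(conds, [-1, b2, b1, b1, b1, b2], default=-1)
    qual = np.select(
        conds,
        [0, q2, q1, np.minimum(q1 + q2, q_cap), q1 - q2, q2 - q1],
        default=0,
    )
    return base, qual


def build_merged_read(
    r1: Read,
    r2rc: Read,
    insert_size: int,
    *,
    q_cap: int = Q_CAP_DEFAULT,
    allow_gap: bool = False,
) -> MergedRead:
    """Assemble the merged read for an accepted insert size.

    With ``allow_gap`` (k-mer extension rescue of non-overlapping pairs),
    insert sizes of L1+L2 and beyond are permitted; the positions covered
    by neither read are filled with N at quality 0.
    """
    L1, L2 = len(r1), len(r2rc)
    s = insert_size
    if s < 1 or (s >= L1 + L2 and not allow_gap):
        raise ValueError(
            f"insert size {s} outside [1, {L1 + L2 - 1}] for reads of "
            f"length {L1} and {L2}"
        )
    if s >= L1 + L2:
        gap = s - L1 - L2
        return MergedRead(
            r1.id,
            r1.seq + "N" * gap + r2rc.seq,
            r1.qual + b"\x00" * gap + r2rc.qual,
            source_insert=s,
        )
    o = s - L2
    j0, j1 = max(0, o), min(L1, s)
    b1 = encode_bases(r1.seq)[j0:j1]
    b2 = encode_bases(r2rc.seq)[j0 - o:j1 - o]
    q1 = np.frombuffer(r1.qual, dtype=np.uint8)[j0:j1].astype(np.int32)
    q2 = np.frombuffer(r2rc.qual, dtype=np.uint8)[j0 - o:j1 - o].astype(np.int32)
    cons_b, cons_q = _consensus_arrays(b1, q1, b2, q2, q_cap)
    seq = r1.seq[:j0] + decode_bases(cons_b) + r2rc.seq[j1 - o:]
    qual = r1.qual[:j0] + cons_q.astype(np.uint8).tobytes() + r2rc.qual[j1 - o:]
    assert len(seq) == s
    return MergedRead(r1.id, seq, qual, source_insert=s)


def merge_pair(
    pair: ReadPair,
    profile: SensitivityProfile = DEFAULT_PROFILE,
    adapters: Optional[tuple[Optional[str], Optional[str]]] = None,
    q_cap: int = Q_CAP_DEFAULT,
) -> MergeDecision:
    """Overlap detection plus consensus: the one-call merge of a pair."""
    decision = find_overlap(pair, profile, adapters)
    if decision.status is MergeStatus.MERGED:
        assert decision.candidate is not None
        decision.merged = build_merged_read(
            pair.r1,
            reverse_complement(pair.r2),
            decision.candidate.insert_size,
            q_cap=q_cap,
        )
    return decision
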