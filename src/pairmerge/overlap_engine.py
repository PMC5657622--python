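"""Gap-free overlap detection between read pairs.

The best relative placement of read 1 against reverse-complemented read 2
is chosen in "ratio mode": every candidate insert size S is scored by

    R = (B + C0) / (B + G)

where G and B are the match and mismatch counts over the implied overlap
(indels are not considered).  The lowest-ratio candidate is then vetted by
a ladder of heuristic gates — an absolute ratio ceiling, separation from
the runner-up, a complexity-adjusted minimum overlap, an insert-size
floor, optional flat-mode (minimum-mismatch) confirmation or rescue,
adapter agreement for read-through inserts, an expected-mismatch budget
derived from quality scores, and a binomial tail test on the observed
match/mismatch pattern.  Each gate's constant lives on a
:class:`SensitivityProfile`; named presets scale them into a monotone
sensitivity ladder.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.special import bdtrc

from .io_formats import Read, ReadPair

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Phred -> error probability lookup.
PHRED_TO_PROB = 10.0 ** (-np.arange(94) / 10.0)

#: Minimum-overlap demanded of a zero-entropy (homopolymer) pair.
COMPLEXITY_V_MAX = 40
#: Normalized dinucleotide entropy at and above which V hits its floor (0).
COMPLEXITY_H0 = 0.9


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to int8 codes A=0 C=1 G=2 T=3, N (or other) = -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    out = np.where(codes < 0, 4, codes).astype(np.intp)
    return _DECODE[out].tobytes().decode("ascii")


def reverse_complement(read: Read) -> Read:
    """Reverse-complement the sequence and reverse the qualities."""
    bad = re.search(r"[^ACGTN]", read.seq)
    if bad is not None:
        raise ValueError(
            f"illegal character {read.seq[bad.start()]!r} at position "
            f"{bad.start()}"
        )
    return Read(read.id, read.seq.translate(_COMPLEMENT)[::-1], read.qual[::-1])


class MergeStatus(str, Enum):
    MERGED = "merged"
    NO_OVERLAP = "no_overlap"
    INVALID = "invalid"
    AMBIGUOUS = "ambiguous"
    TOO_SHORT_OVERLAP = "too_short_overlap"
    TOO_SHORT_INSERT = "too_short_insert"
    ADAPTER_MISMATCH = "adapter_mismatch"
    TOO_MANY_MISMATCHES = "too_many_mismatches"
    IMPROBABLE_PATTERN = "improbable_pattern"
    KMER_FILTER = "kmer_filter"


@dataclass(frozen=True, slots=True)
class OverlapCandidate:
    """One candidate insert size with its overlap evidence.

    ``matches``/``mismatches`` are plain counts, or quality-derived weights
    when the profile's ``ouq`` flag is set.
    """

    insert_size: int
    overlap_len: int
    matches: float
    mismatches: float
    ratio: float


@dataclass(slots=True)
class MergeDecision:
    status: MergeStatus
    candidate: Optional[OverlapCandidate] = None
    merged: Optional[Read] = None


@dataclass(frozen=True)
class SensitivityProfile:
    """Gate constants plus mode switches, organized as named presets.

    The preset ladder (ustrict .. xloose) scales ``c1`` and ``c2``
    geometrically so each looser preset strictly relaxes the previous one,
    and toggles flat-mode confirmation (ustrict/xstrict) or rescue (xloose).
    """

    c0: float = 0.4          # pseudocount in the ratio
    c1: float = 0.12         # max accepted best ratio R1
    c2: float = 6.0          # separation factor: require R1*c2 <= R2
    c3: float = 0.05         # floor on the second-best ratio
    c4: int = 12             # minimum overlap matches (bases)
    c5: float = 8.0          # expected-mismatch multiplier
    c6_insert: int = 35      # minimum insert size (bases)
    c6_prob: float = 1e-5    # minimum pattern probability
    use_flat_confirm: bool = False   # xstrict / ustrict
    use_flat_rescue: bool = False    # xloose
    ouq: bool = False        # quality-weighted match/mismatch counts
    preset_name: str = "default"

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and 0 < self.c1 < 1 and self.c2 >= 1
                and self.c4 >= 1 and self.c6_insert >= 1):
            raise ValueError("sensitivity constants out of range")


#: Preset ladder, strictest first.  Negative steps tighten c1 (halving) and
#: c2 (x1.4); positive steps loosen them symmetrically.
PRESET_STEPS = {
    "ustrict": -4, "xstrict": -3, "vstrict": -2, "strict": -1,
    "default": 0, "loose": 1, "vloose": 2, "xloose": 3,
}
PRESET_ORDER = list(PRESET_STEPS)


def preset(name: str, **overrides) -> SensitivityProfile:
    """Build the named sensitivity preset (optionally overriding fields)."""
    if name not in PRESET_STEPS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {PRESET_ORDER}"
        )
    step = PRESET_STEPS[name]
    base = SensitivityProfile()
    prof = replace(
        base,
        c1=min(base.c1 * 2.0 ** step, 0.99),
        c2=max(base.c2 * 1.4 ** (-step), 1.0),
        use_flat_confirm=name in ("ustrict", "xstrict"),
        use_flat_rescue=name == "xloose",
        preset_name=name,
    )
    return replace(prof, **overrides) if overrides else prof


DEFAULT_PROFILE = preset("default")


def _overlap_count_arrays(c1: np.ndarray, c2rc: np.ndarray):
    """Match and comparable-position counts for every insert size.

    Returns ``(G, M)`` arrays of length L1+L2-1 where index S-1 holds the
    counts for insert size S: read-1 base j is compared against
    reverse-complemented read-2 base j-(S-L2).  Positions where either
    base is N are excluded from both counts.
    """
    g = np.zeros(len(c1) + len(c2rc) - 1)
    for b in range(4):
        g += np.convolve(
            (c1 == b).astype(np.float64), (c2rc == b).astype(np.float64)[::-1]
        )
    m = np.convolve(
        (c1 >= 0).astype(np.float64), (c2rc >= 0).astype(np.float64)[::-1]
    )
    return np.rint(g).astype(np.int64), np.rint(m).astype(np.int64)


def _overlap_slices(L1: int, L2: int, s: int):
    """Index ranges of the overlap for insert size *s*: read-1 positions
    [j0, j1) align with reverse-complemented read-2 positions [j0-o, j1-o)."""
    o = s - L2
    return max(0, o), min(L1, s), o


def _ouq_counts(r1: Read, r2rc: Read, c1, c2, q1p, q2p, s: int):
    """Quality-weighted match/mismatch sums for insert size *s*.

    Match weight 1 - p1 - p2 and mismatch weight 1 - p1*p2, floored at 0.1;
    informative only when quality scores are accurate.
    """
    j0, j1, o = _overlap_slices(len(c1), len(c2), s)
    a, b = c1[j0:j1], c2[j0 - o:j1 - o]
    ok = (a >= 0) & (b >= 0)
    p1, p2 = q1p[j0:j1], q2p[j0 - o:j1 - o]
    match = (a == b) & ok
    mism = (a != b) & ok
    gw = np.maximum(1.0 - p1 - p2, 0.1)[match].sum()
    bw = np.maximum(1.0 - p1 * p2, 0.1)[mism].sum()
    return float(gw), float(bw), int(ok.sum())


def enumerate_candidates(
    r1: Read, r2rc: Read, profile: SensitivityProfile = DEFAULT_PROFILE
) -> list[OverlapCandidate]:
    """Score every candidate insert size from the profile's insert floor to
    L1+L2-1.  Candidates with no comparable (non-N) positions are skipped."""
    c1, c2 = encode_bases(r1.seq), encode_bases(r2rc.seq)
    L1, L2 = len(c1), len(c2)
    g_all, m_all = _overlap_count_arrays(c1, c2)
    s_lo = max(1, profile.c6_insert)
    out: list[OverlapCandidate] = []
    if profile.ouq:
        q1p = PHRED_TO_PROB[np.frombuffer(r1.qual, dtype=np.uint8)]
        q2p = PHRED_TO_PROB[np.frombuffer(r2rc.qual, dtype=np.uint8)]
    for s in range(s_lo, L1 + L2):
        if m_all[s - 1] == 0:
            continue
        w = min(L1, s) + min(L2, s) - s
        if profile.ouq:
            g, b, _ = _ouq_counts(r1, r2rc, c1, c2, q1p, q2p, s)
            if g + b <= 0:
                continue
        else:
            g = int(g_all[s - 1])
            b = int(m_all[s - 1] - g_all[s - 1])
        out.append(
            OverlapCandidate(s, w, g, b, (b + profile.c0) / (b + g))
        )
    return out


class NoOverlapError(ValueError):
    """No candidate insert size had any comparable positions."""


def best_two_ratios(
    candidates: Sequence[OverlapCandidate],
) -> tuple[OverlapCandidate, float]:
    """Lowest-ratio candidate and the runner-up ratio (+inf if alone).
    Ties on the ratio go to the smaller insert size (longer overlap)."""
    if not candidates:
        raise NoOverlapError("no overlap candidates")
    best = min(candidates, key=lambda c: (c.ratio, c.insert_size))
    r2 = min(
        (c.ratio for c in candidates if c is not best), default=math.inf
    )
    return best, r2


def complexity_min_overlap(
    r1: Read, r2: Read, profile: SensitivityProfile = DEFAULT_PROFILE
) -> int:
    """Minimum-overlap requirement V from pair sequence complexity.

    Complexity is the Shannon entropy of the pooled dinucleotide
    distribution, normalized to [0, 1].  V decreases linearly from
    ``COMPLEXITY_V_MAX`` at zero entropy to 0 at normalized entropy
    ``COMPLEXITY_H0`` and beyond, so homopolymers demand long overlaps
    while maximum-entropy sequence falls back to the flat c4 floor.
    """
    counts = np.zeros(16, dtype=np.int64)
    for read in (r1, r2):
        c = encode_bases(read.seq)
        if len(c) < 2:
            continue
        a, b = c[:-1], c[1:]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            counts += np.bincount((a[ok] * 4 + b[ok]), minlength=16)
    total = counts.sum()
    if total == 0:
        return COMPLEXITY_V_MAX
    p = counts[counts > 0] / total
    h = float(-(p * np.log2(p)).sum()) / 4.0  # log2(16) == 4
    return int(round(COMPLEXITY_V_MAX * max(0.0, 1.0 - h / COMPLEXITY_H0)))


def apply_gates(
    best: OverlapCandidate,
    r2_ratio: float,
    complexity_min: int,
    profile: SensitivityProfile = DEFAULT_PROFILE,
) -> Optional[MergeStatus]:
    """Primary acceptance heuristics, in order; None means the candidate
    survives to the secondary (adapter/quality/pattern) gates."""
    if best.ratio > profile.c1:
        return MergeStatus.INVALID
    if best.ratio * profile.c2 > r2_ratio:
        return MergeStatus.AMBIGUOUS
    if r2_ratio < profile.c3:
        return MergeStatus.AMBIGUOUS
    if best.matches < max(profile.c4, complexity_min):
        return MergeStatus.TOO_SHORT_OVERLAP
    if best.insert_size < profile.c6_insert:
        return MergeStatus.TOO_SHORT_INSERT
    return None


def flat_mode_best(
    r1: Read, r2rc: Read, profile: SensitivityProfile = DEFAULT_PROFILE
) -> Optional[OverlapCandidate]:
    """Minimum-mismatch candidate subject to the overlap/insert floors.

    Used only at extreme sensitivity settings: as a cross-check on the
    ratio-mode choice (xstrict/ustrict) or as a fallback when ratio mode
    produced nothing (xloose).
    """
    c1, c2 = encode_bases(r1.seq), encode_bases(r2rc.seq)
    L1, L2 = len(c1), len(c2)
    g_all, m_all = _overlap_count_arrays(c1, c2)
    v = complexity_min_overlap(r1, r2rc, profile)
    floor = max(profile.c4, v)
    s_lo = max(1, profile.c6_insert)
    g_all, m_all = g_all[s_lo - 1:], m_all[s_lo - 1:]
    mask = (m_all > 0) & (g_all >= floor)
    if not mask.any():
        return None
    b_all = np.where(mask, m_all - g_all, np.iinfo(np.int64).max)
    i = int(np.argmin(b_all))  # first minimum == smallest insert size
    s = i + s_lo
    b = int(b_all[i])
    g = int(g_all[i])
    w = min(L1, s) + min(L2, s) - s
    return OverlapCandidate(s, w, g, b, (b + profile.c0) / (b + g))


ADAPTER_MISMATCH_FRACTION = 0.25


def adapter_check(
    r1: Read,
    r2rc: Read,
    candidate: OverlapCandidate,
    adapter1: Optional[str],
    adapter2: Optional[str],
) -> bool:
    """For read-through inserts, the bases past the insert end must look
    like the expected adapters.

    Read-1 bases beyond position S are compared to the prefix of
    *adapter1*, and read-2 (as sequenced) bases beyond S to the prefix of
    *adapter2*; each comparison passes when its mismatch fraction over the
    comparable (non-N) positions is at most 25%.  Skipped (pass) when no
    adapters are supplied or there is no overhang.
    """
    s = candidate.insert_size
    if adapter1 is None and adapter2 is None:
        return True
    r2_seq = r2rc.seq.translate(_COMPLEMENT)[::-1]  # back to as-sequenced
    for seq, adapter in ((r1.seq, adapter1), (r2_seq, adapter2)):
        if adapter is None or s >= len(seq):
            continue
        overhang = seq[s:]
        n = min(len(overhang), len(adapter))
        comparable = 0
        mismatches = 0
        for x, y in zip(overhang[:n], adapter[:n]):
            if x == "N" or y == "N":
                continue
            comparable += 1
            if x != y:
                mismatches += 1
        if comparable and mismatches / comparable > ADAPTER_MISMATCH_FRACTION:
            return False
    return True


def _overlap_quality_stats(r1: Read, r2rc: Read, s: int):
    """(expected mismatches E, comparable positions, observed mismatches)
    over the overlap implied by insert size *s*."""
    c1, c2 = encode_bases(r1.seq), encode_bases(r2rc.seq)
    j0, j1, o = _overlap_slices(len(c1), len(c2), s)
    a, b = c1[j0:j1], c2[j0 - o:j1 - o]
    ok = (a >= 0) & (b >= 0)
    p1 = PHRED_TO_PROB[np.frombuffer(r1.qual, dtype=np.uint8)][j0:j1][ok]
    p2 = PHRED_TO_PROB[np.frombuffer(r2rc.qual, dtype=np.uint8)][j0 - o:j1 - o][ok]
    e = float((p1 + p2 - (4.0 / 3.0) * p1 * p2).sum())
    b_obs = int(((a != b) & ok).sum())
    return e, int(ok.sum()), b_obs


def expected_mismatch_gate(
    r1: Read,
    r2rc: Read,
    candidate: OverlapCandidate,
    profile: SensitivityProfile = DEFAULT_PROFILE,
) -> bool:
    """Reject when observed mismatches exceed c5 times the number expected
    from the quality scores: E = sum(p1 + p2 - 4/3 p1 p2) over the overlap."""
    e, _, b_obs = _overlap_quality_stats(r1, r2rc, candidate.insert_size)
    return b_obs <= e * profile.c5


def pattern_probability_gate(
    r1: Read,
    r2rc: Read,
    candidate: OverlapCandidate,
    profile: SensitivityProfile = DEFAULT_PROFILE,
) -> tuple[float, bool]:
    """Binomial tail probability of seeing at least the observed mismatch
    count in W trials at the overlap's mean per-position mismatch rate
    r = E/W; reject when it drops below c6_prob."""
    e, w, b_obs = _overlap_quality_stats(r1, r2rc, candidate.insert_size)
    if w == 0 or b_obs == 0:
        return 1.0, True
    rate = min(max(e / w, 1e-9), 0.999)
    p = float(bdtrc(b_obs - 1, w, rate))
    return p, p >= profile.c6_prob


def find_overlap(
    pair: ReadPair,
    profile: SensitivityProfile = DEFAULT_PROFILE,
    adapters: Optional[tuple[Optional[str], Optional[str]]] = None,
) -> MergeDecision:
    """Full overlap-detection pipeline for one pair; the returned decision
    carries the accepted candidate but no consensus read (see
    :mod:`pairmerge.consensus_merge`)."""
    r1 = pair.r1
    r2rc = reverse_complement(pair.r2)
    c1, c2 = encode_bases(r1.seq), encode_bases(r2rc.seq)
    L1, L2 = len(c1), len(c2)

    best: Optional[OverlapCandidate] = None
    fail: Optional[MergeStatus] = None
    v = complexity_min_overlap(r1, pair.r2, profile)

    if profile.ouq:
        cands = enumerate_candidates(r1, r2rc, profile)
        if not cands:
            fail = MergeStatus.NO_OVERLAP
        else:
            best, r2_ratio = best_two_ratios(cands)
            fail = apply_gates(best, r2_ratio, v, profile)
    else:
        g_all, m_all = _overlap_count_arrays(c1, c2)
        s_lo = max(1, profile.c6_insert)
        g_all = g_all[s_lo - 1:]
        m_all = m_all[s_lo - 1:]
        mask = m_all > 0
        if not mask.any():
            fail = MergeStatus.NO_OVERLAP
        else:
            b_all = m_all - g_all
            with np.errstate(divide="ignore", invalid="ignore"):
                r_all = np.where(
                    mask, (b_all + profile.c0) / np.maximum(m_all, 1), np.inf
                )
            i_best = int(np.argmin(r_all))  # first minimum == smallest S
            s_best = i_best + s_lo
            r1_ratio = float(r_all[i_best])
            r_all[i_best] = np.inf
            r2_ratio = float(r_all.min()) if len(r_all) > 1 else math.inf
            w = min(L1, s_best) + min(L2, s_best) - s_best
            best = OverlapCandidate(
                s_best, w, int(g_all[i_best]), int(b_all[i_best]), r1_ratio
            )
            fail = apply_gates(best, r2_ratio, v, profile)

    if fail is None and profile.use_flat_confirm and best is not None:
        flat = flat_mode_best(r1, r2rc, profile)
        if flat is None or flat.insert_size != best.insert_size:
            fail = MergeStatus.AMBIGUOUS
    if fail is not None and profile.use_flat_rescue:
        flat = flat_mode_best(r1, r2rc, profile)
        if flat is not None:
            best, fail = flat, None

    if fail is not None:
        return MergeDecision(fail, candidate=best)
    assert best is not None

    if adapters is not None and best.insert_size < max(L1, L2):
        if not adapter_check(r1, r2rc, best, adapters[0], adapters[1]):
            return MergeDecision(MergeStatus.ADAPTER_MISMATCH, candidate=best)
    if not expected_mismatch_gate(r1, r2rc, best, profile):
        return MergeDecision(MergeStatus.TOO_MANY_MISMATCHES, candidate=best)
    _, ok = pattern_probability_gate(r1, r2rc, best, profile)
    if not ok:
        return MergeDecision(MergeStatus.IMPROBABLE_PATTERN, candidate=best)
    return MergeDecision(MergeStatus.MERGED, candidate=best)
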