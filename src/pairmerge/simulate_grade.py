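"""Synthetic paired-read simulation and merge grading.

The simulator emulates a randomly sheared shotgun library: fragments are
drawn from a (random or supplied) genome with Gaussian-distributed insert
sizes, sequenced from a uniformly chosen strand, with per-base Phred
qualities from a floor/mode/ceiling/variance model and substitution
errors at the rate the qualities imply.  Inserts shorter than the read
length read through into the supplied adapter sequences.  Every read
header records the true insert size, which is the grading contract: a
merged read is correct exactly when its length equals that insert size.

The grade report gives correct/incorrect percentages and a
signal-to-noise ratio, SNR = 10*log10(C/I) in decibels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import Read, ReadPair
from .overlap_engine import (
    PHRED_TO_PROB,
    MergeDecision,
    MergeStatus,
    decode_bases,
    encode_bases,
)

#: Adapter pair of the fragment library the simulator emulates.
FRAG_ADAPTER_1 = "GACGCTGCCGACGAATAGAGAGGTGTAGATCTCGGTGGTCGCCGTATCATT"
FRAG_ADAPTER_2 = "CCGAGCCCACGAGACTAAGGCGAATCTCGTATGCCGTCTTCTGCTTG"

_INSERT_RE = re.compile(r"insert=(\d+)")
_QUALITY_CLAMP = (2, 41)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults mirror a standard 2x150 shotgun run: Gaussian insert sizes
    truncated to [100, 400] (mean at the midpoint, sd a sixth of the
    range), and a quality model with floor 14, mode 24, ceiling 34 and
    per-base jitter 6.
    """

    n_pairs: int = 1000
    read_len: int = 150
    min_insert: int = 100
    max_insert: int = 400
    insert_mean: Optional[float] = None   # default: midpoint of the range
    insert_sd: Optional[float] = None     # default: range / 6
    minq: int = 14
    midq: int = 24
    maxq: int = 34
    qv: float = 6.0
    adapter1: str = FRAG_ADAPTER_1
    adapter2: str = FRAG_ADAPTER_2
    error_free: bool = False
    n_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_insert < 1 or self.min_insert > self.max_insert:
            raise ValueError("need 1 <= min_insert <= max_insert")
        if self.read_len < 1 or self.n_pairs < 0:
            raise ValueError("read_len and n_pairs must be positive")

    @property
    def mean(self) -> float:
        return (
            self.insert_mean
            if self.insert_mean is not None
            else (self.min_insert + self.max_insert) / 2.0
        )

    @property
    def sd(self) -> float:
        return (
            self.insert_sd
            if self.insert_sd is not None
            else max((self.max_insert - self.min_insert) / 6.0, 1e-9)
        )


def generate_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0
) -> str:
    """i.i.d. random genome with the requested GC content."""
    if length < 1 or not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("need length >= 1 and gc in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.int8)
    return decode_bases(codes)


def _truncated_gaussian_ints(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Rejection-sampled truncated Gaussian, rounded to ints in [lo, hi]."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled) + 16))
        draw = draw[(draw >= lo) & (draw <= hi)].astype(np.int64)
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


_RC_CODE = np.array([3, 2, 1, 0, -1], dtype=np.int8)  # index -1 -> N slot


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_CODE[codes[::-1]]


def simulate_pairs(
    genome: str, cfg: SimConfig
) -> list[ReadPair]:
    """Simulate read pairs; both mate headers carry ``insert=<S>``."""
    gcodes = encode_bases(genome)
    glen = len(gcodes)
    if glen < cfg.max_insert:
        raise ValueError("genome shorter than max_insert")
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_pairs, cfg.read_len
    inserts = _truncated_gaussian_ints(
        rng, n, cfg.mean, cfg.sd, cfg.min_insert, cfg.max_insert
    )
    starts = np.floor(rng.random(n) * (glen - inserts + 1)).astype(np.int64)
    strands = rng.integers(0, 2, size=n)
    if cfg.minq == cfg.maxq:
        means = np.full(n, float(cfg.midq))
    else:
        means = rng.triangular(cfg.minq, cfg.midq, cfg.maxq, size=n)
    a1 = encode_bases(cfg.adapter1) if cfg.adapter1 else np.empty(0, np.int8)
    a2 = encode_bases(cfg.adapter2) if cfg.adapter2 else np.empty(0, np.int8)

    pairs: list[ReadPair] = []
    for i in range(n):
        s = int(inserts[i])
        frag = gcodes[starts[i]:starts[i] + s]
        if strands[i]:
            frag = _revcomp_codes(frag)
        r1c = _fill_read(frag, a1, L, rng)
        r2c = _fill_read(_revcomp_codes(frag), a2, L, rng)
        header = f"s{i} insert={s}"
        pairs.append(
            ReadPair(
                _finish_read(header, r1c, means[i], cfg, rng),
                _finish_read(header, r2c, means[i], cfg, rng),
            )
        )
    return pairs


def _fill_read(
    frag: np.ndarray, adapter: np.ndarray, read_len: int, rng
) -> np.ndarray:
    """First *read_len* bases of fragment + adapter read-through, padded
    with random bases if the adapter is exhausted."""
    if len(frag) >= read_len:
        return frag[:read_len].copy()
    parts = [frag, adapter[: read_len - len(frag)]]
    short = read_len - len(frag) - len(parts[1])
    if short > 0:
        parts.append(rng.integers(0, 4, size=short).astype(np.int8))
    return np.concatenate(parts)


def _finish_read(
    header: str, codes: np.ndarray, mean_q: float, cfg: SimConfig, rng
) -> Read:
    L = len(codes)
    qual = np.clip(
        np.rint(mean_q + rng.normal(0.0, cfg.qv, size=L)),
        *_QUALITY_CLAMP,
    ).astype(np.uint8)
    codes = codes.copy()
    if not cfg.error_free:
        err = rng.random(L) < PHRED_TO_PROB[qual]
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            codes[err] = (codes[err] + shift) % 4
    if cfg.n_rate > 0:
        codes[rng.random(L) < cfg.n_rate] = -1
    return Read(header, decode_bases(codes), qual.tobytes())


def parse_true_insert(header: str) -> int:
    """Extract the true insert size from a simulator-renamed header."""
    m = _INSERT_RE.search(header)
    if m is None:
        raise ValueError(f"header {header!r} carries no insert= token")
    return int(m.group(1))


@dataclass(frozen=True)
class GradeReport:
    """Merge-accuracy tally over P input pairs: C correct, I incorrect,
    U unmerged; percentages and SNR derive from the counts."""

    pairs: int
    correct: int
    incorrect: int

    def __post_init__(self) -> None:
        if self.correct + self.incorrect > self.pairs:
            raise ValueError("more merged reads than input pairs")

    @property
    def unmerged(self) -> int:
        return self.pairs - self.correct - self.incorrect

    @property
    def correct_pct(self) -> float:
        return 100.0 * self.correct / self.pairs if self.pairs else 0.0

    @property
    def incorrect_pct(self) -> float:
        return 100.0 * self.incorrect / self.pairs if self.pairs else 0.0

    @property
    def snr_db(self) -> float:
        if self.incorrect == 0:
            return math.inf if self.correct > 0 else math.nan
        if self.correct == 0:
            return -math.inf
        return 10.0 * math.log10(self.correct / self.incorrect)

    def as_dict(self) -> dict:
        return {
            "pairs": self.pairs,
            "correct": self.correct,
            "incorrect": self.incorrect,
            "unmerged": self.unmerged,
            "correct_pct": self.correct_pct,
            "incorrect_pct": self.incorrect_pct,
            "snr_db": self.snr_db,
        }


def grade(merged: Iterable[Read], pairs: int) -> GradeReport:
    """Grade merged reads against the insert sizes in their headers.

    Correct means the merged length exactly equals the header's insert
    size; anything else counts as incorrect.
    """
    c = i = 0
    for read in merged:
        if len(read.seq) == parse_true_insert(read.id):
            c += 1
        else:
            i += 1
    return GradeReport(pairs, c, i)


def insert_histogram(
    decisions: Iterable[MergeDecision],
) -> dict[int, int]:
    """Histogram of accepted insert sizes over a stream of decisions."""
    hist: dict[int, int] = {}
    for d in decisions:
        if d.status is MergeStatus.MERGED and d.candidate is not None:
            s = d.candidate.insert_size
            hist[s] = hist.get(s, 0) + 1
    return dict(sorted(hist.items()))


def write_histogram(hist: Mapping[int, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("#insert\tcount\n")
        for s in sorted(hist):
            fh.write(f"{s}\t{hist[s]}\n")
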