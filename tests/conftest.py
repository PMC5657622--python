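"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest

from pairmerge.io_formats import Read, ReadPair

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_str(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def random_seq(rng: random.Random, length: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def make_read(seq: str, qual=30, rid: str = "r") -> Read:
    if isinstance(qual, int):
        qual = bytes([qual]) * len(seq)
    return Read(rid, seq, bytes(qual))


def pair_from_fragment(
    fragment: str, read_len: int, rid: str = "p", qual: int = 30
) -> ReadPair:
    """Error-free pair sequenced from an insert: r1 is the fragment head,
    r2 the reverse-complement head (both as sequenced)."""
    r1 = make_read(fragment[:read_len], qual, rid)
    r2 = make_read(revcomp_str(fragment)[:read_len], qual, rid)
    return ReadPair(r1, r2)


def brute_force_candidates(seq1: str, seq2rc: str, c0: float = 0.4, s_min: int = 1):
    """Literal per-position scan of every insert size: returns
    {S: (W, G, B, R)} skipping candidates with no comparable positions."""
    L1, L2 = len(seq1), len(seq2rc)
    out = {}
    for s in range(s_min, L1 + L2):
        o = s - L2
        g = b = 0
        for j in range(max(0, o), min(L1, s)):
            x, y = seq1[j], seq2rc[j - o]
            if x == "N" or y == "N":
                continue
            if x == y:
                g += 1
            else:
                b += 1
        if g + b == 0:
            continue
        w = min(L1, s) + min(L2, s) - s
        out[s] = (w, g, b, (b + c0) / (b + g))
    return out


def brute_force_best(cands: dict, key=None):
    """Best (lowest-ratio) insert size from a brute-force scan, ties to the
    smaller insert; also the runner-up ratio."""
    items = sorted(cands.items(), key=lambda kv: (kv[1][3], kv[0]))
    best_s, best = items[0]
    r2 = items[1][1][3] if len(items) > 1 else float("inf")
    return best_s, best, r2


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20170901)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(20170901)
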