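# Methods

## Overlap model

A read pair is assumed to come from opposite strands of one DNA
fragment, so after reverse-complementing read 2 the two reads agree over
the region where they cover the same fragment positions. Candidate
placements are parameterized directly by the implied insert size `S`
(the fragment length): read-1 position `j` aligns with reverse-
complemented read-2 position `j − (S − L2)`, and the overlap width is
`W = min(L1,S) + min(L2,S) − S`. Only substitutions are modelled —
placements are gap-free, so indel-containing pairs are expected to fail
the gates rather than merge at a shifted length. Positions where either
base is `N` are excluded from both the match count `G` and the mismatch
count `B`; candidates with no comparable positions are skipped.

Scoring uses the ratio `R = (B + C0)/(B + G)`. The pseudocount `C0`
penalizes short overlaps: a clean 4-base overlap scores `0.4/4 = 0.1`
while a clean 40-base overlap scores `0.01`, so longer evidence wins
without a separate length bonus. Ties on `R` resolve to the smaller
insert size, i.e. the longer overlap — the candidate with more evidence
— which also makes selection deterministic.

Candidate counting is vectorized: per-base one-hot channels of the two
reads are cross-correlated (`numpy.convolve` against the reversed
channel), which yields `G` and the comparable-position count for every
insert size in a handful of array operations per pair. The tests pin
this against a literal per-position scan.

## Acceptance gates and sensitivity presets

Gates run in a fixed order; the first failure labels the rejection:

| gate | constant | default | meaning |
|---|---|---|---|
| ratio ceiling | `C1` | 0.12 | best ratio `R1` must be small in absolute terms |
| separation | `C2` | 6 | runner-up must satisfy `R1·C2 ≤ R2` |
| runner-up floor | `C3` | 0.05 | a second near-perfect placement is ambiguity |
| overlap floor | `C4` | 12 bases | minimum matches, raised to `V` for low-complexity pairs |
| insert floor | `C6_insert` | 35 bases | shorter implied inserts are artifacts |
| adapter check | — | 25% mismatch cap | read-through overhangs must look like the declared adapters |
| mismatch budget | `C5` | 8 | observed `B` may not exceed `C5×` the expectation `E` from qualities |
| pattern test | `C6_prob` | 1e-5 | binomial tail probability of the mismatch count |

`E = Σ (p1 + p2 − 4/3·p1·p2)` over compared positions, with
`p = 10^(−Q/10)`; the same per-position rate `r = E/W` parameterizes the
binomial tail `P = Σ_{k≥B} C(W,k) r^k (1−r)^{W−k}` (computed with
`scipy.special.bdtrc`). The binomial model is the minimal choice
consistent with treating positions as independent given their quality
scores.

The complexity floor `V` is derived from the Shannon entropy of the
pair's pooled dinucleotide distribution, normalized to `[0,1]`: `V`
falls linearly from 40 bases at zero entropy to 0 at normalized entropy
0.9. Homopolymer-like pairs therefore need long overlaps, while random
sequence (normalized entropy ≈ 0.99) always sits at the floor, leaving
`C4` in charge.

Named presets (`ustrict, xstrict, vstrict, strict, default, loose,
vloose, xloose`) scale `C1` by powers of 2 and `C2` by powers of 1.4 so
each looser preset strictly relaxes the previous one — the merged set of
a stricter preset is provably a subset of any looser one, which the
acceptance tests verify on 50k simulated pairs. The two strictest
presets additionally require "flat mode" (global minimum-mismatch
placement, subject to the same floors) to agree with the ratio choice;
`xloose` uses flat mode as a fallback when ratio mode produced nothing.
The constant values themselves are engineering defaults exposed as
configuration, validated by the behavioral properties in the test suite
rather than by comparison with any particular external binary.

With `ouq` set, `G` and `B` become quality-weighted sums (match weight
`1 − p1 − p2`, mismatch weight `1 − p1·p2`, floored at 0.1). This only
helps when quality scores are trustworthy and is off by default.

## Consensus

A merged read has length exactly `S`. Matching bases keep the base and
get quality `min(q1 + q2, 41)` — an additive boost under the
conventional Illumina ceiling, chosen over a probabilistic update for
monotonicity and simplicity (configurable via `q_cap`). Mismatching
bases keep the higher-quality base at quality `|q1 − q2|`; an exact tie
produces `N` at quality 0, as does a double-`N`. A single `N` defers to
the called base. For read-through inserts (`S < L`) the result is pure
consensus trimmed to `S`, dropping the adapter overhang.

## k-mer modes

Pass one counts canonical (strand-minimum) 31-mers over all input reads;
`N`-containing windows are skipped. Pass two merges. Each read is
extended tail-only, up to 50 bases by default, stepping to the unique
successor k-mer whose count is at least `min_depth` (default 2) provided
the runner-up stays below `max(2, best/8)`; otherwise the walk stops at
a branch (two haplotypes, a repeat boundary, or an error k-mer that
happens to recur). Extension bases carry synthetic quality 20 and are
used **only** to compute the extended-pair insert size `S1`; they are
never emitted in output.

Because extension is tail-only, read start positions — and hence the
insert-size parameterization — are unchanged, so `S1` is directly
comparable to the original `S0`. REM accepts a confirmed `S0`, accepts
`S1` alone when overlap detection found nothing (this rescues
non-overlapping pairs; positions covered by neither original read are
filled with `N` at quality 0), and rejects disagreements, which is what
suppresses short-repeat-induced false merges. RSEM accepts only a
confirmed `S0`. When extension adds no bases to either read, `S0` stands
unchanged in both modes. If `S0` exists but the extended pair yields no
overlap at all, the pair is rejected as unconfirmed — the extended reads
are strictly more informative, so a vanishing overlap is treated as
evidence against `S0`.

The extended-pair overlap run omits the adapter gate: an extended read's
overhang past the insert end is k-mer walk output (genomic
continuation), not adapter, and adapter agreement was already enforced
when computing `S0`.

The optional `kfilter` gate rejects any merged read containing an
`N`-free k-mer absent from the input at the required depth (default 1)
— a chimeric junction produces exactly such k-mers.

## Simulator

The generator emulates a randomly sheared 2×150 fragment library.
Defaults are Gaussian insert sizes truncated to [100, 400] with the mean
at the midpoint and sd one sixth of the range; per-read mean quality
drawn from a triangular distribution with floor 14, mode 24 and ceiling
34; per-base quality adds Gaussian jitter of sd 6, clamped to [2, 41];
each base substitutes to a uniformly chosen different base with
probability `10^(−Q/10)`, so the realized error rate tracks the emitted
qualities exactly. Inserts shorter than the read length read through
into the library's adapter pair (read-2's adapter is 47 bp; an overhang
beyond it is random padding). Fragments come from a uniformly chosen
strand and position of an i.i.d. random genome of configurable GC
content. Both mate headers carry `insert=<S>`, the grading contract.

What the simulator does *not* reproduce: genomic repeat structure,
GC-dependent coverage and error biases, indels, quality miscalibration,
and position-dependent error profiles. Consequently incorrect merges are
far rarer here than on real genomes — on the standard 50k-pair runs the
grader typically measures zero — so passing tests demonstrate the
selection and gating machinery, not the false-positive rate to expect on
repeat-rich data. The tests that need wrong-merge pressure construct
repeats explicitly.

## Grading

`C` counts merged reads whose length exactly equals the header insert —
off-by-one is incorrect, deliberately, since a merged read's coordinates
are wrong if its length is. `C% = 100·C/P`, `I% = 100·I/P`,
`SNR = 10·log10(C/I)` dB, reported as `+inf` when `I = 0` and `C > 0`.
Conservation `C + I + U = P` is asserted structurally.

## Determinism and scale

Merging is per-pair and pure, so output is byte-identical for any worker
count and any read-buffer length (the worker pool maps buffers in input
order; gzip is written with a zero mtime). The simulator is deterministic
per seed. The acceptance checks run at 50,000 pairs on a 1 Mbp genome
(sequence depth 15×) and 10,000 non-overlapping pairs at depth 20 on a
150 kbp genome — sizes chosen so the full battery, including the
eight-preset ladder, completes in a few minutes on one CPU while keeping
binomial counting noise well below every asserted margin.

## Known limitations

* No indel-tolerant alignment: pairs from indel-bearing fragments are
  (correctly) rejected rather than repaired.
* The k-mer table is an exact in-memory dictionary — linear in distinct
  k-mers, fine for the target scale, not for terabase inputs.
* FASTA input carries no qualities; a constant (default Q30) stands in,
  which weakens the quality-driven gates.
* Error correction of unmerged pairs and adapter auto-detection are out
  of scope.
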