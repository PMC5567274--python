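"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from the definitions, without
reusing package internals (and without scipy for the exact tests), so a
test comparing package output to an oracle is a genuine dual-route
check.
"""

from __future__ import annotations

import math


# --- scar scores ----------------------------------------------------------


def ntai_oracle(profile, genome, min_len=11_000_000, tol=1_000_000,
                exclude_x=True) -> int:
    n = 0
    for chrom in genome.names:
        if exclude_x and chrom == "X":
            continue
        segs = [s for s in profile.segments if s.chromosome == chrom]
        segs.sort(key=lambda s: s.start)
        if not segs:
            continue
        clen = genome.length(chrom)
        cs, ce = genome.centromere(chrom)
        for k, s in enumerate(segs):
            if s.a == s.b:
                continue
            if s.end - s.start + 1 <= min_len:
                continue
            if s.start < cs and s.end > ce:  # spans the centromere
                continue
            at_p = k == 0 and s.start <= tol
            at_q = k == len(segs) - 1 and s.end >= clen - tol + 1
            if at_p or at_q:
                n += 1
    return n


def lst_oracle(profile, genome, smooth_below=3_000_000, min_flank=10_000_000,
               exclude_x=True) -> int:
    total = 0
    for chrom in genome.names:
        if exclude_x and chrom == "X":
            continue
        segs = sorted(
            (s for s in profile.segments if s.chromosome == chrom),
            key=lambda s: s.start,
        )
        cs, ce = genome.centromere(chrom)
        clen = genome.length(chrom)
        for lo, hi in ((1, cs - 1), (ce + 1, clen)):
            arm = []
            for s in segs:
                a, b = max(s.start, lo), min(s.end, hi)
                if a <= b:
                    arm.append([a, b, (s.a, s.b)])
            # fixpoint smoothing: drop the shortest sub-threshold piece,
            # bridging equal-state neighbours, until none remain
            while True:
                short = [x for x in arm if x[1] - x[0] + 1 < smooth_below]
                if not short:
                    break
                victim = min(short, key=lambda x: (x[1] - x[0] + 1, x[0]))
                i = arm.index(victim)
                del arm[i]
                if 0 < i < len(arm) and arm[i - 1][2] == arm[i][2]:
                    arm[i - 1][1] = arm[i][1]
                    del arm[i]
            for left, right in zip(arm, arm[1:]):
                if (
                    left[2] != right[2]
                    and left[1] - left[0] + 1 >= min_flank
                    and right[1] - right[0] + 1 >= min_flank
                ):
                    total += 1
    return total


def hrd_loh_oracle(profile, genome, min_len=15_000_000,
                   excluded=("17",), exclude_x=True) -> int:
    n = 0
    for s in profile.segments:
        if s.chromosome in excluded:
            continue
        if exclude_x and s.chromosome == "X":
            continue
        if s.b == 0 and s.cnt >= 1 and s.end - s.start + 1 > min_len:
            n += 1
    return n


# --- exact tests ----------------------------------------------------------


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(k: int, M: int, K: int, n: int) -> float:
    """P(X = k) drawing n from M with K successes."""
    if k < max(0, n + K - M) or k > min(K, n):
        return 0.0
    return math.exp(
        _log_comb(K, k) + _log_comb(M - K, n - k) - _log_comb(M, n)
    )


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p by full hypergeometric enumeration."""
    M, K, n = a + b + c + d, a + b, a + c
    p_obs = hypergeom_pmf(a, M, K, n)
    total = 0.0
    for k in range(max(0, n + K - M), min(K, n) + 1):
        p = hypergeom_pmf(k, M, K, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def binom_two_sided_oracle(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p by pmf enumeration."""
    def pmf(j):
        return math.exp(
            _log_comb(n, j) + j * math.log(p) + (n - j) * math.log(1 - p)
        )
    p_obs = pmf(k)
    return min(
        sum(pmf(j) for j in range(n + 1) if pmf(j) <= p_obs * (1 + 1e-9)), 1.0
    )


# --- survival -------------------------------------------------------------


def logrank_oracle(times_a, events_a, times_b, events_b) -> float:
    """Log-rank chi-square by longhand observed-minus-expected arithmetic."""
    subjects = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in subjects if e})
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in subjects if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee and g == 0)
        if n < 2:
            continue
        O_minus_E += d1 - d * n1 / n
        V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return O_minus_E**2 / V if V > 0 else 0.0


# --- profile fuzzing ------------------------------------------------------

STATE_POOL = [(1, 1), (2, 1), (2, 0), (1, 0), (2, 2), (3, 1), (3, 0), (4, 2)]


def fuzz_profile(genome, rng, sample_id="fuzz"):
    """Random valid ASCN profile on a build: random breakpoints, states,
    gaps, including sub-3 Mb slivers that stress the LST smoothing."""
    from brcaloh.genome import ASCNSegment, TumorProfile

    segments = []
    for chrom, clen in genome.chromosomes:
        k = int(rng.integers(0, 10))
        cuts = sorted(rng.integers(1, clen, size=k).tolist())
        bounds = [1] + cuts + [clen]
        pos = bounds[0]
        for end in bounds[1:]:
            if end < pos:
                continue
            if rng.random() < 0.15:  # leave a gap
                pos = end + 1
                continue
            a, b = STATE_POOL[int(rng.integers(0, len(STATE_POOL)))]
            segments.append(ASCNSegment(chrom, pos, end, a + b, a, b))
            pos = end + 1
    return TumorProfile(
        sample_id=sample_id,
        purity=float(rng.uniform(0.2, 1.0)),
        ploidy=float(rng.uniform(1.6, 4.2)),
        segments=segments,
        genome=genome,
    )
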