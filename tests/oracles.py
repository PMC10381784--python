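"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration from the rule
definitions, sharing no code with the package implementation — so the tests
compare two independently derived answers.
"""

from __future__ import annotations

import itertools
from math import comb


# ---------------------------------------------------------------- scanner

MIN_TRACT = 3
MAX_LOOP = 30
MAX_SPAN = 45


def all_g_intervals(seq: str) -> list[tuple[int, int]]:
    """Every 1-based interval of length >= 3 consisting solely of G."""
    n = len(seq)
    out = []
    for s in range(1, n + 1):
        if seq[s - 1] != "G":
            continue
        for e in range(s + MIN_TRACT - 1, min(n, s + MAX_SPAN - 1) + 1):
            if all(seq[i - 1] == "G" for i in range(s, e + 1)):
                out.append((s, e))
            else:
                break
    return out


def enumerate_candidates(seq: str) -> set[tuple[tuple[int, int], ...]]:
    """All four-tract placements satisfying the motif constraints."""
    seq = seq.upper()
    intervals = all_g_intervals(seq)
    out = set()
    for t1 in intervals:
        window_end = t1[0] + MAX_SPAN - 1
        if t1[1] > window_end:
            continue
        in_window = [t for t in intervals if t[0] > t1[1] and t[1] <= window_end]
        for t2 in in_window:
            if not 1 <= t2[0] - t1[1] - 1 <= MAX_LOOP:
                continue
            for t3 in in_window:
                if not 1 <= t3[0] - t2[1] - 1 <= MAX_LOOP:
                    continue
                for t4 in in_window:
                    if not 1 <= t4[0] - t3[1] - 1 <= MAX_LOOP:
                        continue
                    out.add((t1, t2, t3, t4))
    return out


def greedy_select(seq: str, candidates) -> list[tuple[tuple[int, int], ...]]:
    """The stated selection rule applied literally to (tract-tuple) candidates."""

    def loops(c):
        return [(c[i][1] + 1, c[i + 1][0] - 1) for i in range(3)]

    def score(c):
        tract_lens = [e - s + 1 for s, e in c]
        loop_lens = [b - a + 1 for a, b in loops(c)]
        mean = sum(loop_lens) / 3
        var = sum((x - mean) ** 2 for x in loop_lens) / 3
        span = c[3][1] - c[0][0] + 1
        return 10 * min(min(tract_lens), 5) - var - (span - 15) / 2

    def loop_concat(c):
        return "".join(seq[a - 1 : b] for a, b in loops(c))

    ordered = sorted(
        candidates,
        key=lambda c: (-score(c), c[0][0], c[3][1] - c[0][0] + 1, loop_concat(c), c),
    )
    chosen: list = []
    for c in ordered:
        if all(c[3][1] < k[0][0] or k[3][1] < c[0][0] for k in chosen):
            chosen.append(c)
    return sorted(chosen, key=lambda c: c[0][0])


# ------------------------------------------------------------- clustering


def brute_force_clusters(intervals, min_intersection):
    """Greedy cluster extraction by scanning *every* window, not just the
    seed windows the implementation uses.

    ``intervals`` are (species, first, last) triples.  Returns a list of
    (member tuple, common) with members as (species, first, last).
    """
    pool = list(intervals)
    out = []
    while True:
        best = None
        positions = sorted({iv[1] for iv in pool} | {iv[2] for iv in pool})
        for a in positions:
            for b in positions:
                if b - a + 1 < min_intersection:
                    continue
                covering = [iv for iv in pool if iv[1] <= a and iv[2] >= b]
                by_species = {}
                for iv in sorted(covering, key=lambda v: (v[1], v[2], v[0])):
                    by_species.setdefault(iv[0], iv)
                members = sorted(by_species.values())
                if len(members) < 2:
                    continue
                common = (max(v[1] for v in members), min(v[2] for v in members))
                key = (len(members), common[1] - common[0] + 1, -common[0])
                if best is None or key > best[0]:
                    best = (key, members, common)
        if best is None:
            break
        _, members, common = best
        out.append((tuple(members), common))
        chosen = set(map(id, members))
        pool = [iv for iv in pool if id(iv) not in chosen]
    return out


# ----------------------------------------------------------- placements


def brute_force_placements(row: str, symbol: str, lo: int, hi: int):
    """All feasible 4-tract column placements for one gapped row, by direct
    enumeration over every all-symbol column interval in [lo, hi]."""
    width = len(row)
    hi = min(hi, width)

    def ungapped(a, b):
        return sum(1 for c in range(a, b + 1) if row[c - 1] != "-")

    options = []
    for s in range(lo, hi + 1):
        for e in range(s + MIN_TRACT - 1, hi + 1):
            if all(row[c - 1] == symbol for c in range(s, e + 1)):
                options.append((s, e))
            else:
                break
    out = []
    for combo in itertools.combinations(options, 4):
        ok = True
        for i in range(3):
            if combo[i + 1][0] <= combo[i][1]:
                ok = False
                break
            loop = ungapped(combo[i][1] + 1, combo[i + 1][0] - 1)
            if not 1 <= loop <= MAX_LOOP:
                ok = False
                break
        if ok and ungapped(combo[0][0], combo[3][1]) <= MAX_SPAN:
            out.append(combo)
    return set(out)


# ------------------------------------------------------------- statistics


def exact_signed_rank_p(diffs) -> float:
    """One-sided (greater) signed-rank p by full enumeration of sign flips.

    Assumes no zeros and distinct absolute values (no rank ties).
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, 1):
        ranks[i] = r
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs:
            count += 1
    return count / 2**n


def holm_adjust(ps):
    """Textbook Holm step-down, written independently of the package."""
    m = len(ps)
    indexed = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 0.0
    for rank, i in enumerate(indexed):
        val = min(1.0, (m - rank) * ps[i])
        prev = max(prev, val)
        adj[i] = prev
    return adj


def count_identical_columns(rows) -> int:
    return sum(
        1
        for col in zip(*rows)
        if col[0] in "ACGT" and all(c == col[0] for c in col)
    )
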