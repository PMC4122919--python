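"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, per-base bitmaps,
discrete simulation) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# HMM: exhaustive path enumeration
# ---------------------------------------------------------------------------


def enumerate_loglik(initial, transition, emission, obs) -> float:
    """log P(obs) by summing over all 2^T hidden-state paths."""
    n_states = len(initial)
    total = 0.0
    for path in itertools.product(range(n_states), repeat=len(obs)):
        p = initial[path[0]] * emission[path[0]][obs[0]]
        for t in range(1, len(obs)):
            p *= transition[path[t - 1]][path[t]] * emission[path[t]][obs[t]]
        total += p
    return math.log(total)


def enumerate_best_path(initial, transition, emission, obs):
    """(best log path probability, best path) by exhaustive enumeration."""
    best_lp, best_path = -math.inf, None
    for path in itertools.product(range(len(initial)), repeat=len(obs)):
        p = initial[path[0]] * emission[path[0]][obs[0]]
        for t in range(1, len(obs)):
            p *= transition[path[t - 1]][path[t]] * emission[path[t]][obs[t]]
        lp = math.log(p) if p > 0 else -math.inf
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, best_path


# ---------------------------------------------------------------------------
# Spearman: naive midrank implementation
# ---------------------------------------------------------------------------


def naive_midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    return ranks


def naive_spearman(x, y) -> float:
    rx, ry = naive_midranks(list(x)), naive_midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


# ---------------------------------------------------------------------------
# Alignment: exhaustive affine-gap global alignment on short strings
# ---------------------------------------------------------------------------


def _score_alignment(a_row: str, b_row: str, match, mismatch, gap_open, gap_extend) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a_row, b_row):
        if x == "-":
            score += gap_extend + (0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += gap_extend + (0 if in_gap_b else gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += match if (x == y and x != "N") else mismatch
            in_gap_a = in_gap_b = False
    return score


def exhaustive_alignment_score(a: str, b: str, match=1.0, mismatch=-2.0,
                               gap_open=-5.0, gap_extend=-1.0) -> float:
    """Optimal affine-gap global alignment score by enumerating all alignments."""
    best = [-math.inf]

    def recurse(i, j, row_a, row_b):
        if i == len(a) and j == len(b):
            best[0] = max(
                best[0],
                _score_alignment(row_a, row_b, match, mismatch, gap_open, gap_extend),
            )
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, row_a + a[i], row_b + b[j])
        if i < len(a):
            recurse(i + 1, j, row_a + a[i], row_b + "-")
        if j < len(b):
            recurse(i, j + 1, row_a + "-", row_b + b[j])

    recurse(0, 0, "", "")
    return best[0]


# ---------------------------------------------------------------------------
# Replication: discrete-time fork simulation
# ---------------------------------------------------------------------------


def fork_simulation_dssh(L: int, origin_h: int, origin_l: int, direction: int) -> np.ndarray:
    """Single-strandedness durations by stepping both forks one bp per tick.

    The leading fork starts at O_H and marks each site single-stranded as it
    passes; the lagging fork starts at O_L once the leading fork arrives
    there and travels the opposite way, rescuing sites.  A site rescued
    before being passed is never single-stranded.
    """
    pass_time = np.full(L, np.inf)
    rescue_time = np.full(L, np.inf)
    pos = origin_h
    for t in range(L + 1):
        if np.isinf(pass_time[pos]):
            pass_time[pos] = t
        pos = (pos + direction) % L
    lead_dist = (direction * (origin_l - origin_h)) % L
    pos = origin_l
    for s in range(L + 1):
        t = lead_dist + s
        if np.isinf(rescue_time[pos]):
            rescue_time[pos] = t
        pos = (pos - direction) % L
    return np.maximum(rescue_time - pass_time, 0.0)


# ---------------------------------------------------------------------------
# Intervals: per-base bitmaps
# ---------------------------------------------------------------------------


def bitmap_overlap(starts_a, ends_a, starts_b, ends_b, L: int) -> int:
    a = np.zeros(L, dtype=bool)
    b = np.zeros(L, dtype=bool)
    for s, e in zip(starts_a, ends_a):
        a[s:e] = True
    for s, e in zip(starts_b, ends_b):
        b[s:e] = True
    return int((a & b).sum())
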