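"""Independent oracles used by the test suite.

Each oracle is a deliberately simple, self-contained implementation kept
separate from the library code paths it checks: a plain-Python Gotoh dynamic
program for local alignment, textbook rank formulas for Kruskal–Wallis and
Dunn, the closed-form Holm–Šídák step-down, and an exhaustive enumeration of
maximal one-to-one feature matchings.
"""
from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1,
                    ) -> float:
    """Smith–Waterman score by explicit Gotoh recursion (gap cost open+g*ext)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def kruskal_wallis_oracle(groups) -> float:
    """H by the rank formula (no tie correction; caller supplies tie-free data)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    assert len({v for v, _ in pooled}) == len(pooled), "oracle needs tie-free data"
    n = len(pooled)
    rank_sums = [0.0] * len(groups)
    for rank, (_, gi) in enumerate(pooled, start=1):
        rank_sums[gi] += rank
    h = 12.0 / (n * (n + 1)) * sum(
        rs ** 2 / len(g) for rs, g in zip(rank_sums, groups)) - 3 * (n + 1)
    return h


def dunn_z_oracle(groups, i: int, j: int) -> float:
    """Dunn pairwise z by the rank formula (tie-free data)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    rank_sums = [0.0] * len(groups)
    for rank, (_, gi) in enumerate(pooled, start=1):
        rank_sums[gi] += rank
    mean_i = rank_sums[i] / len(groups[i])
    mean_j = rank_sums[j] / len(groups[j])
    se = math.sqrt(n * (n + 1) / 12.0 * (1 / len(groups[i]) + 1 / len(groups[j])))
    return (mean_i - mean_j) / se


def holm_sidak_oracle(p_values):
    """Closed-form step-down: adj_(i) = 1 - (1 - p_(i))^(m-i+1), monotonized."""
    m = len(p_values)
    order = sorted(range(m), key=lambda k: p_values[k])
    adj_sorted = []
    running = 0.0
    for rank, k in enumerate(order):
        a = 1.0 - (1.0 - p_values[k]) ** (m - rank)
        running = max(running, min(a, 1.0))
        adj_sorted.append(running)
    out = [0.0] * m
    for rank, k in enumerate(order):
        out[k] = adj_sorted[rank]
    return out


def matching_oracle(set_a, set_b, mz_tol=0.01, rt_tol=1.0,
                    require_msms="both"):
    """Lexicographically minimal maximal matching by exhaustive enumeration.

    Candidate pairs are keyed by (|dmz|, |drt|, sorted ids); among all maximal
    one-to-one matchings the one whose sorted key sequence is smallest is
    returned as a set of (id_a, id_b) pairs.
    """
    candidates = []
    for a in set_a:
        for b in set_b:
            if a.charge != b.charge:
                continue
            if abs(a.mz - b.mz) >= mz_tol or abs(a.rt - b.rt) >= rt_tol:
                continue
            if require_msms == "both" and not (a.has_msms and b.has_msms):
                continue
            key = (abs(a.mz - b.mz), abs(a.rt - b.rt),
                   tuple(sorted((a.feature_id, b.feature_id))))
            candidates.append((key, a.feature_id, b.feature_id))

    best = {"keys": None, "pairs": None}

    def recurse(idx, chosen, used_a, used_b):
        if idx == len(candidates):
            for _, ia, ib in candidates:
                if ia not in used_a and ib not in used_b:
                    return  # not maximal: an admissible pair is still free
            keys = sorted(k for k, _, _ in chosen)
            if best["keys"] is None or keys < best["keys"]:
                best["keys"] = keys
                best["pairs"] = {(ia, ib) for _, ia, ib in chosen}
            return
        key, ia, ib = candidates[idx]
        if ia in used_a or ib in used_b:
            recurse(idx + 1, chosen, used_a, used_b)
            return
        recurse(idx + 1, chosen + [(key, ia, ib)],
                used_a | {ia}, used_b | {ib})
        recurse(idx + 1, chosen, used_a, used_b)

    recurse(0, [], set(), set())
    return best["pairs"] or set()
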