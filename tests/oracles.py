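"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive (full matrices, explicit loops,
rank-walking) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def sw_affine_oracle(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> int:
    """Full three-matrix affine Smith-Waterman; gap of length k scores
    gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def locate_oracle(seq: str, tag: str, primer: str, max_mismatch: int) -> int | None:
    """Sliding Hamming scan for tag+primer anchored at positions 0..2."""
    probe = tag + primer
    for start in (0, 1, 2):
        window = seq[start:start + len(probe)]
        if len(window) < len(probe):
            continue
        if sum(x != y for x, y in zip(window, probe)) <= max_mismatch:
            return start + len(probe)
    return None


def consensus_oracle(taxa: list[tuple]) -> tuple[str, str | None]:
    """Walk ranks upward comparing all tie-set members pairwise."""
    for rank_idx, rank in ((2, "species"), (1, "genus"), (0, "family")):
        values = [t[rank_idx] for t in taxa]
        if any(v is None for v in values):
            continue
        if all(v == values[0] for v in values[1:]):
            return rank, values[0]
    return "unknown", None


def average_ranks_oracle(xs) -> list[float]:
    """Average ranks with ties shared, computed by explicit sorting."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and xs[order[j]] == xs[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def spearman_oracle(x, y) -> float:
    return pearson_oracle(average_ranks_oracle(x), average_ranks_oracle(y))


def perm_pvalue_oracle(rho: float, n: int) -> float:
    """Exhaustive two-sided permutation p over all n! orders (no ties)."""
    base = list(range(1, n + 1))
    count = 0
    total = 0
    for perm in itertools.permutations(base):
        r = spearman_oracle(base, list(perm))
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def pooled_t_oracle(a, b) -> tuple[float, int]:
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def best_matching_oracle(dna, micro, match_rank) -> int:
    """Maximum number of disjoint matchable pairs, by exhaustive assignment.

    ``match_rank(d, m)`` returns the agreement rank or None.  Suitable
    only for small lists.
    """
    best = 0
    micro = list(micro)
    for perm in itertools.permutations(range(len(micro))):
        used = set()
        count = 0
        for d in dna:
            for mi in perm:
                if mi in used:
                    continue
                if match_rank(d, micro[mi]) is not None:
                    used.add(mi)
                    count += 1
                    break
        best = max(best, count)
    return best
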