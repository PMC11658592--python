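"""Independent reference implementations used only as test oracles.

These deliberately re-derive results along different code paths than the
package: a top-down memoized alignment recursion and a brute-force
alignment enumerator (vs the package's bottom-up rolling-row DP), and a
from-scratch greedy step replayer (vs the package's incremental loop).
"""

from functools import lru_cache
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices


def oracle_align(a: str, b: str, gap_open: int = 10, gap_extend: int = 4,
                 matrix: str = "BLOSUM62") -> tuple[float, int, int]:
    """(score, matches, alignment length) by top-down memoized recursion.

    Maximizes the lexicographic tuple (score, matches, -length); gap of
    length k costs open + (k-1)*extend.
    """
    mat = substitution_matrices.load(matrix)
    idx = {ch: i for i, ch in enumerate(str(mat.alphabet))}
    n, m = len(a), len(b)
    NEG = (float("-inf"), 0, 0)

    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> tuple[float, int, int]:
        if i == n and j == m:
            return (0.0, 0, 0)
        best = NEG
        if i < n and j < m:
            s = float(mat[idx[a[i]], idx[b[j]]])
            eq = 1 if a[i] == b[j] else 0
            sub = f(i + 1, j + 1, "m")
            cand = (sub[0] + s, sub[1] + eq, sub[2] - 1)
            if cand > best:
                best = cand
        if i < n:
            cost = gap_extend if prev == "ix" else gap_open
            sub = f(i + 1, j, "ix")
            cand = (sub[0] - cost, sub[1], sub[2] - 1)
            if cand > best:
                best = cand
        if j < m:
            cost = gap_extend if prev == "iy" else gap_open
            sub = f(i, j + 1, "iy")
            cand = (sub[0] - cost, sub[1], sub[2] - 1)
            if cand > best:
                best = cand
        return best

    score, matches, neglen = f(0, 0, "m")
    f.cache_clear()
    return score, matches, -neglen


def brute_force_align(a: str, b: str, gap_open: int = 10, gap_extend: int = 4,
                      matrix: str = "BLOSUM62") -> tuple[float, int, int]:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    mat = substitution_matrices.load(matrix)
    idx = {ch: i for i, ch in enumerate(str(mat.alphabet))}
    best = (float("-inf"), 0, 0)

    def rec(i, j, prev, score, matches, length):
        nonlocal best
        if i == len(a) and j == len(b):
            cand = (score, matches, -length)
            if cand > best:
                best = cand
            return
        if i < len(a) and j < len(b):
            s = float(mat[idx[a[i]], idx[b[j]]])
            rec(i + 1, j + 1, "m", score + s, matches + (a[i] == b[j]), length + 1)
        if i < len(a):
            rec(i + 1, j, "ix", score - (gap_extend if prev == "ix" else gap_open), matches, length + 1)
        if j < len(b):
            rec(i, j + 1, "iy", score - (gap_extend if prev == "iy" else gap_open), matches, length + 1)

    rec(0, 0, "m", 0.0, 0, 0)
    return best[0], best[1], -best[2]


def replay_greedy(trace, table, matrix, levels, params, universe) -> None:
    """Re-derive every greedy step from scratch and assert agreement.

    Recomputes, per step: coverage admissibility of each remaining term,
    score deltas with masked pairs at fill_value, the epsilon-argmax set,
    and the level/random tie-break (consuming the seeded generator exactly
    when the post-level tie has >= 2 members).
    """
    psets = {t: table.proteins_of(t) for t in matrix.terms}
    uni = set(universe)
    current = list(matrix.terms)
    rng = np.random.default_rng(params.seed)

    def cov(sub):
        covered = set().union(*(psets[t] for t in sub)) if sub else set()
        return len(covered & uni) / len(uni)

    def mean(sub):
        pairs = list(combinations(sub, 2))
        if not pairs:
            return None
        vals = [matrix.get(x, y) for x, y in pairs]
        return sum(params.fill_value if v is None else v for v in vals) / len(pairs)

    for step in trace.steps:
        base = mean(current)
        base_v = 0.0 if base is None else base
        cands = {}
        for t in current:
            rest = [u for u in current if u != t]
            c = cov(rest)
            if c < params.min_coverage:
                continue
            m = mean(rest)
            cands[t] = (c, (0.0 if m is None else m) - base_v)
        assert cands, "pipeline removed a term when no candidate was admissible"
        best = max(d for _, d in cands.values())
        argmax = [t for t in current if t in cands and cands[t][1] >= best - params.epsilon - 1e-12]
        assert set(step.argmax_set) <= set(argmax), (step.argmax_set, argmax)
        assert step.removed in argmax, f"{step.removed} not within epsilon of best delta"
        if len(step.argmax_set) == 1:
            pick = step.argmax_set[0]
        else:
            extreme_of = min if params.preference == "specific" else max
            extreme = extreme_of(levels[t] for t in step.argmax_set)
            tied = [t for t in step.argmax_set if levels[t] == extreme]
            pick = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
        assert pick == step.removed, "tie-break disagrees with replay"
        assert abs(step.coverage_after - cands[step.removed][0]) < 1e-12
        assert step.coverage_after >= params.min_coverage
        current.remove(step.removed)
    assert current == trace.final_subset
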