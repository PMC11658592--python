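"""Coverage-constrained greedy term removal.

The optimization target: a small subset of annotation terms whose pairwise
classifier scores are high (non-redundant, separable classes) while still
covering at least a fraction ``c`` of all proteins in the dataset.

Each iteration removes one term. A term is a removal candidate if the
remaining terms still cover >= c of the proteins. Among candidates, the one
whose removal most increases the mean pairwise score is removed; masked
matrix entries (pairs with too few unique proteins to evaluate) count as
``fill_value`` (default -1), so terms entangled in unevaluable pairs are
removed first. Candidates within ``epsilon`` of the best improvement are
treated as tied; ties resolve by ontology level (keep-specific removes the
most abstract, i.e. lowest-level, term) and finally by a seeded
deterministic random draw. The loop stops when no candidate remains.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from gosubset.dataset import AnnotationTable
from gosubset.simmatrix import PairScoreMatrix


@dataclass(frozen=True)
class GreedyParams:
    """Knobs of the greedy reduction.

    n               minimum proteins per term (prefilter).
    m               minimum unique proteins per pair (matrix masking; kept
                    here for the run manifest — masking happens upstream).
    top_percentile  p: drop terms above the (100-p)th percentile of the
                    protein-count distribution before optimizing.
    min_coverage    c: smallest allowed fraction of proteins still covered.
    preference      which terms to KEEP: "specific" removes the most
                    abstract tied candidate, "abstract" the most specific.
    epsilon         score-delta slack within which candidates count as tied
                    (<= 0.05 recommended; scores live in [0, 1]).
    fill_value      value substituted for masked pairs when averaging.
    seed            seed of the deterministic tie-break generator.
    """

    n: int = 20
    m: int = 15
    top_percentile: float = 0.0
    min_coverage: float = 0.9
    preference: str = "specific"
    epsilon: float = 0.0
    fill_value: float = -1.0
    seed: int = 0
    require_positive_delta: bool = False

    def __post_init__(self):
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.preference not in ("specific", "abstract"):
            raise ValueError("preference must be 'specific' or 'abstract'")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.fill_value > 0:
            raise ValueError("fill_value must be <= 0 (it must rank below real scores)")


@dataclass
class GreedyStep:
    removed: str
    level: int
    coverage_before: float
    coverage_after: float
    mean_before: float | None
    mean_after: float | None
    n_candidates: int
    argmax_set: list[str]
    tie_stage: str  # "unique" | "level" | "random"
    rng_draw_index: int | None


@dataclass
class GreedyTrace:
    steps: list[GreedyStep]
    final_subset: list[str]
    final_coverage: float
    final_median_score: float | None
    defined_pair_fraction: float
    params: GreedyParams

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.steps:
                fh.write(json.dumps(asdict(s)) + "\n")
            fh.write(json.dumps({
                "final_subset": self.final_subset,
                "final_coverage": self.final_coverage,
                "final_median_score": self.final_median_score,
                "defined_pair_fraction": self.defined_pair_fraction,
                "params": asdict(self.params),
            }) + "\n")


def prefilter(
    terms: Sequence[str],
    table: AnnotationTable,
    params: GreedyParams,
    root: str | None = None,
) -> list[str]:
    """Apply the n-count floor and the top-percentile ceiling.

    The percentile is a linear-interpolation percentile of the protein-count
    distribution over the *full* input term set excluding the root, computed
    before the n-filter. The root term itself never enters the working set.
    """
    counts = table.counts()
    pool = [t for t in terms if t != root]
    if not pool:
        raise ValueError("no terms left after excluding the root")
    ceiling = None
    if params.top_percentile > 0:
        dist = np.array([counts.get(t, 0) for t in pool], dtype=float)
        ceiling = float(np.percentile(dist, 100.0 - params.top_percentile))
    kept = [t for t in pool if counts.get(t, 0) >= params.n]
    if ceiling is not None:
        kept = [t for t in kept if counts.get(t, 0) <= ceiling]
    if not kept:
        raise ValueError(
            f"prefilter removed every term (n={params.n}, p={params.top_percentile}, "
            f"{len(pool)} input terms, max count {max(counts.get(t, 0) for t in pool)})"
        )
    return kept


def coverage(subset: Sequence[str], table: AnnotationTable, universe: Sequence[str]) -> float:
    """Fraction of ``universe`` proteins annotated with >= 1 subset term."""
    if not universe:
        raise ValueError("universe must be non-empty")
    subset = set(subset)
    covered = {p for p, t in table.relation if t in subset}
    return len(covered & set(universe)) / len(set(universe))


def mean_score(subset: Sequence[str], matrix: PairScoreMatrix, fill_value: float) -> float | None:
    """Mean over unordered within-subset pairs, masked entries -> fill_value.

    Returns ``None`` for subsets with fewer than two members (no pairs).
    """
    idx = [matrix.index(t) for t in subset]
    if len(idx) < 2:
        return None
    total = 0.0
    npairs = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            total += fill_value if matrix.mask[i, j] else matrix.values[i, j]
            npairs += 1
    return total / npairs


def step_candidates(
    current: Sequence[str],
    matrix: PairScoreMatrix,
    table: AnnotationTable,
    params: GreedyParams,
    universe: Sequence[str],
) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Candidates for removal and the epsilon-argmax set.

    Returns ``(candidates, argmax_set)`` where candidates maps each
    removable term to ``(coverage_after_removal, score_delta)``. A term is
    removable when the remaining terms keep coverage >= min_coverage;
    its delta is mean_score(current minus term) - mean_score(current)
    (a singleton remainder contributes mean 0).
    """
    current = list(current)
    base = mean_score(current, matrix, params.fill_value)
    base_v = base if base is not None else 0.0
    candidates: dict[str, tuple[float, float]] = {}
    for t in current:
        rest = [u for u in current if u != t]
        cov_after = coverage(rest, table, universe)
        if cov_after < params.min_coverage:
            continue
        after = mean_score(rest, matrix, params.fill_value)
        delta = (after if after is not None else 0.0) - base_v
        candidates[t] = (cov_after, delta)
    if not candidates:
        return candidates, []
    best = max(d for _, d in candidates.values())
    if params.require_positive_delta and best <= 0:
        return candidates, []
    argmax = [t for t in current if t in candidates and candidates[t][1] >= best - params.epsilon]
    return candidates, argmax


def tie_break(
    argmax_set: Sequence[str],
    levels: Mapping[str, int],
    preference: str,
    rng: np.random.Generator,
) -> tuple[str, str, int | None]:
    """Pick the term to remove from the epsilon-argmax set.

    preference="specific" keeps specific terms, so the most abstract
    (minimum-level) tied term is removed; "abstract" removes the
    maximum-level one. Remaining level ties are resolved by one draw from
    the seeded generator — the draw is consumed only when actually needed,
    so traces are prefix-stable under config changes downstream.

    Returns (term, stage, draw) where stage is "unique" | "level" | "random"
    and draw is the drawn index or None.
    """
    if not argmax_set:
        raise ValueError("argmax set must be non-empty")
    if len(argmax_set) == 1:
        return argmax_set[0], "unique", None
    pick_level = min if preference == "specific" else max
    extreme = pick_level(levels[t] for t in argmax_set)
    tied = [t for t in argmax_set if levels[t] == extreme]
    if len(tied) == 1:
        return tied[0], "level", None
    draw = int(rng.integers(len(tied)))
    return tied[draw], "random", draw


def reduce_terms(
    table: AnnotationTable,
    matrix: PairScoreMatrix,
    levels: Mapping[str, int],
    params: GreedyParams,
    universe: Sequence[str] | None = None,
) -> GreedyTrace:
    """Run the greedy loop to completion and return the full trace.

    ``matrix`` must be indexed by the prefiltered working terms. The
    ``universe`` defaults to every protein in the table. The matrix is
    fixed: deltas always come from the once-computed pair scores.
    """
    universe = list(universe) if universe is not None else list(table.proteins)
    current = list(matrix.terms)
    rng = np.random.default_rng(params.seed)
    steps: list[GreedyStep] = []

    while len(current) >= 2:
        candidates, argmax = step_candidates(current, matrix, table, params, universe)
        if not argmax:
            break
        term, stage, draw = tie_break(argmax, levels, params.preference, rng)
        cov_before = coverage(current, table, universe)
        cov_after, _ = candidates[term]
        before = mean_score(current, matrix, params.fill_value)
        current = [t for t in current if t != term]
        after = mean_score(current, matrix, params.fill_value)
        steps.append(
            GreedyStep(
                removed=term,
                level=int(levels[term]),
                coverage_before=cov_before,
                coverage_after=cov_after,
                mean_before=before,
                mean_after=after,
                n_candidates=len(candidates),
                argmax_set=list(argmax),
                tie_stage=stage,
                rng_draw_index=draw,
            )
        )

    sub = matrix.submatrix(current)
    iu = np.triu_indices(len(current), k=1)
    defined = ~sub.mask[iu]
    pair_vals = sub.values[iu][defined]
    return GreedyTrace(
        steps=steps,
        final_subset=current,
        final_coverage=coverage(current, table, universe),
        final_median_score=float(np.median(pair_vals)) if pair_vals.size else None,
        defined_pair_fraction=float(defined.mean()) if defined.size else 1.0,
        params=params,
    )
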