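"""Greedy coverage-constrained removal: prefilter, deltas, ties, traces."""

import numpy as np
import pytest

from gosubset.dataset import AnnotationTable
from gosubset.greedy import (
    GreedyParams,
    coverage,
    mean_score,
    prefilter,
    reduce_terms,
    step_candidates,
    tie_break,
)
from gosubset.simmatrix import PairScoreMatrix
from tests.oracles import replay_greedy


def _table(rel):
    return AnnotationTable(
        proteins=sorted({p for p, _ in rel}),
        terms=sorted({t for _, t in rel}),
        relation=set(rel),
    )


def _counts_table(counts: dict[str, int]):
    rel = {(f"{t}_p{i}", t) for t, n in counts.items() for i in range(n)}
    return _table(rel)


def _matrix(terms, values=None, masked=()):
    k = len(terms)
    vals = np.full((k, k), 0.9) if values is None else np.asarray(values, float)
    mask = np.zeros((k, k), bool)
    np.fill_diagonal(mask, True)
    for a, b in masked:
        i, j = terms.index(a), terms.index(b)
        mask[i, j] = mask[j, i] = True
    return PairScoreMatrix(terms=list(terms), values=vals, mask=mask)


def random_instance(rng, max_terms=12, max_proteins=200):
    k = int(rng.integers(4, max_terms + 1))
    n = int(rng.integers(20, max_proteins + 1))
    terms = [f"T{i}" for i in range(k)]
    rel = set()
    for p in range(n):
        mine = rng.random(k) < rng.uniform(0.08, 0.4)
        if not mine.any():
            mine[rng.integers(k)] = True
        rel |= {(f"P{p}", terms[i]) for i in np.nonzero(mine)[0]}
    table = _table(rel)
    vals = np.round(rng.random((k, k)), 3)
    vals = (vals + vals.T) / 2
    mask = rng.random((k, k)) < 0.2
    mask |= mask.T
    np.fill_diagonal(mask, True)
    matrix = PairScoreMatrix(terms=terms, values=vals, mask=mask)
    levels = {t: int(rng.integers(1, 5)) for t in terms}
    params = GreedyParams(
        n=1, m=1,
        min_coverage=float(rng.uniform(0.3, 0.9)),
        preference=str(rng.choice(["specific", "abstract"])),
        epsilon=float(rng.choice([0.0, 0.005, 0.05])),
        fill_value=float(rng.choice([-1.0, 0.0])),
        seed=int(rng.integers(1 << 16)),
    )
    return table, matrix, levels, params


class TestPrefilter:
    def test_low_count_terms_dropped(self):
        tbl = _counts_table({"X": 5, "Y": 25, "Z": 30})
        assert prefilter(["X", "Y", "Z"], tbl, GreedyParams(n=20)) == ["Y", "Z"]

    def test_p_zero_means_no_percentile_removal(self):
        tbl = _counts_table({"X": 25, "Y": 800})
        assert prefilter(["X", "Y"], tbl, GreedyParams(n=20, top_percentile=0)) == ["X", "Y"]

    def test_percentile_matches_sort_based_oracle(self):
        rng = np.random.default_rng(9)
        counts = {f"T{i}": int(rng.integers(1, 500)) for i in range(100)}
        tbl = _counts_table(counts)
        params = GreedyParams(n=1, top_percentile=5)
        got = prefilter(sorted(counts), tbl, params)
        ceiling = np.percentile(np.array([counts[t] for t in sorted(counts)], float), 95)
        expect = [t for t in sorted(counts) if counts[t] <= ceiling]
        assert got == expect

    def test_root_excluded_and_not_in_percentile_pool(self):
        tbl = _counts_table({"ROOT": 1000, "X": 30, "Y": 40})
        got = prefilter(["ROOT", "X", "Y"], tbl, GreedyParams(n=20, top_percentile=40), root="ROOT")
        # percentile over {30, 40} only: 60th pct = 36 -> Y dropped
        assert got == ["X"]

    def test_empty_result_is_diagnostic_error(self):
        tbl = _counts_table({"X": 2})
        with pytest.raises(ValueError, match="prefilter removed every term"):
            prefilter(["X"], tbl, GreedyParams(n=20))


class TestCoverage:
    def test_empty_subset_zero(self):
        tbl = _counts_table({"X": 3})
        assert coverage([], tbl, tbl.proteins) == 0.0

    def test_full_cover_is_one(self):
        rel = {("P1", "X"), ("P2", "Y")}
        tbl = _table(rel)
        assert coverage(["X", "Y"], tbl, tbl.proteins) == 1.0

    def test_random_subsets_match_set_union_oracle(self):
        rng = np.random.default_rng(10)
        terms = [f"T{i}" for i in range(8)]
        rel = {(f"P{p}", t) for p in range(50) for t in terms if rng.random() < 0.2}
        tbl = _table(rel)
        universe = sorted({p for p, _ in rel})
        for _ in range(20):
            sub = [t for t in terms if rng.random() < 0.5]
            covered = {p for p, t in rel if t in sub}
            assert coverage(sub, tbl, universe) == len(covered) / len(universe)


class TestMeanScore:
    def test_uniform_defined_pairs(self):
        m = _matrix(["A", "B", "C"])
        assert mean_score(["A", "B", "C"], m, -1.0) == pytest.approx(0.9)

    def test_masked_pair_filled(self):
        m = _matrix(["A", "B", "C"], masked=[("A", "B")])
        assert mean_score(["A", "B", "C"], m, -1.0) == pytest.approx((0.9 + 0.9 - 1.0) / 3)
        assert mean_score(["A", "B", "C"], m, 0.0) == pytest.approx(0.6)

    def test_singleton_returns_sentinel(self):
        m = _matrix(["A", "B"])
        assert mean_score(["A"], m, -1.0) is None


class TestStepCandidates:
    def test_every_term_essential_means_no_candidates(self):
        rel = {("P1", "X"), ("P2", "Y"), ("P3", "Z")}
        tbl = _table(rel)
        m = _matrix(["X", "Y", "Z"])
        cands, argmax = step_candidates(["X", "Y", "Z"], m, tbl, GreedyParams(min_coverage=1.0), tbl.proteins)
        assert cands == {} and argmax == []

    def test_all_masked_term_has_best_delta(self):
        # proteins of D fully covered elsewhere; its pairs all masked at fill -1
        rel = {("P1", "X"), ("P2", "Y"), ("P3", "Z"), ("P1", "D")}
        tbl = _table(rel)
        m = _matrix(["X", "Y", "Z", "D"], masked=[("D", "X"), ("D", "Y"), ("D", "Z")])
        params = GreedyParams(min_coverage=1.0, fill_value=-1.0)
        cands, argmax = step_candidates(["X", "Y", "Z", "D"], m, tbl, params, tbl.proteins)
        assert argmax == ["D"]
        assert cands["D"][1] == max(d for _, d in cands.values())

    def test_large_epsilon_makes_all_candidates_tie(self):
        rel = {("P1", "X"), ("P1", "Y"), ("P1", "Z")}
        tbl = _table(rel)
        m = _matrix(["X", "Y", "Z"], values=[[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        cands, argmax = step_candidates(["X", "Y", "Z"], m, tbl, GreedyParams(min_coverage=0.0, epsilon=1.0),
                                        tbl.proteins)
        assert set(argmax) == {"X", "Y", "Z"}


class TestTieBreak:
    def test_singleton_no_draw(self):
        rng = np.random.default_rng(0)
        assert tie_break(["X"], {"X": 3}, "specific", rng) == ("X", "unique", None)
        # the generator was not consumed
        assert rng.integers(100) == np.random.default_rng(0).integers(100)

    def test_keep_specific_removes_most_abstract(self):
        rng = np.random.default_rng(0)
        term, stage, _ = tie_break(["deep", "shallow"], {"deep": 3, "shallow": 1}, "specific", rng)
        assert term == "shallow" and stage == "level"

    def test_keep_abstract_removes_most_specific(self):
        rng = np.random.default_rng(0)
        term, _, _ = tie_break(["deep", "shallow"], {"deep": 3, "shallow": 1}, "abstract", rng)
        assert term == "deep"

    def test_same_seed_reproduces_draw_sequence(self):
        levels = {t: 1 for t in "ABCD"}
        picks1 = [tie_break(list("ABCD"), levels, "specific", np.random.default_rng(42))[0] for _ in range(1)]
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(7)
        seq1 = [tie_break(list("ABCD"), levels, "specific", rng1)[0] for _ in range(10)]
        seq2 = [tie_break(list("ABCD"), levels, "specific", rng2)[0] for _ in range(10)]
        assert seq1 == seq2


class TestReduce:
    def _parent_children_instance(self):
        """Redundant parent over two separable children; parent removable."""
        rel = {(f"P{i}", "parent") for i in range(20)}
        rel |= {(f"P{i}", "c1") for i in range(10)}
        rel |= {(f"P{i}", "c2") for i in range(10, 20)}
        tbl = _table(rel)
        terms = ["parent", "c1", "c2"]
        m = _matrix(terms, masked=[("parent", "c1"), ("parent", "c2")])
        levels = {"parent": 1, "c1": 2, "c2": 2}
        return tbl, m, levels

    def test_redundant_parent_removed_children_kept(self):
        tbl, m, levels = self._parent_children_instance()
        trace = reduce_terms(tbl, m, levels, GreedyParams(min_coverage=0.9, preference="specific"))
        assert sorted(trace.final_subset) == ["c1", "c2"]
        assert [s.removed for s in trace.steps] == ["parent"]
        assert trace.final_coverage == 1.0

    def test_zero_steps_when_everything_essential(self):
        rel = {("P1", "X"), ("P2", "Y")}
        tbl = _table(rel)
        m = _matrix(["X", "Y"])
        trace = reduce_terms(tbl, m, {"X": 1, "Y": 1}, GreedyParams(min_coverage=1.0))
        assert trace.steps == [] and sorted(trace.final_subset) == ["X", "Y"]

    def test_coverage_invariants_along_trace(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            tbl, m, levels, params = random_instance(rng)
            trace = reduce_terms(tbl, m, levels, params)
            covs = [coverage(m.terms, tbl, tbl.proteins)] + [s.coverage_after for s in trace.steps]
            assert all(c >= params.min_coverage for c in covs[1:])
            assert all(a >= b - 1e-12 for a, b in zip(covs, covs[1:]))  # non-increasing

    def test_trace_replay_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            tbl, m, levels, params = random_instance(rng)
            trace = reduce_terms(tbl, m, levels, params)
            replay_greedy(trace, tbl, m, levels, params, tbl.proteins)

    def test_epsilon_zero_no_level_ties_is_seed_independent(self):
        tbl, m, levels, _ = random_instance(np.random.default_rng(14))
        # distinct levels and epsilon=0: the trace cannot depend on the seed
        levels = {t: i + 1 for i, t in enumerate(m.terms)}
        p1 = GreedyParams(min_coverage=0.5, epsilon=0.0, seed=1)
        p2 = GreedyParams(min_coverage=0.5, epsilon=0.0, seed=999)
        t1 = reduce_terms(tbl, m, levels, p1)
        t2 = reduce_terms(tbl, m, levels, p2)
        assert [s.removed for s in t1.steps] == [s.removed for s in t2.steps]

    def test_mean_score_improves_when_any_delta_positive(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            tbl, m, levels, params = random_instance(rng)
            trace = reduce_terms(tbl, m, levels, params)
            if any(s.mean_after is not None and s.mean_before is not None
                   and s.mean_after > s.mean_before for s in trace.steps):
                first = trace.steps[0].mean_before
                last = trace.steps[-1].mean_after
                if any((s.mean_after or 0) - (s.mean_before or 0) > 0 for s in trace.steps) \
                        and all((s.mean_after or 0) - (s.mean_before or 0) >= 0 for s in trace.steps):
                    assert last >= first

    def test_require_positive_delta_stops_early(self):
        tbl, m, levels = self._parent_children_instance()
        # after the parent is gone every further delta is <= 0
        params = GreedyParams(min_coverage=0.0, require_positive_delta=True)
        trace = reduce_terms(tbl, m, levels, params)
        assert trace.steps and all(
            (s.mean_after or 0.0) - (s.mean_before or 0.0) > 0 for s in trace.steps
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GreedyParams(min_coverage=1.5)
        with pytest.raises(ValueError):
            GreedyParams(preference="neither")
        with pytest.raises(ValueError):
            GreedyParams(fill_value=0.5)
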