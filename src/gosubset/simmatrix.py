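"""Term-by-term similarity matrices: sequence, semantic (Wang), overlap.

Three independent views of how related two annotation terms are:

* aggregated global-alignment sequence identity between their protein sets;
* Wang graph-based semantic similarity, computed from downward-propagated
  semantic contributions (S-values) of shared ancestors;
* the protein-overlap matrix (shared-annotation counts or fractions).

Identity caveat: for integer substitution scores, several global alignments
usually share the optimal score but differ in number of identities and in
length. To make "percent identity" a well-defined function of the inputs we
report the canonical co-optimal alignment that first maximizes identities
and then minimizes alignment length, via a Gotoh affine-gap DP over
lexicographically ordered (score, matches, -length) tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from gosubset.dataset import STANDARD_RESIDUES, AnnotationTable
from gosubset.ontology import OntologyGraph


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters (affine gaps).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``: the opening
    penalty is charged for the first gapped position, extension for each
    further one.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 4

    def __post_init__(self):
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=8)
def _scoring(matrix_name: str):
    mat = substitution_matrices.load(matrix_name)
    alphabet = str(mat.alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    return np.asarray(mat, dtype=np.int64), index


_NEG = (float("-inf"), 0, 0)


def _align_stats(a: str, b: str, params: AlignmentParams) -> tuple[float, int, int]:
    """(score, matches, alignment length) of the canonical optimal alignment.

    Gotoh three-state DP; cell values are (score, matches, -length) tuples
    compared lexicographically. Additive transitions preserve optimal
    substructure under lexicographic order, so the final tuple describes the
    co-optimal alignment with the most identities (shortest among those).
    """
    mat, index = _scoring(params.matrix)
    try:
        ai = [index[ch] for ch in a]
        bi = [index[ch] for ch in b]
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in {params.matrix} alphabet") from exc
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    # rolling rows of (score, matches, -length) per state
    M = [_NEG] * (m + 1)
    Ix = [_NEG] * (m + 1)  # gap in b (a-residue over gap)
    Iy = [_NEG] * (m + 1)  # gap in a
    M[0] = (0.0, 0, 0)
    for j in range(1, m + 1):
        Iy[j] = (-(go + (j - 1) * ge), 0, -j)
    for i in range(1, n + 1):
        pM, pIx, pIy = M, Ix, Iy
        M = [_NEG] * (m + 1)
        Ix = [_NEG] * (m + 1)
        Iy = [_NEG] * (m + 1)
        Ix[0] = (-(go + (i - 1) * ge), 0, -i)
        row = mat[ai[i - 1]]
        for j in range(1, m + 1):
            s = int(row[bi[j - 1]])
            eq = 1 if a[i - 1] == b[j - 1] else 0
            best = pM[j - 1]
            if pIx[j - 1] > best:
                best = pIx[j - 1]
            if pIy[j - 1] > best:
                best = pIy[j - 1]
            if best[0] != float("-inf"):
                M[j] = (best[0] + s, best[1] + eq, best[2] - 1)
            cand = (pM[j][0] - go, pM[j][1], pM[j][2] - 1)
            c2 = (pIx[j][0] - ge, pIx[j][1], pIx[j][2] - 1)
            if c2 > cand:
                cand = c2
            c3 = (pIy[j][0] - go, pIy[j][1], pIy[j][2] - 1)
            if c3 > cand:
                cand = c3
            Ix[j] = cand
            cand = (M[j - 1][0] - go, M[j - 1][1], M[j - 1][2] - 1)
            c2 = (Ix[j - 1][0] - go, Ix[j - 1][1], Ix[j - 1][2] - 1)
            if c2 > cand:
                cand = c2
            c3 = (Iy[j - 1][0] - ge, Iy[j - 1][1], Iy[j - 1][2] - 1)
            if c3 > cand:
                cand = c3
            Iy[j] = cand
    score, matches, neglen = max(M[m], Ix[m], Iy[m])
    return score, matches, -neglen


def global_score(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Optimal Needleman-Wunsch/Gotoh global alignment score."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _align_stats(a, b, params)[0]


def global_identity(
    a: str,
    b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    denominator: str = "alignment",
) -> float:
    """Fraction of identical positions in the optimal global alignment.

    ``denominator="alignment"`` (default) divides by the alignment length
    including gap columns; ``"shorter"`` divides by the shorter sequence
    length. Ties among co-optimal alignments are resolved toward the most
    identities, then the shortest alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _, matches, alen = _align_stats(a, b, params)
    if denominator == "alignment":
        return matches / alen
    if denominator == "shorter":
        return matches / min(len(a), len(b))
    raise ValueError(f"unknown denominator {denominator!r}")


# -- term-level sequence similarity ------------------------------------

_AGGS = {"mean": np.mean, "median": np.median, "min": np.min, "max": np.max}


def term_sequence_similarity(
    t1: str,
    t2: str,
    table: AnnotationTable,
    seqs: Mapping[str, str],
    agg: str = "mean",
    params: AlignmentParams = DEFAULT_PARAMS,
    include_self_pairs: bool = True,
    _cache: dict | None = None,
) -> float:
    """Aggregate pairwise identity over the two terms' protein cross-product.

    A protein annotated with both terms appears in both sets; its self-pair
    (identity 1.0) is included unless ``include_self_pairs=False``.
    """
    if agg not in _AGGS:
        raise ValueError(f"agg must be one of {sorted(_AGGS)}")
    p1 = sorted(table.proteins_of(t1))
    p2 = sorted(table.proteins_of(t2))
    if not p1 or not p2:
        raise ValueError(f"term with no annotated proteins: {t1 if not p1 else t2}")
    vals = []
    for x in p1:
        for y in p2:
            if x == y and not include_self_pairs:
                continue
            if x == y:
                vals.append(1.0)
                continue
            key = (x, y) if x < y else (y, x)
            if _cache is not None and key in _cache:
                vals.append(_cache[key])
                continue
            v = global_identity(seqs[x], seqs[y], params)
            if _cache is not None:
                _cache[key] = v
            vals.append(v)
    if not vals:
        raise ValueError(f"no protein pairs between {t1} and {t2}")
    return float(_AGGS[agg](vals))


# -- Wang semantic similarity ------------------------------------------

DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _svalues(term: str, g: OntologyGraph, w: Mapping[str, float]) -> dict[str, float]:
    """Semantic contributions of ``term`` and its ancestors (Wang S-values).

    S(term) = 1; for an ancestor a, S(a) = max over child edges (c -> a)
    with c in the closure of w[relation] * S(c).
    """
    up: dict[str, list[tuple[str, float]]] = {}
    for c, p, r in g.edges:
        if r in w:
            up.setdefault(c, []).append((p, w[r]))
    sval = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p, weight in up.get(t, ()):
                cand = weight * sval[t]
                if cand > sval.get(p, 0.0):
                    sval[p] = cand
                    nxt.append(p)
        frontier = nxt
    return sval


def wang_similarity(
    t1: str,
    t2: str,
    g: OntologyGraph,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> float:
    """Wang graph-based semantic similarity in [0, 1].

    sim = sum over shared closure terms of (S1 + S2), divided by
    (SV(t1) + SV(t2)) where SV is the sum of a term's S-values.
    """
    for t in (t1, t2):
        if t not in g.terms:
            raise KeyError(f"term {t!r} not in graph")
    s1 = _svalues(t1, g, weights)
    s2 = _svalues(t2, g, weights)
    shared = s1.keys() & s2.keys()
    num = sum(s1[t] + s2[t] for t in shared)
    return num / (sum(s1.values()) + sum(s2.values()))


# -- overlap matrices ---------------------------------------------------


@dataclass
class PairScoreMatrix:
    """Dense term-by-term score matrix with explicit missingness mask."""

    terms: list[str]
    values: np.ndarray
    mask: np.ndarray  # True where the value is undefined
    symmetric: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        k = len(self.terms)
        if self.values.shape != (k, k) or self.mask.shape != (k, k):
            raise ValueError("values/mask shape must be (len(terms), len(terms))")

    def index(self, term: str) -> int:
        return self.terms.index(term)

    def get(self, t1: str, t2: str) -> float | None:
        i, j = self.index(t1), self.index(t2)
        return None if self.mask[i, j] else float(self.values[i, j])

    def submatrix(self, terms: Sequence[str]) -> "PairScoreMatrix":
        idx = [self.index(t) for t in terms]
        return PairScoreMatrix(
            terms=list(terms),
            values=self.values[np.ix_(idx, idx)].copy(),
            mask=self.mask[np.ix_(idx, idx)].copy(),
            symmetric=self.symmetric,
        )

    def write_tsv(self, values_path, mask_path=None) -> None:
        pd.DataFrame(self.values, index=self.terms, columns=self.terms).to_csv(values_path, sep="\t")
        if mask_path is not None:
            pd.DataFrame(self.mask.astype(int), index=self.terms, columns=self.terms).to_csv(mask_path, sep="\t")

    @classmethod
    def read_tsv(cls, values_path, mask_path=None, symmetric: bool = True) -> "PairScoreMatrix":
        vals = pd.read_csv(values_path, sep="\t", index_col=0)
        terms = [str(t) for t in vals.index]
        if mask_path is not None:
            mask = pd.read_csv(mask_path, sep="\t", index_col=0).to_numpy().astype(bool)
        else:
            mask = np.isnan(vals.to_numpy())
        return cls(terms=terms, values=np.nan_to_num(vals.to_numpy()), mask=mask, symmetric=symmetric)


def overlap_matrix(table: AnnotationTable, terms: Sequence[str] | None = None) -> PairScoreMatrix:
    """Counts of shared proteins: entry (i, j) = |proteins(i) & proteins(j)|."""
    terms = list(terms) if terms is not None else list(table.terms)
    psets = table.protein_sets()
    k = len(terms)
    vals = np.zeros((k, k))
    for i, t1 in enumerate(terms):
        for j, t2 in enumerate(terms):
            if j < i:
                continue
            vals[i, j] = vals[j, i] = len(psets.get(t1, set()) & psets.get(t2, set()))
    return PairScoreMatrix(terms=terms, values=vals, mask=np.zeros((k, k), bool), symmetric=True)


def overlap_fraction_matrix(table: AnnotationTable, terms: Sequence[str] | None = None) -> PairScoreMatrix:
    """Row-normalized overlap: entry (i, j) = |intersection| / count(i).

    Not symmetric: the fraction of term i's proteins that term j also
    annotates. Diagonal is 1 by construction. Zero-count terms are an error.
    """
    terms = list(terms) if terms is not None else list(table.terms)
    psets = table.protein_sets()
    for t in terms:
        if not psets.get(t):
            raise ValueError(f"term {t!r} has no annotated proteins")
    k = len(terms)
    vals = np.zeros((k, k))
    for i, t1 in enumerate(terms):
        for j, t2 in enumerate(terms):
            vals[i, j] = len(psets[t1] & psets[t2]) / len(psets[t1])
    return PairScoreMatrix(terms=terms, values=vals, mask=np.zeros((k, k), bool), symmetric=False)
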