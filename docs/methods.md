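# Methods

This note documents the models and procedures implemented in `gosubset`,
the parameters that matter, the numerical choices made where a definition
was genuinely open, and what the synthetic-data tests do and do not
establish.

## Ontology handling

The working object is the subtree of a chosen root term restricted to a
set of kept relations (default `is_a` only), over one ontology aspect.
Terms from which the root cannot be reached through kept edges of the
chosen aspect are dropped, so downstream code may assume a single-rooted
DAG whose every term's ancestor set contains the root.

**Term level.** The level of a term is its graph distance from the root
and serves as an abstraction proxy in tie-breaking. Distance is ambiguous
on a DAG; the default is the *shortest* child→parent path (deterministic,
cheap, and "more abstract = closer to the root" in the intuitive sense),
with longest-path depth available via `term_levels(..., mode="longest")`
for users who prefer the classical ontology depth.

**Identifier updates.** `alt_id` tags map secondary/obsolete identifiers
to the stanza's primary identifier; obsolete stanzas contribute only their
`replaced_by` target. If a secondary identifier maps to two different
primaries (possible in wild files), the first mapping wins and a warning
is logged.

## Dataset construction

Protein filters (review status, evidence-of-existence level, fragment
flag, taxonomy whitelist, gene-name presence) are conjunctive and
order-preserving. "Experimentally proven existence" defaults to existence
levels 1–2 (protein or transcript evidence); the threshold is a parameter.
Sequences are cleaned by deleting every character outside the 20 standard
residues (ambiguity codes B, Z, J, X, gaps, stops); proteins left empty
are excluded.

Annotation filters keep records by evidence-code and qualifier whitelist
(default: experimental + curated evidence, IEA excluded; qualifier
`enables`). Ancestor propagation then closes the protein–term relation
upward: the relation is replaced by its closure, which is idempotent and
makes `count(root)` equal the number of annotated proteins.

**Sequence clustering.** Redundancy removal is a greedy longest-first
pass: records sorted by decreasing length; each joins the first cluster
whose representative it matches at ≥ the threshold identity, else founds
one. This mirrors representative-based tools (CD-HIT) but uses exact
global-alignment identity rather than word-count shortcuts, so thresholds
are not numerically interchangeable with CD-HIT's. A precomputed
membership table can be supplied instead for parity runs.

## Sequence identity

Global alignment uses BLOSUM62 with affine gap penalties: a gap of length
k costs `open + (k−1)·extend`, defaults 10 and 4. Because substitution
scores are integers, many alignments are usually co-optimal and they can
differ in the number of identical columns and in length — "percent
identity of the optimal alignment" is not well defined by the score alone.
`gosubset` therefore reports a canonical value: among score-optimal
alignments, the one with the most identities, and among those the
shortest. This is computed in one pass by a Gotoh three-state DP over
lexicographically ordered `(score, matches, −length)` tuples (additive
transitions preserve optimal substructure under lexicographic order). The
score component is cross-checked against Biopython's `PairwiseAligner` in
tests; the full tuple against an independent memoized recursion and, at
tiny lengths, exhaustive enumeration of all alignments.

Identity denominator: alignment length including gap columns (default) or
the shorter sequence length (`denominator="shorter"`).

Term-level sequence similarity aggregates pairwise identities over the
cross-product of two terms' protein sets (mean/median/min/max). A protein
annotated with both terms contributes its self-pair (identity 1.0) by
default; `include_self_pairs=False` excludes it.

## Wang semantic similarity

For a term *t*, every term *a* in its ancestor closure (including *t*)
receives an S-value: `S_t(t) = 1`, and `S_t(a)` is the maximum over child
edges into *a* of `w(relation) · S_t(child)`, with `w(is_a) = 0.8` by
default (`part_of` = 0.6 where such edges are kept). The similarity of two
terms is the sum of both terms' S-values over their shared closure terms,
divided by the sum of all S-values of both. The value lies in [0, 1] and
equals 1 exactly for identical terms.

## Pairwise classifier evaluation

For an admissible pair, samples are the union of the two protein sets and
the label is the 2-bit membership vector (shared proteins are (1, 1)).
Admissibility requires ≥ *m* unique proteins on each side — this excludes
parent/child pairs, where the minority "unique" class would be empty or
tiny.

The classifier is binary relevance: one RBF-kernel SVM per output,
preceded by per-output ANOVA-F feature selection (top *p*% of dimensions)
or PCA (components capturing *p*% of variance). Evaluation is nested
stratified cross-validation (5 outer × 5 inner folds; "five iterations"
is read as five outer folds). Stratification uses the joint 2-bit label.
The inner loop selects `(p, C, γ)` by mean macro-F1; the grid defaults to
C ∈ {0.1, 1, 10, 100}, γ ∈ {0.1, 1, 10}/d for d selected dimensions, p ∈
{10, 25, 50, 100}. Ties resolve toward smaller C, then larger p (simpler
models, more features), then smaller γ, by fixed search order. The pair's
score is the macro-averaged F1 across outer test folds.

**Standardization order.** Feature dimensions are z-scored. By default the
scaler is fitted on each training fold only and applied to the held-out
fold; fitting once on all samples before CV (which leaks test statistics
into training) is available as `leaky_standardize=True` for reproducing
pipelines that standardize up front.

**Feature blocks.** AAC (20 residue frequencies), PAAC (400 ordered
dipeptide frequencies over the L−1 overlapping pairs), and summaries of
externally computed PSSM profiles (one per search configuration). The
published feature space this emulates totals 1,600 dimensions, but its
exact PSSM block composition is defined in prior work not reproduced
here; block definitions are therefore pluggable and the default PSSM
summary is the column-wise mean of sigmoid-squashed log-odds (20
dimensions per profile variant). Pipeline behavior does not depend on the
exact block sizes. A missing profile file falls back to the neutral row
(sigmoid(0) = 0.5) with a warning so sequence-only operation works.

## Greedy reduction

Parameters: *n* (minimum proteins per term, default 20), *m* (minimum
unique proteins per pair, default 15; it must be ≥ the outer fold count),
*p* (top count-percentile removed up front, default 0), *c* (minimum
coverage, default 0.9), preference (which terms to keep: `specific`
removes the most abstract tied candidate; `abstract` the reverse), *ε*
(tie slack on score deltas, default 0; ≤ 0.05 recommended since scores
live in [0, 1]), fill value for masked pairs (default −1), and the RNG
seed.

The percentile ceiling is a linear-interpolation percentile computed over
the counts of *all* input terms excluding the root, before the *n*-floor
is applied; the root never enters the working set. The score matrix is
computed once on the prefiltered set and never re-trained inside the
loop.

Each step: terms whose removal keeps coverage ≥ *c* are candidates; each
candidate's delta is the mean pairwise score without it minus the current
mean (masked pairs counted at the fill value; the mean of a singleton
remainder is taken as 0). The ε-argmax set is reduced to the extreme
level, then a single draw from a seeded `numpy` `default_rng` picks among
residual ties. The draw is consumed *only* when the post-level tie has ≥ 2
members, so traces are prefix-stable. Delta comparisons use the stored
means exactly; ε is the only tolerance.

Termination follows coverage alone: the best-delta candidate is removed
even when its delta is ≤ 0, until no candidate remains. (The alternative
reading — stop at the first non-positive delta — is available as
`require_positive_delta=True`.) Coverage of a candidate removal is the
union over the *remaining* terms only; the trace records coverage before
and after each removal for audit.

With fill −1, a term all of whose pairs are masked maximally depresses
the mean, so such terms are removed first whenever coverage admits —
this is the mechanism that eliminates abstract umbrella terms entangled
in unevaluable parent/child pairs.

## Comparative statistics

Pairs are split at macro-F1 0.75 (strictly below vs at-or-above); groups
smaller than 30 trigger a warning, smaller than 3 skip the tests. The
normality screen follows the Shapiro–Wilk *statistic* > 0.9 rule (not its
p-value). Normal variables get one-sided Welch t-tests in both tail
directions; others get Mann–Whitney U tests (exact enumeration below a
combined n of 25 when tie-free, midrank normal approximation with tie
correction otherwise). All p-values are Benjamini–Hochberg adjusted
(step-up, monotone, capped at 1; delegated to statsmodels). Monotone
association uses Spearman rank correlation (Pearson on midranks);
constant inputs return NaN.

## Synthetic world

The generators state a world rather than tune one: four leaf classes of
40 proteins under a balanced binary tree (defaults), class centroids
exactly δ = 6 pooled standard deviations apart (unit isotropic Gaussian
noise; centroids at `δ/√2` along orthogonal axes so *every* centroid pair
is δ apart), dual-membership proteins drawn around the centroid midpoint
so multi-label behavior is genuinely exercised, and 300-residue
uniform-composition prototypes mutated at 10% per position (substitution
always to a different residue, giving within-class identity ≈ (1−r)² ≈
0.8 at r = 0.1 and background identity ≈ 0.15 between classes). δ = 6
makes a midpoint-threshold classifier ≥ 99% accurate in expectation
(Φ(3) per class), which is what the end-to-end recovery test exploits;
δ = 0 collapses all classes to one distribution for the chance-level
control.

What a green synthetic test does *not* establish: real transporter
families are not isotropic Gaussians in feature space, real GO subtrees
are far deeper and more unbalanced, annotation counts follow a steep
exponential rather than equal class sizes, and PSSM-derived features are
not simulated at all. The synthetic results validate the machinery
(propagation, masking, scoring, the greedy loop, determinism), not
biological performance claims.

## Reproducibility and runtime choices

Every stochastic component (fold shuffling, tie-break draws, generators)
is seeded from explicit config fields; two runs with identical config and
seed produce byte-identical subset and trace files. Tests and example
configurations use a reduced hyperparameter grid (a `PairEvalConfig`
knob — the search shrinks, the pipeline does not change) to keep the
suite fast; the full default grid is used by `scripts/acceptance.py`.
The pure-Python alignment DP handles the package's test scales (≤ 300
residues) in well under 0.1 s per pair; large proteome-scale runs would
want a compiled aligner behind the same interface.

## Known limitations

- No globally optimal subset search (the greedy loop can hit local
  optima; ε plus seeds provide cheap restarts, as intended).
- CD-HIT word-identity and global-alignment identity diverge near the
  threshold; cluster memberships are not expected to match CD-HIT's
  exactly.
- PSSM profiles are consumed, never computed; no profile-search binding.
- Chemistry-ontology cross-references (substrate fingerprint similarity)
  are out of scope.
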