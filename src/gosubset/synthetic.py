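"""Ground-truth fixture generators: ontology, labels, features, sequences.

Every stage of the pipeline can be exercised without external downloads by
generating a small world with known structure: a rooted term DAG whose
leaves are the "true" classes, a multi-label annotation table with
controllable sibling overlap, Gaussian feature vectors with controllable
class separation (in pooled-SD units), and mutated-prototype sequences
with controllable within-class identity.

All randomness derives from the spec's seed; each generator draws from its
own deterministic stream, so regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from gosubset.dataset import AnnotationTable, AnnotationRecord, propagate
from gosubset.features import FeatureMatrix, RESIDUES
from gosubset.ontology import OntologyGraph

ROOT = "T:0000000"


@dataclass(frozen=True)
class SynthSpec:
    """Stated world of the synthetic fixtures.

    Defaults mirror the scale at which pairwise classifier behavior is
    assessed: four leaf classes of 40 proteins each, centroids six pooled
    standard deviations apart (near-perfectly separable by construction),
    300-residue sequences mutated at 10% per position within a class.
    """

    n_leaf_classes: int = 4
    proteins_per_class: int = 40
    overlap_fraction: float = 0.0
    dag_shape: str = "tree"  # tree | chain | diamond
    arity: int = 2
    class_separation: float = 6.0
    feature_dim: int = 16
    mutation_rate: float = 0.1
    seq_length: int = 300
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        if self.feature_dim < self.n_leaf_classes:
            raise ValueError("feature_dim must be >= n_leaf_classes")


def leaf_terms(spec: SynthSpec) -> list[str]:
    return [f"T:L{i}" for i in range(spec.n_leaf_classes)]


def make_ontology(spec: SynthSpec) -> OntologyGraph:
    """Rooted DAG whose leaves are the classes; internal terms are unions.

    ``tree``: balanced tree of the given arity over the leaves.
    ``chain``: the leaves form a path under the root (nested classes).
    ``diamond``: two internal terms both subsume leaf 0 (a multi-parent
    leaf); remaining leaves hang off the root.
    """
    g = OntologyGraph(root=ROOT)
    leaves = leaf_terms(spec)
    g.terms.add(ROOT)
    g.names[ROOT] = "synthetic root activity"
    for t in leaves:
        g.terms.add(t)
        g.names[t] = f"leaf class {t}"

    if spec.dag_shape == "tree":
        counter = 0

        def build(parent: str, members: list[str]) -> None:
            nonlocal counter
            if len(members) == 1:
                g.edges.add((members[0], parent, "is_a"))
                return
            k = min(spec.arity, len(members))
            size = math.ceil(len(members) / k)
            for start in range(0, len(members), size):
                group = members[start:start + size]
                if len(group) == 1:
                    g.edges.add((group[0], parent, "is_a"))
                else:
                    node = f"T:I{counter}"
                    counter += 1
                    g.terms.add(node)
                    g.names[node] = f"internal {node}"
                    g.edges.add((node, parent, "is_a"))
                    build(node, group)

        build(ROOT, leaves)
    elif spec.dag_shape == "chain":
        prev = ROOT
        for t in leaves:
            g.edges.add((t, prev, "is_a"))
            prev = t
    elif spec.dag_shape == "diamond":
        for node in ("T:IB", "T:IC"):
            g.terms.add(node)
            g.names[node] = f"internal {node}"
            g.edges.add((node, ROOT, "is_a"))
        g.edges.add((leaves[0], "T:IB", "is_a"))
        g.edges.add((leaves[0], "T:IC", "is_a"))
        for t in leaves[1:]:
            g.edges.add((t, ROOT, "is_a"))
    else:
        raise ValueError(f"unknown dag_shape {spec.dag_shape!r}")
    g.namespaces.update({t: "molecular_function" for t in g.terms})
    return g


def make_annotations(spec: SynthSpec, g: OntologyGraph) -> tuple[AnnotationTable, dict[str, tuple[str, ...]]]:
    """Annotation table (ancestor-closed) plus ground-truth leaf memberships.

    Each protein belongs to one leaf class; for each designated sibling pair
    (consecutive leaves 0-1, 2-3, ...) a ``round(overlap_fraction * n)``
    share of the first sibling's proteins additionally carries the second
    sibling's leaf.
    """
    leaves = leaf_terms(spec)
    memberships: dict[str, tuple[str, ...]] = {}
    records = []
    for ci, leaf in enumerate(leaves):
        for k in range(spec.proteins_per_class):
            acc = f"P{ci:02d}_{k:03d}"
            memberships[acc] = (leaf,)
            records.append(AnnotationRecord(accession=acc, term=leaf))
    n_extra = round(spec.overlap_fraction * spec.proteins_per_class)
    for first in range(0, spec.n_leaf_classes - 1, 2):
        second = first + 1
        for k in range(n_extra):
            acc = f"P{first:02d}_{k:03d}"
            memberships[acc] = (leaves[first], leaves[second])
            records.append(AnnotationRecord(accession=acc, term=leaves[second]))
    table = AnnotationTable.from_records(records)
    return propagate(table, g), memberships


def make_features(spec: SynthSpec, memberships: Mapping[str, tuple[str, ...]]) -> FeatureMatrix:
    """Gaussian feature vectors with centroids ``class_separation`` apart.

    Each leaf class has a centroid; all centroid pairs are exactly delta
    apart in pooled-SD units (unit isotropic noise). A dual-membership
    protein is drawn around the midpoint of its two centroids.
    """
    rng = np.random.default_rng([spec.seed, 1])
    leaves = leaf_terms(spec)
    # delta/sqrt(2) along orthogonal unit axes puts every centroid pair at distance delta
    centroids = {}
    for i, leaf in enumerate(leaves):
        c = np.zeros(spec.feature_dim)
        c[i] = spec.class_separation / math.sqrt(2.0)
        centroids[leaf] = c
    proteins = sorted(memberships)
    values = np.empty((len(proteins), spec.feature_dim))
    for row, acc in enumerate(proteins):
        cs = [centroids[t] for t in memberships[acc]]
        mu = np.mean(cs, axis=0)
        values[row] = mu + rng.standard_normal(spec.feature_dim)
    return FeatureMatrix(
        proteins=proteins,
        block_names=["SYNTH"],
        block_dims=[spec.feature_dim],
        values=values,
        standardized=False,
    )


def make_sequences(spec: SynthSpec, memberships: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    """Mutated-prototype sequences: one random prototype per leaf class.

    Members substitute each position independently at ``mutation_rate``
    (always to a *different* residue), so two members of one class agree at
    a position with probability about ``(1 - r)^2``, i.e. expected
    within-class identity ~ 1 - 2r for small r. Between-class identity sits
    at the uniform-composition background. Dual-membership proteins derive
    from their first class's prototype.
    """
    rng = np.random.default_rng([spec.seed, 2])
    residues = np.array(RESIDUES)
    prototypes = {
        leaf: rng.choice(residues, size=spec.seq_length)
        for leaf in leaf_terms(spec)
    }
    out: dict[str, str] = {}
    for acc in sorted(memberships):
        proto = prototypes[memberships[acc][0]].copy()
        hit = rng.random(spec.seq_length) < spec.mutation_rate
        for pos in np.nonzero(hit)[0]:
            alternatives = residues[residues != proto[pos]]
            proto[pos] = rng.choice(alternatives)
        out[acc] = "".join(proto)
    return out


def to_obo_text(g: OntologyGraph) -> str:
    """Serialize a graph as minimal OBO flat-file text (round-trippable)."""
    chunks = ["format-version: 1.2\n"]
    for t in sorted(g.terms):
        lines = [f"[Term]", f"id: {t}"]
        if t in g.names:
            lines.append(f"name: {g.names[t]}")
        if t in g.namespaces:
            lines.append(f"namespace: {g.namespaces[t]}")
        for old, new in sorted(g.alt_ids.items()):
            if new == t:
                lines.append(f"alt_id: {old}")
        for c, p, r in sorted(g.edges):
            if c == t:
                lines.append(f"is_a: {p}" if r == "is_a" else f"relationship: {r} {p}")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)
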