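"""Ontology graph handling: OBO parsing, subtree filtering, levels.

The working object is a rooted directed acyclic graph of annotation terms
with child->parent edges tagged by relation name (``is_a``, ``part_of``,
...). The pipeline operates on the subtree of a chosen root (for membrane
transporters: *transmembrane transporter activity*) restricted to ``is_a``
edges, so downstream code can rely on a single-rooted DAG in which every
term's ancestor set contains the root.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class OboParseError(ValueError):
    """Raised for malformed OBO input; message names the offending line."""


@dataclass
class OntologyGraph:
    """Directed acyclic graph of ontology terms.

    Attributes
    ----------
    terms : set of term identifiers (non-obsolete).
    edges : set of ``(child, parent, relation)`` triples.
    alt_ids : mapping obsolete/secondary identifier -> current identifier.
    root : identifier of the subtree root, or ``None`` before filtering.
    names : term -> human-readable name.
    namespaces : term -> aspect label (e.g. ``molecular_function``).
    """

    terms: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)
    root: str | None = None
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def resolve(self, term: str) -> str:
        """Map a possibly-obsolete identifier to its current one."""
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> set[str]:
        return {p for c, p, _ in self.edges if c == term}

    def children(self, term: str) -> set[str]:
        return {c for c, p, _ in self.edges if p == term}

    def _child_to_parents(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p, _ in self.edges:
            adj.setdefault(c, set()).add(p)
        return adj

    def _parent_to_children(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p, _ in self.edges:
            adj.setdefault(p, set()).add(c)
        return adj

    def to_networkx(self) -> nx.DiGraph:
        """Child->parent DiGraph over the kept edges (relation as edge attr)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for c, p, r in self.edges:
            g.add_edge(c, p, relation=r)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    # -- serialization -------------------------------------------------

    def write_edgelist(self, edge_path, header_path=None) -> None:
        """Write edges as TSV (child, parent, relation) plus a JSON header."""
        with open(edge_path, "w") as fh:
            fh.write("child\tparent\trelation\n")
            for c, p, r in sorted(self.edges):
                fh.write(f"{c}\t{p}\t{r}\n")
        if header_path is not None:
            header = {
                "root": self.root,
                "relations": sorted({r for _, _, r in self.edges}),
                "n_terms": len(self.terms),
                "terms": sorted(self.terms),
                "names": {t: self.names.get(t, "") for t in sorted(self.terms)},
            }
            with open(header_path, "w") as fh:
                json.dump(header, fh, indent=1)

    @classmethod
    def read_edgelist(cls, edge_path, header_path=None) -> "OntologyGraph":
        g = cls()
        with open(edge_path) as fh:
            header = fh.readline()
            if not header.startswith("child\t"):
                raise OboParseError(f"unexpected edge-list header: {header!r}")
            for line in fh:
                c, p, r = line.rstrip("\n").split("\t")
                g.edges.add((c, p, r))
                g.terms.update((c, p))
        if header_path is not None:
            with open(header_path) as fh:
                meta = json.load(fh)
            g.root = meta.get("root")
            g.terms.update(meta.get("terms", []))
            g.names.update(meta.get("names", {}))
        return g


def parse_obo(stream: IO[str] | str) -> OntologyGraph:
    """Parse OBO 1.2/1.4 flat-file text into an :class:`OntologyGraph`.

    Non-obsolete ``[Term]`` stanzas contribute terms, names, namespaces,
    ``is_a`` and ``relationship:`` edges, and ``alt_id`` entries (mapping the
    secondary id to the stanza's id). Obsolete stanzas contribute only
    identifier-update entries, via their ``replaced_by`` tag.

    Raises
    ------
    OboParseError
        On a tag line without a colon, or a stanza lacking an ``id:`` field;
        the message contains the 1-based line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    g = OntologyGraph()
    # each stanza collected as list of (lineno, tag, value)
    stanza: list[tuple[int, str, str]] | None = None
    stanza_start = 0
    pending: list[tuple[list[tuple[int, str, str]], int]] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip() if not raw.lstrip().startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            if stanza is not None:
                pending.append((stanza, stanza_start))
            stanza = [] if line == "[Term]" else None
            stanza_start = lineno
            continue
        if stanza is None:
            continue  # header or non-Term stanza
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, value = line.split(":", 1)
        stanza.append((lineno, tag.strip(), value.strip()))
    if stanza is not None:
        pending.append((stanza, stanza_start))

    for fields, start in pending:
        tags: dict[str, list[str]] = {}
        for _, tag, value in fields:
            tags.setdefault(tag, []).append(value)
        ids = tags.get("id", [])
        if not ids:
            raise OboParseError(f"stanza at line {start}: missing 'id' field")
        tid = ids[0]
        obsolete = tags.get("is_obsolete", ["false"])[0].lower() == "true"
        if obsolete:
            for target in tags.get("replaced_by", [])[:1]:
                _add_alt(g, tid, target)
            continue
        g.terms.add(tid)
        if "name" in tags:
            g.names[tid] = tags["name"][0]
        if "namespace" in tags:
            g.namespaces[tid] = tags["namespace"][0]
        for old in tags.get("alt_id", []):
            _add_alt(g, old, tid)
        for parent in tags.get("is_a", []):
            g.edges.add((tid, parent.split()[0], "is_a"))
        for rel in tags.get("relationship", []):
            parts = rel.split()
            if len(parts) >= 2:
                g.edges.add((tid, parts[1], parts[0]))
    return g


def _add_alt(g: OntologyGraph, old: str, new: str) -> None:
    if old in g.alt_ids and g.alt_ids[old] != new:
        logger.warning("alt_id %s maps to both %s and %s; keeping first", old, g.alt_ids[old], new)
        return
    g.alt_ids[old] = new


def filter_subtree(
    g: OntologyGraph,
    root: str,
    relations: Iterable[str] = ("is_a",),
    aspect: str | None = None,
) -> OntologyGraph:
    """Restrict ``g`` to the descendants of ``root`` under kept relations.

    Keeps only edges whose relation is in ``relations`` and only terms of
    the given aspect (namespace) from which ``root`` is reachable via kept
    child->parent edges. Idempotent. ``alt_ids`` are retained only where the
    target survives.
    """
    if root not in g.terms:
        raise KeyError(f"root term {root!r} not in graph")
    relations = set(relations)
    kept_edges = {(c, p, r) for c, p, r in g.edges if r in relations}

    def aspect_ok(t: str) -> bool:
        if aspect is None:
            return True
        ns = g.namespaces.get(t)
        if ns is None:
            logger.warning("term %s has no namespace; dropped by aspect filter", t)
            return False
        return ns == aspect

    # BFS downward from root over kept edges, restricted to the aspect.
    down = {t: set() for t in g.terms}
    for c, p, _ in kept_edges:
        down.setdefault(p, set()).add(c)
    reachable: set[str] = set()
    queue = deque([root])
    while queue:
        t = queue.popleft()
        if t in reachable or not aspect_ok(t):
            continue
        reachable.add(t)
        queue.extend(down.get(t, ()))

    out = OntologyGraph(
        terms=reachable,
        edges={(c, p, r) for c, p, r in kept_edges if c in reachable and p in reachable},
        alt_ids={o: n for o, n in g.alt_ids.items() if n in reachable},
        root=root,
        names={t: g.names[t] for t in reachable if t in g.names},
        namespaces={t: g.namespaces[t] for t in reachable if t in g.namespaces},
    )
    if not nx.is_directed_acyclic_graph(out.to_networkx()):
        raise ValueError("kept relations induce a cycle; not a valid ontology subtree")
    return out


def ancestors(g: OntologyGraph, term: str) -> set[str]:
    """Transitive closure of child->parent edges from ``term`` (excl. itself)."""
    if term not in g.terms:
        raise KeyError(f"term {term!r} not in graph")
    up = g._child_to_parents()
    seen: set[str] = set()
    queue = deque(up.get(term, ()))
    while queue:
        t = queue.popleft()
        if t in seen:
            continue
        seen.add(t)
        queue.extend(up.get(t, ()))
    return seen & g.terms


def term_levels(g: OntologyGraph, mode: str = "shortest") -> dict[str, int]:
    """Distance of every term from the root.

    The level is a proxy for abstraction: terms closer to the root are more
    abstract. ``mode="shortest"`` (default) is the BFS distance along
    child->parent edges; ``mode="longest"`` is the longest path, for callers
    preferring the classical ontology depth.

    Raises ``ValueError`` if any term cannot reach the root (subtree
    invariant violated) or the graph is not rooted.
    """
    if g.root is None:
        raise ValueError("graph has no root; apply filter_subtree first")
    down = g._parent_to_children()
    if mode == "shortest":
        levels = {g.root: 0}
        queue = deque([g.root])
        while queue:
            t = queue.popleft()
            for c in down.get(t, ()):
                if c not in levels:
                    levels[c] = levels[t] + 1
                    queue.append(c)
    elif mode == "longest":
        nxg = g.to_networkx().reverse()  # parent -> child
        order = list(nx.topological_sort(nxg))
        levels = {g.root: 0}
        for t in order:
            if t not in levels:
                continue
            for c in nxg.successors(t):
                levels[c] = max(levels.get(c, 0), levels[t] + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    missing = g.terms - levels.keys()
    if missing:
        raise ValueError(f"{len(missing)} terms unreachable from root, e.g. {sorted(missing)[:3]}")
    return levels
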