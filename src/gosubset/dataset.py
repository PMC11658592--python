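"""Protein dataset construction: filtering, annotation closure, clustering.

Builds the multi-label protein/term relation the rest of the pipeline runs
on. Proteins are filtered on review status, evidence of existence, fragment
flag, taxonomy and gene names; annotations are filtered on evidence code
and qualifier, re-mapped through identifier updates, and finally closed
under ontology ancestors so that annotating a protein with a term implies
annotation with every ancestor of that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from gosubset.ontology import OntologyGraph, ancestors

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: GO evidence codes by provenance class. IEA is the only purely electronic code.
EXPERIMENTAL_EVIDENCE = {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
CURATED_EVIDENCE = {"IBA", "IBD", "IKR", "IRD", "ISS", "ISO", "ISA", "ISM", "IGC", "RCA", "TAS", "IC", "NAS", "ND"}
ELECTRONIC_EVIDENCE = {"IEA"}
DEFAULT_EVIDENCE = EXPERIMENTAL_EVIDENCE | CURATED_EVIDENCE


class EmptySequenceError(ValueError):
    """Sequence contains no standard residues after cleaning."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    reviewed: bool = True
    existence_level: int = 1
    fragment: bool = False
    taxon: int = 0
    gene_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationRecord:
    accession: str
    term: str
    evidence_code: str = "EXP"
    qualifier: str = "enables"


@dataclass
class AnnotationTable:
    """Multi-label protein<->term relation.

    ``relation`` is a set of ``(accession, term)`` pairs. ``closed`` records
    whether ancestor propagation has been applied; once closed, membership
    in a term implies membership in all its ancestors.
    """

    proteins: list[str]
    terms: list[str]
    relation: set[tuple[str, str]]
    closed: bool = False

    @classmethod
    def from_records(cls, records: Iterable[AnnotationRecord]) -> "AnnotationTable":
        rel = {(r.accession, r.term) for r in records}
        return cls(
            proteins=sorted({p for p, _ in rel}),
            terms=sorted({t for _, t in rel}),
            relation=rel,
        )

    def proteins_of(self, term: str) -> set[str]:
        return {p for p, t in self.relation if t == term}

    def terms_of(self, accession: str) -> set[str]:
        return {t for p, t in self.relation if p == accession}

    def count(self, term: str) -> int:
        return len(self.proteins_of(term))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {t: 0 for t in self.terms}
        for _, t in self.relation:
            out[t] = out.get(t, 0) + 1
        return out

    def protein_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for p, t in self.relation:
            out.setdefault(t, set()).add(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.relation), columns=["accession", "term"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, closed: bool = False) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        rel = set(zip(df["accession"], df["term"]))
        tbl = cls(
            proteins=sorted({p for p, _ in rel}),
            terms=sorted({t for _, t in rel}),
            relation=rel,
            closed=closed,
        )
        return tbl


def clean_sequence(raw: str) -> str:
    """Delete every character outside the 20 standard residues.

    Ambiguity codes such as B, Z, J or X (and gaps, stops, whitespace) are
    removed; residue order is preserved. Raises :class:`EmptySequenceError`
    when nothing remains, so callers can exclude the protein.
    """
    cleaned = "".join(ch for ch in raw.upper() if ch in STANDARD_RESIDUES)
    if not cleaned:
        raise EmptySequenceError(f"sequence empty after removing non-standard residues: {raw[:30]!r}")
    return cleaned


def filter_proteins(
    records: Iterable[ProteinRecord],
    reviewed_only: bool = False,
    min_existence: int | None = None,
    drop_fragments: bool = False,
    taxa: Iterable[int] | None = None,
    require_gene_names: bool = False,
) -> list[ProteinRecord]:
    """Conjunction of the active per-record filters; input order preserved.

    ``min_existence`` keeps records with ``existence_level <= min_existence``
    (UniProt-style ordinal: 1 = protein-level evidence, 2 = transcript-level,
    larger = weaker). ``taxa`` is a whitelist of taxonomy identifiers.
    """
    if taxa is not None:
        taxa = {int(t) for t in taxa}
    out = []
    for r in records:
        if reviewed_only and not r.reviewed:
            continue
        if min_existence is not None and r.existence_level > min_existence:
            continue
        if drop_fragments and r.fragment:
            continue
        if taxa is not None and r.taxon not in taxa:
            continue
        if require_gene_names and not r.gene_names:
            continue
        out.append(r)
    return out


def filter_annotations(
    records: Iterable[AnnotationRecord],
    graph: OntologyGraph,
    allowed_evidence: Iterable[str] | None = None,
    allowed_qualifiers: Iterable[str] | None = ("enables",),
) -> list[AnnotationRecord]:
    """Keep annotations with allowed evidence/qualifier and a resolvable term.

    Obsolete term identifiers are updated through the graph's ``alt_ids``
    map; records whose (updated) term is absent from the graph are dropped
    with a log message, never fatally. ``None`` for either whitelist
    disables that filter.
    """
    allowed_evidence = set(allowed_evidence) if allowed_evidence is not None else None
    allowed_qualifiers = set(allowed_qualifiers) if allowed_qualifiers is not None else None
    out = []
    n_dropped = 0
    for r in records:
        if allowed_evidence is not None and r.evidence_code not in allowed_evidence:
            continue
        if allowed_qualifiers is not None and r.qualifier not in allowed_qualifiers:
            continue
        term = graph.resolve(r.term)
        if term not in graph.terms:
            n_dropped += 1
            continue
        out.append(r if term == r.term else replace(r, term=term))
    if n_dropped:
        logger.info("dropped %d annotations citing terms outside the working graph", n_dropped)
    return out


def propagate(table: AnnotationTable, graph: OntologyGraph) -> AnnotationTable:
    """Close the relation under ontology ancestors.

    Every ``(protein, term)`` pair gains ``(protein, a)`` for each ancestor
    ``a`` of ``term``. Idempotent; the returned table has ``closed=True``.
    """
    anc_cache: dict[str, set[str]] = {}
    rel = set(table.relation)
    for p, t in table.relation:
        if t not in graph.terms:
            raise KeyError(f"annotated term {t!r} missing from graph")
        if t not in anc_cache:
            anc_cache[t] = ancestors(graph, t)
        rel.update((p, a) for a in anc_cache[t])
    return AnnotationTable(
        proteins=sorted({p for p, _ in rel}),
        terms=sorted({t for _, t in rel}),
        relation=rel,
        closed=True,
    )


def cluster_sequences(
    records: Sequence[ProteinRecord],
    identity_threshold: float,
    deduplicate: bool = False,
) -> dict[str, int]:
    """Greedy longest-first single-linkage-to-representative clustering.

    Records are sorted by decreasing sequence length; each joins the first
    existing cluster whose *representative* it matches at >= threshold
    global identity, else founds a new cluster. Mirrors the classical
    representative-based redundancy removal (CD-HIT style) without the
    word-index shortcuts, so identities are exact global-alignment values.

    Returns accession -> cluster id (0-based, in order of founding). With
    ``deduplicate`` only the representatives' accessions are returned.
    """
    if not 0.4 <= identity_threshold <= 1.0:
        raise ValueError(f"identity threshold {identity_threshold} outside [0.4, 1.0]")
    from gosubset.simmatrix import global_identity

    order = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    reps: list[ProteinRecord] = []
    assignment: dict[str, int] = {}
    for rec in order:
        for cid, rep in enumerate(reps):
            if global_identity(rec.sequence, rep.sequence) >= identity_threshold:
                assignment[rec.accession] = cid
                break
        else:
            assignment[rec.accession] = len(reps)
            reps.append(rec)
    if deduplicate:
        return {rep.accession: cid for cid, rep in enumerate(reps)}
    return assignment


# -- file I/O ----------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Accession -> raw sequence from a FASTA file (first token of header)."""
    return {rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for acc in sorted(sequences):
            fh.write(f">{acc}\n{sequences[acc]}\n")


def read_protein_table(path) -> list[ProteinRecord]:
    """Read a UniProt-like TSV of protein metadata.

    Expected columns: accession, sequence, reviewed, existence, fragment,
    taxon, gene_names (gene names separated by spaces; may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProteinRecord(
                accession=row.accession,
                sequence=row.sequence,
                reviewed=str(row.reviewed).lower() in ("1", "true", "yes"),
                existence_level=int(row.existence),
                fragment=str(row.fragment).lower() in ("1", "true", "yes"),
                taxon=int(row.taxon),
                gene_names=tuple(str(row.gene_names).split()) if str(row.gene_names) else (),
            )
        )
    return out


def read_gaf_tsv(path) -> list[AnnotationRecord]:
    """Read a GAF-style TSV: accession, qualifier, term, evidence columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!").fillna("")
    return [
        AnnotationRecord(
            accession=row.accession,
            term=row.term,
            evidence_code=row.evidence,
            qualifier=row.qualifier,
        )
        for row in df.itertuples(index=False)
    ]
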