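"""Shared domain types and readers/writers for the pipeline's external formats.

The pipeline touches a handful of plain-text formats: protein and rDNA
FASTA, OBO 1.2 ontologies, ptt-style protein tables with COG assignments,
and TSV edge lists / matrices / result tables.  Everything here is strictly
deterministic: outputs are ordered lexicographically so repeated runs are
diffable byte for byte.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("paraclave")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

#: relationship types retained from OBO files
KEPT_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class Protein:
    """A single protein: identifier, sequence and COG category letters."""

    id: str
    sequence: str
    cog_categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains illegal characters: {sorted(bad)}"
            )


@dataclass
class Proteome:
    """An organism's protein complement plus genome metadata.

    ``genome_size`` is the length of the main chromosome in base pairs;
    plasmids are deliberately excluded so that genome-size trend fits are
    not distorted by plasmid-rich organisms.
    """

    organism_id: str
    species_label: str
    strain_label: str
    proteins: list[Protein]
    genome_size: int

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not self.proteins:
            raise ValueError("proteome must contain at least one protein")
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein IDs in proteome: {dup}")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def by_id(self) -> dict[str, Protein]:
        return {p.id: p for p in self.proteins}


class OntologyDag:
    """A rooted, acyclic ontology with ``is_a`` / ``part_of`` edges.

    Edges point child -> parent.  Roots are the terms without outgoing
    edges.  ``alt_ids`` maps secondary identifiers onto canonical ones.
    """

    def __init__(
        self,
        terms: Iterable[str],
        edges: Iterable[tuple[str, str, str]],
        namespaces: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: set[str] = set(terms)
        self.edges: set[tuple[str, str, str]] = set(edges)
        self.namespaces: dict[str, str] = dict(namespaces or {})
        self.names: dict[str, str] = dict(names or {})
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        for child, parent, rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child},{parent},{rel}) references unknown term")
            if rel not in KEPT_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in sorted(self.edges):
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def resolve(self, term: str) -> str:
        """Map an alt_id onto its canonical term ID (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> list[tuple[str, str]]:
        return self._parents[term]

    def children(self, term: str) -> list[tuple[str, str]]:
        return self._children[term]

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self._parents[t]}

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _ in self._parents[t]:
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def namespace(self, term: str) -> str:
        return self.namespaces.get(self.resolve(term), "process")

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class AnnotationMap:
    """Direct protein -> term assignments plus their ancestor closure."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class ResultBundle:
    """Provenance (parameters, seeds, digests) plus per-stage outputs."""

    provenance: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, output, **params) -> None:
        self.stages[stage] = output
        if params:
            self.provenance.setdefault("stages", {})[stage] = params

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str) + "\n"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    IDs are the first whitespace-delimited token of the header; sequences
    are uppercased.  Order is preserved.  Empty files and duplicate IDs are
    errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


_COG_CELL_RE = re.compile(r"^(?:COG\d+)?([A-Z]*)$")


def parse_cog_cell(cell: str) -> set[str]:
    """Parse a ptt COG cell such as ``COG0583K``, ``KL`` or ``-``.

    An optional leading ``COG<digits>`` token is stripped; the remaining
    letters are the category assignments.  ``-`` (or blank) means
    unclassified and yields the empty set.
    """
    cell = cell.strip()
    if cell in {"-", ""}:
        return set()
    m = _COG_CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"unparseable COG cell {cell!r}")
    return set(m.group(1))


def read_protein_table(path: str | Path) -> dict[str, set[str]]:
    """Read a ptt-style tab-delimited table into protein -> COG categories.

    The protein-ID column is the first of ``PID``/``Synonym``/``protein_id``
    present (else the first column); the COG column is the first whose
    header contains ``COG``.  Malformed rows are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = next(
        (c for c in ("PID", "Synonym", "protein_id", "id") if c in df.columns),
        df.columns[0],
    )
    cog_col = next((c for c in df.columns if "COG" in c.upper()), None)
    if cog_col is None:
        raise ValueError(f"no COG column found in {path} (columns: {list(df.columns)})")
    out: dict[str, set[str]] = {}
    skipped = 0
    for _, row in df.iterrows():
        pid = str(row[id_col]).strip()
        try:
            if not pid:
                raise ValueError("empty protein ID")
            out[pid] = parse_cog_cell(str(row[cog_col]))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping malformed row in %s: %s", path, exc)
    if skipped:
        logger.warning("%d malformed rows skipped in %s", skipped, path)
    return out


def read_obo(path: str | Path) -> OntologyDag:
    """Read an OBO 1.2 ontology, keeping only is_a and part_of edges.

    Obsolete terms are dropped (obonet's default) and alt_ids are mapped to
    their canonical terms.  A cycle raises an error naming one cycle.
    """
    graph = obonet.read_obo(str(path))
    terms = set(graph.nodes)
    edges: set[tuple[str, str, str]] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel in KEPT_RELATIONS and parent in terms:
            edges.add((child, parent, rel))
    namespaces: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        namespaces[term] = {
            "biological_process": "process",
            "molecular_function": "function",
            "cellular_component": "component",
        }.get(ns, ns or "process")
        names[term] = data.get("name", term)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    return OntologyDag(terms, edges, namespaces, names, alt_ids)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (protein_id, term_id) into a direct map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for pid, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(pid), set()).add(str(term))
    return out


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        g.add_edge(str(row.iloc[0]), str(row.iloc[1]), weight=row.iloc[2])
    return g


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a weighted graph as a 3-column TSV (source, target, weight)."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("weight", 1)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w}\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV with lexicographic row order."""
    matrix.sort_index(axis=0).sort_index(axis=1).to_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_annotations(direct: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "term_id": term}
        for pid in sorted(direct)
        for term in sorted(direct[pid])
    ]
    write_tsv(pd.DataFrame(rows, columns=["protein_id", "term_id"]), path)


def write_obo(dag: OntologyDag, path: str | Path) -> None:
    """Write an OntologyDag as a minimal OBO 1.2 document."""
    ns_long = {
        "process": "biological_process",
        "function": "molecular_function",
        "component": "cellular_component",
    }
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: paraclave-synthetic\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            ns = dag.namespaces.get(term, "process")
            fh.write(f"namespace: {ns_long.get(ns, ns)}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
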