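"""Ontologies and gene annotations.

An :class:`Ontology` is a directed acyclic graph of terms with child-to-parent
edges (``is_a`` and, by default, ``part_of``).  Flat controlled vocabularies
(KEGG/Reactome/InterPro-like) are represented as ontologies with no edges.
An :class:`AnnotationSet` maps genes to the terms they are directly annotated
with; propagation to ancestors happens downstream, when information content
is computed.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
import networkx as nx
import obonet

from ._util import (
    CyclicOntologyError,
    FormatError,
    UnknownParentError,
    logger,
)

DEFAULT_RELATIONS = ("is_a", "part_of")


class Ontology:
    """A DAG of terms with directed child->parent edges.

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` whose edges point from child to parent and carry
        a ``relation`` attribute.  The graph must be acyclic.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise CyclicOntologyError(f"ontology graph is cyclic: {path}")
        self._graph = graph
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_term_parents(
        cls,
        parents: Mapping[str, Iterable[str]],
        relation: str = "is_a",
    ) -> "Ontology":
        """Build from a mapping term -> iterable of parent terms.

        Every parent must itself appear as a key (terms with no parents map
        to an empty iterable).
        """
        g = nx.DiGraph()
        g.add_nodes_from(parents)
        for child, ps in parents.items():
            for p in ps:
                if p not in parents:
                    raise UnknownParentError(
                        f"term {child!r} references unknown parent {p!r}"
                    )
                g.add_edge(child, p, relation=relation)
        return cls(g)

    @classmethod
    def flat(cls, terms: Iterable[str]) -> "Ontology":
        """A hierarchy-less vocabulary: a set of terms with no edges."""
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        return cls(g)

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self._graph.nodes if self._graph.out_degree(t) == 0)

    @property
    def is_flat(self) -> bool:
        return self._graph.number_of_edges() == 0

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def parents(self, term: str) -> list[str]:
        return list(self._graph.successors(term))

    def children(self, term: str) -> list[str]:
        return list(self._graph.predecessors(term))

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable from ``term`` via parent edges (cached).

        With ``include_self`` the term itself is counted as its own ancestor,
        which is the convention used for common-ancestor computations.
        """
        if term not in self._graph:
            raise KeyError(f"unknown term: {term!r}")
        anc = self._anc_cache.get(term)
        if anc is None:
            anc = frozenset(nx.descendants(self._graph, term))
            self._anc_cache[term] = anc
        return anc | {term} if include_self else anc

    def descendants(self, term: str, include_self: bool = False) -> frozenset[str]:
        if term not in self._graph:
            raise KeyError(f"unknown term: {term!r}")
        dec = frozenset(nx.ancestors(self._graph, term))
        return dec | {term} if include_self else dec


class AnnotationSet:
    """Direct gene -> term annotations.

    Genes with an empty term set are dropped so that the universe (all genes
    with at least one annotation) is exactly the set of keys.
    """

    def __init__(
        self,
        direct: Mapping[str, Iterable[str]],
        source: str = "annotations",
        ontology: Ontology | None = None,
    ):
        self.direct: dict[str, frozenset[str]] = {
            g: frozenset(ts) for g, ts in direct.items() if ts
        }
        self.source = source
        if ontology is not None:
            unknown = self.terms - ontology.terms
            if unknown:
                some = ", ".join(sorted(unknown)[:5])
                raise FormatError(
                    f"{len(unknown)} annotated term(s) absent from ontology: {some}"
                )

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.direct)

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.direct.values():
            out |= ts
        return frozenset(out)

    def annotations(self, gene: str) -> frozenset[str]:
        return self.direct.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self.direct

    def __len__(self) -> int:
        return len(self.direct)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_STANZA_RE = re.compile(r"^\[(?P<name>[^\]]+)\]\s*$")


def _scan_obo_stanzas(path: str) -> tuple[set[str], set[str]]:
    """Light pre-scan of an OBO file: declared term ids and obsolete ids.

    The real parsing is done by obonet; this scan only exists to tell a
    parent that was never declared apart from one that obonet dropped.
    """
    declared: set[str] = set()
    obsolete: set[str] = set()
    in_term = False
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            m = _STANZA_RE.match(line)
            if m:
                in_term = m.group("name") == "Term"
                current = None
                continue
            if not in_term:
                continue
            if line.startswith("id:"):
                current = line[3:].strip()
                declared.add(current)
            elif line.startswith("is_obsolete:") and "true" in line and current:
                obsolete.add(current)
    return declared, obsolete


def load_obo(path: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> Ontology:
    """Parse an OBO 1.2 file into an :class:`Ontology`.

    Obsolete terms are excluded.  Only the configured relation types (default
    ``is_a`` and ``part_of``) become edges; all other relationships are
    ignored.  A reference to an undeclared parent term is a hard error, as is
    a cyclic graph.
    """
    relations = set(relations)
    declared, obsolete = _scan_obo_stanzas(path)
    multigraph = obonet.read_obo(path)  # skips obsolete stanzas

    g = nx.DiGraph()
    for node in multigraph.nodes:
        if node in obsolete:
            continue
        if node not in declared:
            raise UnknownParentError(f"reference to undeclared term {node!r}")
        g.add_node(node)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in relations:
            continue
        if parent in obsolete or child in obsolete:
            logger.warning("dropping edge to obsolete term: %s -> %s", child, parent)
            continue
        if parent not in declared:
            raise UnknownParentError(
                f"term {child!r} references undeclared parent {parent!r}"
            )
        g.add_edge(child, parent, relation=rel)
    return Ontology(g)


def write_obo(
    ont: Ontology,
    path: str,
    names: Mapping[str, str] | None = None,
) -> None:
    """Write a minimal OBO 1.2 file (used by the synthetic-data generator)."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: plnet\n")
        for term in sorted(ont.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {names.get(term, term)}\n")
            for parent in sorted(ont.parents(term)):
                rel = ont.graph.edges[term, parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def read_annotation_tsv(
    path: str,
    source: str | None = None,
    ontology: Ontology | None = None,
) -> AnnotationSet:
    """Read ``gene<TAB>term`` lines (``#`` comments and blank lines skipped)."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected 'gene<TAB>term', got {line!r}"
                )
            direct.setdefault(fields[0], set()).add(fields[1])
    return AnnotationSet(direct, source=source or path, ontology=ontology)


def write_annotation_tsv(ann: AnnotationSet, path: str, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for gene in sorted(ann.direct):
            for term in sorted(ann.direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gaf(
    path: str,
    evidence_codes: Iterable[str] | None = ("IDA", "IMP", "TAS", "IC"),
    source: str | None = None,
    ontology: Ontology | None = None,
) -> AnnotationSet:
    """Read a GAF 2.x association file (convenience reader).

    Uses column 2 (object id) and column 5 (term id); rows whose evidence
    code (column 7) is not in ``evidence_codes`` are skipped.  Pass
    ``evidence_codes=None`` to keep every row.
    """
    keep = set(evidence_codes) if evidence_codes is not None else None
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: fewer than 7 GAF columns")
            gene, term, evidence = fields[1], fields[4], fields[6]
            if keep is not None and evidence not in keep:
                continue
            direct.setdefault(gene, set()).add(term)
    return AnnotationSet(direct, source=source or path, ontology=ontology)


def read_gene_set(path: str) -> list[str]:
    """One gene id per line; ``#`` comments skipped; de-duplicated, order kept."""
    seen: set[str] = set()
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            gene = raw.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
    return out


def read_ortholog_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping source gene id -> target gene id."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            mapping[fields[0]] = fields[1]
    return mapping
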