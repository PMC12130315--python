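"""Ontology graph machinery: term classification, area mapping, and
semantic distances.

Terms live in a directed multigraph with child -> parent edges typed by
relation name (``is_a``, ``is_conjugate_base_of``, ``is_conjugate_acid_of``,
``is_tautomer_of``, ``has_role``, ...). ``is_a`` edges define the taxonomy
used for depth, descendant walks and the Leacock semantic distance; the
extended relation whitelist only matters for class matching, where e.g. a
conjugate base should count as a match for its acid's class.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "ClassScheme",
    "load_obo",
    "write_obo",
    "term_matches_class",
    "classify_entity",
    "map_to_areas",
    "leacock_distance",
    "bma_aggregate",
    "ORPHAN",
]

ORPHAN = "orphan"

DEFAULT_CLASS_RELATIONS = (
    "is_a",
    "is_conjugate_base_of",
    "is_conjugate_acid_of",
    "is_tautomer_of",
    "has_role",
)


def _norm_rel(rel: str) -> str:
    return rel.strip().replace(" ", "_")


class OntologyGraph:
    """Directed acyclic term graph with typed child->parent relations."""

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph
        isa = self.isa_subgraph()
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            raise ValueError(f"cycle over is_a edges: {cycle}")
        self._depth: int | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, edges, labels=None) -> "OntologyGraph":
        """Build from (child, parent, relation) triples."""
        g = nx.MultiDiGraph()
        for child, parent, rel in edges:
            g.add_edge(child, parent, key=_norm_rel(rel))
        for t in list(g.nodes):
            g.nodes[t].setdefault("name", t)
        if labels:
            for t, name in labels.items():
                g.add_node(t, name=name)
        return cls(g)

    # -- basic queries ------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term) -> bool:
        return term in self.graph

    def label(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def isa_subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, k in self.graph.edges(keys=True):
            if k == "is_a":
                g.add_edge(u, v)
        return g

    @property
    def roots(self) -> set[str]:
        """Terms with no outgoing typed edge."""
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term: {term}")

    def ancestors(self, term: str, relations=("is_a",)) -> dict[str, int]:
        """BFS child->parent over whitelisted relations.

        Returns {ancestor: edge distance}, including the term itself at 0.
        """
        self._require(term)
        rels = {_norm_rel(r) for r in relations}
        dist = {term: 0}
        queue = deque([term])
        while queue:
            u = queue.popleft()
            for _, v, k in self.graph.out_edges(u, keys=True):
                if k in rels and v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist

    def descendants(self, term: str) -> set[str]:
        """All terms reaching ``term`` via is_a edges (excluding itself)."""
        self._require(term)
        isa = self.isa_subgraph()
        return set(nx.ancestors(isa, term))  # nx ancestors = upstream = children here

    def max_depth(self) -> int:
        """Maximum root-to-leaf depth in node count over is_a edges."""
        if self._depth is None:
            isa = self.isa_subgraph()
            longest = nx.dag_longest_path_length(isa) if isa.number_of_nodes() else 0
            self._depth = longest + 1
        return self._depth


def load_obo(path) -> OntologyGraph:
    """Load an OBO file; obsolete terms are skipped."""
    g = obonet.read_obo(str(path))
    mg = nx.MultiDiGraph()
    mg.add_nodes_from((n, dict(d)) for n, d in g.nodes(data=True))
    for u, v, k in g.edges(keys=True):
        mg.add_edge(u, v, key=_norm_rel(k))
    return OntologyGraph(mg)


def write_obo(graph: OntologyGraph, path, ontology_name="toy-ontology") -> Path:
    """Serialize the term graph to a minimal OBO 1.2 file."""
    path = Path(path)
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(graph.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {graph.label(term)}")
        for _, parent, rel in sorted(graph.graph.out_edges(term, keys=True),
                                     key=lambda e: (e[2], e[1])):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {graph.label(parent)}")
            else:
                lines.append(f"relationship: {rel} {parent} ! {graph.label(parent)}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


@dataclass
class ClassScheme:
    """Ordered classification scheme: earlier classes win ambiguity.

    ``classes`` maps class label -> set of anchor terms, in priority
    order (most specific first, most generic last). ``relations`` is the
    whitelist of child->parent relations followed during matching.
    """

    classes: list[tuple[str, set[str]]]
    relations: tuple[str, ...] = DEFAULT_CLASS_RELATIONS

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")
        self.relations = tuple(_norm_rel(r) for r in self.relations)

    def validate(self, graph: OntologyGraph) -> None:
        for label, anchors in self.classes:
            missing = [a for a in anchors if a not in graph]
            if missing:
                raise ValueError(f"class {label!r}: anchors not in ontology: {missing}")


def term_matches_class(graph: OntologyGraph, term: str, class_anchors,
                       relations=DEFAULT_CLASS_RELATIONS) -> bool:
    """True iff an anchor is reachable from ``term`` walking child->parent
    over whitelisted relations (a term matches its own anchor)."""
    anchors = set(class_anchors)
    reached = graph.ancestors(term, relations=relations)
    return bool(anchors & reached.keys())


def classify_entity(graph: OntologyGraph, entity_terms, scheme: ClassScheme,
                    override: str | None = None) -> str:
    """Single class label for an entity's annotated terms.

    First match in scheme order wins; an empty term set yields
    ``"orphan"``. An ``override`` label (manual curation) takes
    precedence over everything.
    """
    if override is not None:
        return override
    terms = set(entity_terms)
    if not terms:
        return ORPHAN
    reachable: set[str] = set()
    for t in terms:
        reachable |= graph.ancestors(t, relations=scheme.relations).keys()
    for label, anchors in scheme.classes:
        if reachable & anchors:
            return label
    return ORPHAN


def map_to_areas(graph: OntologyGraph, entity_terms, area_terms,
                 exclusions=()) -> set[str]:
    """Areas (e.g. disease areas) hit by an entity's terms.

    An area is returned iff some non-excluded entity term equals it or is
    an is_a-descendant of it; a single term may hit several areas.
    """
    excl = set(exclusions)
    terms = {t for t in entity_terms if t not in excl and t in graph}
    areas = set()
    for area in area_terms:
        if area not in graph:
            continue
        hits = {area} | graph.descendants(area)
        if terms & hits:
            areas.add(area)
    return areas


def _isa_up_distances(graph: OntologyGraph, term: str) -> dict[str, int]:
    return graph.ancestors(term, relations=("is_a",))


def leacock_distance(graph: OntologyGraph, term_a: str, term_b: str) -> float:
    """Leacock-style semantic distance in [0, 1].

    Similarity ``s = -log(len / (2 D))`` where ``len`` is the node count
    on the shortest is_a path through a common ancestor (1 for identical
    terms) and ``D`` the maximum root-to-leaf depth in node count. The
    distance is ``1 - s / s_max`` with ``s_max = -log(1 / (2 D))``, so
    identical terms map to 0 and terms with no common ancestor to 1.
    """
    graph._require(term_a)
    graph._require(term_b)
    D = graph.max_depth()
    if term_a == term_b:
        return 0.0
    up_a = _isa_up_distances(graph, term_a)
    up_b = _isa_up_distances(graph, term_b)
    common = up_a.keys() & up_b.keys()
    if not common:
        return 1.0
    path_len = min(up_a[c] + up_b[c] for c in common) + 1  # node count
    s = -math.log(path_len / (2.0 * D))
    s_max = -math.log(1.0 / (2.0 * D))
    return float(np.clip(1.0 - s / s_max, 0.0, 1.0))


def bma_aggregate(pairwise: np.ndarray) -> float:
    """Best-match average of an |A| x |B| distance table.

    Mean of each row's minimum, averaged with the mean of each column's
    minimum: ``BMA = (mean_a min_b d + mean_b min_a d) / 2``.
    """
    m = np.asarray(pairwise, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("bma_aggregate requires a non-empty 2-d distance table")
    if np.isnan(m).any():
        raise ValueError("bma_aggregate requires a complete distance table")
    return float((m.min(axis=1).mean() + m.min(axis=0).mean()) / 2.0)


class TermDistanceCache:
    """Memoized Leacock distances over a fixed ontology."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._cache:
            self._cache[key] = leacock_distance(self.graph, a, b)
        return self._cache[key]
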