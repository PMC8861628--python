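"""Independent brute-force oracles used by the extraction tests.

These deliberately avoid the library's own traversal code: reachability by
plain breadth-first search over an edge list, relation extraction by
exhaustive triple scans, and the medical-domain filter as a literal
two-pass edge-walk.
"""

from collections import deque

from rdflib import RDF, SKOS, OWL, Graph, URIRef
from rdflib.namespace import DCTERMS


def bfs_ancestors(edges: dict, start, max_depth: int) -> set:
    """Breadth-first reachable set via successor lists, excluding start."""
    seen = set()
    queue = deque([(start, 0)])
    while queue:
        node, d = queue.popleft()
        if d >= max_depth:
            continue
        for parent in edges.get(node, ()):
            if parent not in seen and parent != start:
                seen.add(parent)
                queue.append((parent, d + 1))
    return seen


def edge_map(graph: Graph, relation: URIRef) -> dict:
    edges: dict = {}
    for s, _, o in graph.triples((None, relation, None)):
        edges.setdefault(s, []).append(o)
    return edges


def scan_pairs(graph: Graph, subject: URIRef, prop: URIRef) -> set:
    """All objects of (subject, prop, ?) by a full triple scan."""
    return {o for s, p, o in graph if s == subject and p == prop}


def two_pass_medical_filter(graph: Graph, entities, seeds, classes,
                            max_depth: int = 10) -> set:
    """The two-constraint medical-domain filter, applied by exhaustive
    edge-walks: returns the qualifying subject categories per entity."""
    seeds = set(seeds)
    classes = set(classes)
    broader = edge_map(graph, SKOS.broader)
    out = set()
    for e in entities:
        same = {o for s, p, o in graph if s == e and p == OWL.sameAs}
        typed = any((t, RDF.type, k) in graph for t in same for k in classes)
        if not typed:
            continue
        for subj in {o for s, p, o in graph
                     if s == e and p == DCTERMS.subject}:
            closure = {subj} | bfs_ancestors(broader, subj, max_depth)
            if closure & seeds:
                out.add((e, subj))
    return out
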