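"""Species similarity graph from shared overrepresented terms.

Two organisms are linked when their lists of overrepresented annotation
terms overlap strongly: at least ``min_count`` common terms AND the
overlap covering at least ``min_relative`` of the maximum possible overlap
for the pair, taken as ``min(|A|, |B|)``.  The weighted edge list can be
exported for any external graph viewer; layout and visual cluster picking
are out of scope.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx


def term_overlap(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[int, float]:
    """Absolute and relative overlap between two term sets.

    The relative overlap is ``|A ∩ B| / min(|A|, |B|)``; if either set is
    empty the result is ``(0, 0.0)``.
    """
    a, b = set(list_a), set(list_b)
    count = len(a & b)
    denom = min(len(a), len(b))
    return count, (count / denom if denom else 0.0)


def build_graph(
    term_lists: Mapping[str, Iterable[str]],
    min_count: int = 10,
    min_relative: float = 0.30,
) -> nx.Graph:
    """Thresholded organism graph; edge weight = shared term count.

    Only organisms incident to at least one retained edge appear as nodes,
    so sparse term lists yield an empty graph rather than isolated nodes.
    """
    if len(term_lists) < 2:
        raise ValueError("need at least 2 organisms")
    sets = {org: set(terms) for org, terms in term_lists.items()}
    orgs = sorted(sets)
    g = nx.Graph()
    for i, a in enumerate(orgs):
        for b in orgs[i + 1 :]:
            count, relative = term_overlap(sets[a], sets[b])
            if count >= min_count and relative >= min_relative:
                g.add_edge(a, b, weight=count)
    return g


def graph_summary(graph: nx.Graph) -> dict:
    """Deterministic node/edge/degree/component summary."""
    n = graph.number_of_nodes()
    degrees = sorted(d for _, d in graph.degree())
    return {
        "n_nodes": n,
        "n_edges": graph.number_of_edges(),
        "degree_min": degrees[0] if degrees else 0,
        "degree_max": degrees[-1] if degrees else 0,
        "degree_mean": (sum(degrees) / n) if n else 0.0,
        "n_components": nx.number_connected_components(graph) if n else 0,
    }
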