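"""Graph-based (Wang-style) semantic similarity between ontology terms.

Each term's meaning is encoded by the semantic contributions of its
ancestors: the term itself contributes 1, and a contribution decays by a
per-edge weight (0.8 for is_a, 0.6 for part_of) along each step towards
the root, taking the best (max-product) path.  The similarity of two terms
is the summed contribution of their shared ancestors, normalised by the
two total semantic values, giving a score in [0, 1].  Cross-namespace
pairs score 0 rather than being dropped, so mixed-namespace clusters are
penalised but their scores remain well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import OntologyDag

logger = logging.getLogger("paraclave")

DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SemanticValue:
    term: str
    s_values: dict[str, float]
    sv_total: float


def semantic_value(
    term: str, dag: OntologyDag, weights: Mapping[str, float] | None = None
) -> SemanticValue:
    """Ancestor contributions (S-values) and their sum for one term.

    ``S(term) = 1``; for an ancestor t, ``S(t)`` is the maximum over the
    children of t inside the term's ancestor graph of ``w(edge) * S(child)``.
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    term = dag.resolve(term)
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    anc = dag.ancestors(term)
    s: dict[str, float] = {}

    def value(t: str) -> float:
        if t in s:
            return s[t]
        if t == term:
            s[t] = 1.0
            return 1.0
        best = 0.0
        for child, rel in dag.children(t):
            if child in anc:
                cand = w[rel] * value(child)
                if cand > best:
                    best = cand
        s[t] = best
        return best

    for t in anc:
        value(t)
    return SemanticValue(term=term, s_values=s, sv_total=float(sum(s.values())))


def term_similarity(
    a: str, b: str, dag: OntologyDag, weights: Mapping[str, float] | None = None
) -> float:
    """Similarity in [0, 1]; identical terms score exactly 1."""
    a, b = dag.resolve(a), dag.resolve(b)
    if dag.namespace(a) != dag.namespace(b):
        return 0.0
    sa = semantic_value(a, dag, weights)
    sb = semantic_value(b, dag, weights)
    shared = set(sa.s_values) & set(sb.s_values)
    num = sum(sa.s_values[t] + sb.s_values[t] for t in shared)
    return num / (sa.sv_total + sb.sv_total)


def cluster_similarity(
    terms: Sequence[str],
    dag: OntologyDag,
    weights: Mapping[str, float] | None = None,
    include_self_pairs: bool = False,
) -> float:
    """Mean pairwise term similarity over a cluster's term set.

    A single-term cluster scores 1.0 (it is trivially self-similar; callers
    should treat singleton clusters separately when ranking).  With
    ``include_self_pairs`` the k self-pairs (each scoring 1) enter the mean
    as well.
    """
    terms = sorted(set(dag.resolve(t) for t in terms))
    if not terms:
        raise ValueError("cluster has no terms")
    if len(terms) == 1:
        return 1.0
    sims = [term_similarity(a, b, dag, weights) for a, b in combinations(terms, 2)]
    if include_self_pairs:
        sims.extend([1.0] * len(terms))
    return float(np.mean(sims))


def similarity_matrix(
    terms: Sequence[str], dag: OntologyDag, weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    terms = sorted(set(dag.resolve(t) for t in terms))
    mat = np.eye(len(terms))
    for i, a in enumerate(terms):
        for j in range(i + 1, len(terms)):
            mat[i, j] = mat[j, i] = term_similarity(a, terms[j], dag, weights)
    return pd.DataFrame(mat, index=terms, columns=terms)


def compare_backgrounds(
    scores_by_model: Mapping[str, Iterable[float]],
) -> tuple[pd.DataFrame, pd.DataFrame, str | None]:
    """Box-plot statistics and pairwise Welch t-tests across background models.

    Models with fewer than two cluster scores are excluded with a warning.
    Returns (summary table, pairwise two-sided p-values, highest-mean model).
    """
    usable: dict[str, np.ndarray] = {}
    for model, scores in scores_by_model.items():
        arr = np.asarray(list(scores), dtype=float)
        if arr.size < 2:
            logger.warning("model %s has %d scores (<2); excluded", model, arr.size)
            continue
        usable[model] = arr
    rows = []
    for model in sorted(usable):
        arr = usable[model]
        rows.append(
            {
                "model": model,
                "n": arr.size,
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
            }
        )
    summary = pd.DataFrame(rows, columns=["model", "n", "mean", "median", "q1", "q3"])
    pairs = []
    models = sorted(usable)
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            if np.array_equal(usable[a], usable[b]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(usable[a], usable[b], equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
            pairs.append({"model_a": a, "model_b": b, "p_value": p})
    pairwise = pd.DataFrame(pairs, columns=["model_a", "model_b", "p_value"])
    best = max(usable, key=lambda m: usable[m].mean()) if usable else None
    return summary, pairwise, best
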