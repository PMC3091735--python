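"""Per-organism term overrepresentation with selectable background models.

The test set is always an organism's paranome.  The background is one of
three pools: all paralogs across organisms, all proteins of all proteomes,
or the organism's own proteome.  Each annotated term with at least one
study hit is tested with a one-sided Fisher exact test (hypergeometric
upper tail) and Bonferroni-corrected over that organism's tested-term
count; only terms passing the corrected threshold in at least
``min_organisms`` distinct organisms survive the cross-organism filter.

Annotations follow the true-path rule: a protein annotated to a term is
implicitly annotated to every ancestor via is_a and part_of.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy.stats import hypergeom

from .core_model import AnnotationMap, OntologyDag

logger = logging.getLogger("paraclave")

BackgroundKind = Literal["all_paralogs", "all_proteomes", "individual_proteome"]


@dataclass(frozen=True)
class BackgroundModel:
    kind: BackgroundKind
    member_ids: frozenset[str]


@dataclass(frozen=True)
class EnrichmentRecord:
    organism_id: str
    term: str
    k: int  # study hits
    n: int  # study size
    K: int  # background hits
    N: int  # background size
    p_raw: float
    p_bonferroni: float
    m_tests: int


def propagate(
    annotations: AnnotationMap, dag: OntologyDag, relations: tuple[str, ...] = ("is_a", "part_of")
) -> AnnotationMap:
    """Ancestor-close the direct annotations (true-path rule).

    Terms not present in the ontology are dropped with a warning.  The
    default closes over both is_a and part_of; pass ``("is_a",)`` for
    is_a-only propagation.
    """
    if set(relations) == set(("is_a", "part_of")):
        anc = dag.ancestors
    else:
        wanted = set(relations)
        cache: dict[str, frozenset[str]] = {}

        def anc(term: str) -> frozenset[str]:
            term = dag.resolve(term)
            if term in cache:
                return cache[term]
            out = {term}
            stack = [term]
            while stack:
                t = stack.pop()
                for parent, rel in dag.parents(t):
                    if rel in wanted and parent not in out:
                        out.add(parent)
                        stack.append(parent)
            cache[term] = frozenset(out)
            return cache[term]

    direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    dropped: set[str] = set()
    for pid, terms in annotations.direct.items():
        kept = set()
        for t in terms:
            if t in dag:
                kept.add(dag.resolve(t))
            else:
                dropped.add(t)
        direct[pid] = kept
        closed: set[str] = set()
        for t in kept:
            closed |= anc(t)
        propagated[pid] = closed
    if dropped:
        logger.warning("dropped %d annotation terms not in ontology: %s",
                       len(dropped), sorted(dropped)[:5])
    return AnnotationMap(direct=direct, propagated=propagated)


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided overrepresentation p-value for a 2x2 table.

    P(X >= k) for X hypergeometric with ``n`` draws from ``N`` objects of
    which ``K`` are marked.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid 2x2 bounds: k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def term_counts(ids: Iterable[str], annotations: AnnotationMap) -> Counter:
    counts: Counter = Counter()
    for pid in ids:
        counts.update(annotations.propagated.get(pid, ()))
    return counts


def enrich_organism(
    organism_id: str,
    study_ids: set[str],
    background: BackgroundModel,
    annotations: AnnotationMap,
    alpha: float = 0.01,
    background_counts: Counter | None = None,
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Bonferroni-significant overrepresented terms for one paranome.

    Every term annotated (after propagation) to at least one study protein
    is tested; the Bonferroni factor is the number of such terms.  Records
    with corrected p below ``alpha`` are returned, sorted by raw p then
    term.  ``background_counts`` can be passed to reuse precomputed counts
    across organisms sharing a background.  With ``ease`` the conservative
    EASE-score variant is used: one study hit is removed before taking the
    tail, which penalises terms supported by very few genes.
    """
    if background.kind in ("all_paralogs", "individual_proteome"):
        stray = study_ids - background.member_ids
        if stray:
            raise ValueError(
                f"study set not contained in {background.kind} background: {sorted(stray)[:5]}"
            )
    if not study_ids:
        logger.warning("empty paranome for %s; no enrichment computed", organism_id)
        return []
    study = term_counts(study_ids, annotations)
    bg = (
        background_counts
        if background_counts is not None
        else term_counts(background.member_ids, annotations)
    )
    n = len(study_ids)
    N = len(background.member_ids)
    m = len(study)
    records = []
    for term in sorted(study):
        k = study[term]
        K = bg.get(term, 0)
        if k > K:
            raise ValueError(
                f"term {term}: study hits ({k}) exceed background hits ({K}); "
                "study annotations must be drawn from the background pool"
            )
        p = fisher_p(max(k - 1, 0) if ease else k, n, K, N)
        p_bonf = min(1.0, p * m)
        # alpha = 1 is the "keep everything tested" sanity path; otherwise
        # the threshold is strict (significance *below* alpha)
        if alpha >= 1.0 or p_bonf < alpha:
            records.append(
                EnrichmentRecord(organism_id, term, k, n, K, N, p, p_bonf, m)
            )
    records.sort(key=lambda r: (r.p_raw, r.term))
    return records


def cross_organism_filter(
    per_organism_results: dict[str, list[EnrichmentRecord]],
    min_organisms: int = 3,
) -> dict[str, list[EnrichmentRecord]]:
    """Keep only terms significant in at least ``min_organisms`` organisms."""
    orgs_per_term: Counter = Counter()
    for org, records in per_organism_results.items():
        for term in {r.term for r in records}:
            orgs_per_term[term] += 1
    return {
        org: [r for r in records if orgs_per_term[r.term] >= min_organisms]
        for org, records in per_organism_results.items()
    }
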