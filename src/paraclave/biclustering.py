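"""Inclusion-maximal biclustering of the species x term incidence matrix.

A bicluster is a pair (row set, column set) whose submatrix is all ones
and to which no further row or column can be added without breaking that
property.  These objects coincide with the formal concepts of the binary
relation, and are enumerated here with a Close-by-One depth-first search
over columns using bitset row masks, with canonical-generation pruning so
every concept is produced exactly once.  Enumeration is exponential in the
worst case, so a budget guard caps the number of concepts.

Overlapping biclusters are retained deliberately: they represent
alternative groupings of the same species/term associations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("paraclave")


@dataclass(frozen=True)
class Bicluster:
    rows: tuple[str, ...]
    cols: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(sorted(self.rows)))
        object.__setattr__(self, "cols", tuple(sorted(self.cols)))


def binarize(
    term_sets: Mapping[str, Iterable[str]], min_terms: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Build the binary organism x term incidence matrix.

    Organisms with fewer than ``min_terms`` terms cannot take part in any
    non-trivial bicluster; they are excluded from the matrix and returned
    as a separate "unclusterable" list.
    """
    sets = {org: set(terms) for org, terms in term_sets.items()}
    excluded = sorted(org for org, terms in sets.items() if len(terms) < min_terms)
    kept = {org: terms for org, terms in sets.items() if len(terms) >= min_terms}
    if not kept:
        raise ValueError("no organism has enough terms to build an incidence matrix")
    cols = sorted(set().union(*kept.values()))
    rows = sorted(kept)
    data = [[1 if t in kept[org] else 0 for t in cols] for org in rows]
    if excluded:
        logger.warning("%d organisms excluded from biclustering: %s", len(excluded), excluded)
    return pd.DataFrame(data, index=rows, columns=cols), excluded


def bimax(
    matrix: pd.DataFrame,
    min_rows: int = 2,
    min_cols: int = 2,
    max_biclusters: int = 100_000,
) -> list[Bicluster]:
    """Enumerate all inclusion-maximal all-ones submatrices above size minima.

    Output is deterministic: sorted by (|rows| desc, |cols| desc, labels).
    Raises if the concept count exceeds ``max_biclusters`` -- such inputs
    should be decomposed (e.g. by connected component) before enumeration.
    """
    row_labels = list(matrix.index)
    col_labels = list(matrix.columns)
    n_rows, n_cols = len(row_labels), len(col_labels)
    vals = matrix.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise ValueError("incidence matrix must be binary")
    row_masks = [
        sum(1 << j for j in range(n_cols) if vals[i, j]) for i in range(n_rows)
    ]
    full_cols = (1 << n_cols) - 1

    def intent_of(rows: list[int]) -> int:
        out = full_cols
        for r in rows:
            out &= row_masks[r]
        return out

    concepts: list[tuple[tuple[int, ...], int]] = []
    all_rows = list(range(n_rows))
    top_intent = intent_of(all_rows) if all_rows else 0

    def emit(rows: tuple[int, ...], intent: int) -> None:
        concepts.append((rows, intent))
        if len(concepts) > max_biclusters:
            raise RuntimeError(
                f"more than {max_biclusters} biclusters; decompose the matrix "
                "(e.g. by connected component) or raise max_biclusters"
            )

    def dfs(extent: list[int], intent: int, start_col: int) -> None:
        for j in range(start_col, n_cols):
            bit = 1 << j
            if intent & bit:
                continue
            new_extent = [r for r in extent if row_masks[r] & bit]
            if not new_extent:
                continue
            new_intent = intent_of(new_extent)
            below = bit - 1  # columns with index < j
            if (new_intent & below) == (intent & below):
                emit(tuple(new_extent), new_intent)
                dfs(new_extent, new_intent, j + 1)

    if n_rows:
        emit(tuple(all_rows), top_intent)
        dfs(all_rows, top_intent, 0)

    out = []
    for rows, intent in concepts:
        cols = [j for j in range(n_cols) if intent & (1 << j)]
        if len(rows) >= min_rows and len(cols) >= min_cols:
            out.append(
                Bicluster(
                    rows=tuple(row_labels[r] for r in rows),
                    cols=tuple(col_labels[c] for c in cols),
                )
            )
    out = sorted(set(out), key=lambda b: (-len(b.rows), -len(b.cols), b.rows, b.cols))
    return out


def drop_single_species_clusters(
    biclusters: list[Bicluster],
    strain_map: Mapping[str, str],
    species: Iterable[str] | None = None,
) -> tuple[list[Bicluster], dict[str, int]]:
    """Remove biclusters whose organisms all belong to one species.

    Many sequenced strains of a single species produce large, artificially
    uniform clusters; dropping them keeps only multi-species signal.  With
    ``species`` given, only those species labels trigger removal.  Returns
    the kept clusters and a per-species count of removals.  Organisms
    missing from ``strain_map`` are treated as their own species.
    """
    limit = set(species) if species is not None else None
    removed: Counter = Counter()
    kept: list[Bicluster] = []
    warned: set[str] = set()
    for bc in biclusters:
        labels = set()
        for org in bc.rows:
            if org not in strain_map and org not in warned:
                logger.warning("organism %s missing from strain map; using its own ID", org)
                warned.add(org)
            labels.add(strain_map.get(org, org))
        if len(labels) == 1:
            label = next(iter(labels))
            if limit is None or label in limit:
                removed[label] += 1
                continue
        kept.append(bc)
    return kept, dict(sorted(removed.items()))


def cooccurrence_counts(
    biclusters: list[Bicluster],
    exclude_species: Iterable[str] = (),
    strain_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count (organism, term) co-memberships over all biclusters.

    The count for a pair is the number of biclusters containing both the
    organism row and the term column.  Organisms belonging to
    ``exclude_species`` (via ``strain_map``) are removed first, since many
    near-identical strains inflate their own associations.
    """
    excluded = set(exclude_species)
    smap = strain_map or {}
    counts: Counter = Counter()
    for bc in biclusters:
        for org in bc.rows:
            if smap.get(org, org) in excluded:
                continue
            for term in bc.cols:
                counts[(org, term)] += 1
    rows = [
        {"organism_id": org, "term": term, "count": n}
        for (org, term), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["organism_id", "term", "count"])
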