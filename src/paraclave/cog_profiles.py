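"""COG-category frequency profiles and consensus labels.

A protein classified in several COG categories contributes one count to
each (multi-domain proteins genuinely belong to several functional
classes); an unclassified protein contributes a single count to ``-``.
Fractions are therefore over *assignments*, not proteins.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("paraclave")

CATEGORIES = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + ["-"]

RIBOSOMAL_RE = re.compile(r"ribosomal", re.IGNORECASE)


@dataclass
class CogDistribution:
    counts: dict[str, int]
    fractions: dict[str, float]
    total_assignments: int


class ConsensusCog(NamedTuple):
    category: str
    support: float
    tied: bool


def cog_distribution(
    protein_ids: Iterable[str], cog_map: Mapping[str, set[str]]
) -> CogDistribution:
    """Category counts/fractions for a set of proteins.

    ``cog_map`` maps protein ID to its set of category letters; proteins
    absent from the map or with an empty set count once under ``-``.
    """
    counts: Counter = Counter()
    for pid in protein_ids:
        cats = cog_map.get(pid, set())
        if cats:
            counts.update(cats)
        else:
            counts["-"] += 1
    total = sum(counts.values())
    full = {c: counts.get(c, 0) for c in CATEGORIES}
    fractions = {c: (n / total if total else 0.0) for c, n in full.items()}
    return CogDistribution(counts=full, fractions=fractions, total_assignments=total)


def compare_distributions(
    paralogs: CogDistribution,
    singletons: CogDistribution,
    reference: CogDistribution,
    epsilon: float = 0.005,
) -> pd.DataFrame:
    """Per-category comparison of paralog / singleton / reference fractions.

    Because the relative scaling of the two groups is sensitive to choices
    such as ribosomal-protein inclusion, categories are flagged "dominated"
    when one group's fraction is below ``epsilon`` while the other's is at
    least ``5 * epsilon`` -- i.e. comparisons are anchored on near-zero
    classes rather than on ratios alone.
    """
    rows = []
    for cat in CATEGORIES:
        p = paralogs.fractions.get(cat, 0.0)
        s = singletons.fractions.get(cat, 0.0)
        ref = reference.fractions.get(cat, 0.0)
        if p == s:
            log_ratio = 0.0
        elif s == 0.0:
            log_ratio = np.inf
        elif p == 0.0:
            log_ratio = -np.inf
        else:
            log_ratio = float(np.log2(p / s))
        if s < epsilon <= 5 * epsilon <= p:
            dominated = "paralog"
        elif p < epsilon <= 5 * epsilon <= s:
            dominated = "singleton"
        else:
            dominated = ""
        rows.append(
            {
                "category": cat,
                "paralog_fraction": p,
                "singleton_fraction": s,
                "reference_fraction": ref,
                "log2_ratio": log_ratio,
                "dominated": dominated,
            }
        )
    return pd.DataFrame(rows)


def consensus_cog(
    cluster_paralog_ids: Iterable[str], cog_map: Mapping[str, set[str]]
) -> ConsensusCog:
    """Plurality COG category over all paralogs in a cluster.

    Ties are broken by the lexicographically smallest letter and flagged.
    Support is the winning count over total assignments.
    """
    ids = list(cluster_paralog_ids)
    if not ids:
        raise ValueError("cluster must be non-empty")
    dist = cog_distribution(ids, cog_map)
    best = max(dist.counts.values())
    winners = sorted(c for c, n in dist.counts.items() if n == best)
    return ConsensusCog(
        category=winners[0],
        support=best / dist.total_assignments,
        tied=len(winners) > 1,
    )


def per_term_cog(
    member_paralogs: Iterable[str], cog_map: Mapping[str, set[str]]
) -> str:
    """Plurality COG category for the paralogs annotated with one term.

    Applied per ontology term this may legitimately differ from the
    cluster-level consensus; both labels are reported unchanged.
    """
    return consensus_cog(member_paralogs, cog_map).category


def filter_ribosomal(
    protein_ids: Iterable[str], product_names: Mapping[str, str]
) -> list[str]:
    """Drop proteins whose product name matches a ribosomal regex."""
    return [
        pid
        for pid in protein_ids
        if not RIBOSOMAL_RE.search(product_names.get(pid, ""))
    ]
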