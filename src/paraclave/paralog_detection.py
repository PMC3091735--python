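"""Within-proteome paralog calling and the paralog-count vs genome-size trend.

Paralogs are detected by an all-vs-all local-alignment search of a proteome
against itself (BLOSUM62, affine gaps, Karlin-Altschul E-values with the
proteome's residue count as database size).  A protein is a paralog when it
has at least one non-self hit at or above the identity threshold; the
number of copies is deliberately ignored, so the paralog fraction counts
proteins, not duplication events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Align import PairwiseAligner, substitution_matrices
from statsmodels.stats.outliers_influence import OLSInfluence

from .core_model import PROTEIN_ALPHABET, Proteome

logger = logging.getLogger("paraclave")

# gapped Karlin-Altschul parameters for BLOSUM62 with open/extend 11/1
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-hits must not be stored")
        if self.percent_identity > 100.0:
            raise ValueError("percent identity above 100")


@dataclass
class Paranome:
    organism_id: str
    paralog_ids: frozenset[str]
    paralog_fraction: float


@dataclass
class TrendFit:
    slope: float
    intercept: float
    pearson_r: float
    outlier_ids: frozenset = frozenset()
    refit: "TrendFit | None" = field(default=None, repr=False)


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(a: str, b: str, mode: str = "local") -> tuple[float, int, float]:
    """Percent identity over the aligned columns of the best alignment.

    Returns (percent_identity, alignment_length, score).  Alignment length
    counts every column of the aligned region, including internal gaps,
    mirroring the BLAST tabular convention.
    """
    aligner = _make_aligner(mode)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    pident = 100.0 * counts.identities / length if length else 0.0
    return pident, length, aln.score


def evalue(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expectation for a gapped local alignment score."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def all_vs_all(
    proteome: Proteome,
    evalue_max: float = 1e-5,
    max_hits: int = 1000,
    min_coverage: float = 0.0,
) -> list[SimilarityHit]:
    """All-vs-all self search of a proteome; returns per-query hit lists.

    Each unordered pair is aligned once and reported in both directions
    (the E-values differ because the query length enters the expectation).
    ``min_coverage``, if set, additionally requires the aligned region to
    cover that fraction of the shorter sequence.
    """
    for p in proteome.proteins:
        bad = set(p.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"protein {p.id!r} contains illegal characters: {sorted(bad)}")
    db_len = sum(len(p.sequence) for p in proteome.proteins)
    proteins = sorted(proteome.proteins, key=lambda p: p.id)
    per_query: dict[str, list[SimilarityHit]] = {p.id: [] for p in proteins}
    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            pident, length, score = alignment_identity(p.sequence, q.sequence)
            if min_coverage > 0.0:
                if length < min_coverage * min(len(p.sequence), len(q.sequence)):
                    continue
            for query, subject in ((p, q), (q, p)):
                e = evalue(score, len(query.sequence), db_len)
                if e <= evalue_max:
                    per_query[query.id].append(
                        SimilarityHit(query.id, subject.id, pident, length, e, score)
                    )
    hits: list[SimilarityHit] = []
    for pid in sorted(per_query):
        lst = sorted(per_query[pid], key=lambda h: (h.evalue, h.subject_id))
        hits.extend(lst[:max_hits])
    return hits


def call_paralogs(
    proteome: Proteome,
    hits: list[SimilarityHit],
    identity_threshold: float = 75.0,
) -> Paranome:
    """Proteins with >= 1 hit at or above the identity threshold."""
    ids = {
        h.query_id
        for h in hits
        if h.percent_identity >= identity_threshold
    }
    ids |= {
        h.subject_id for h in hits if h.percent_identity >= identity_threshold
    }
    known = set(proteome.by_id)
    unknown = ids - known
    if unknown:
        raise ValueError(f"hits reference proteins not in proteome: {sorted(unknown)}")
    return Paranome(
        organism_id=proteome.organism_id,
        paralog_ids=frozenset(ids),
        paralog_fraction=len(ids) / len(proteome),
    )


def paralog_fraction_rank(paranomes: list[Paranome], top_n: int = 200) -> pd.DataFrame:
    """Rank organisms by paralog fraction (descending, ties lexicographic).

    Returns the top ``top_n`` rows with a ``tied`` flag marking fractions
    shared by more than one organism.
    """
    if not paranomes:
        raise ValueError("at least one paranome required")
    if top_n > len(paranomes):
        logger.warning(
            "top_n=%d exceeds the %d available paranomes; returning all",
            top_n,
            len(paranomes),
        )
    rows = sorted(paranomes, key=lambda p: (-p.paralog_fraction, p.organism_id))
    fractions = [p.paralog_fraction for p in rows]
    df = pd.DataFrame(
        {
            "organism_id": [p.organism_id for p in rows],
            "paralog_fraction": fractions,
            "tied": [fractions.count(f) > 1 for f in fractions],
        }
    )
    return df.head(top_n).reset_index(drop=True)


def fit_trend(
    sizes_mb,
    counts,
    ids=None,
    outlier_policy: str = "flag",
) -> TrendFit:
    """OLS fit of paralog-gene count against genome size (Mb) with Pearson r.

    With ``outlier_policy="flag"``, points whose absolute internally
    studentized residual exceeds 3 are flagged and a second fit excluding
    them is attached as ``refit``.
    """
    x = np.asarray(sizes_mb, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in genome size")
    if ids is None:
        ids = list(range(x.size))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    r = float(np.corrcoef(x, y)[0, 1])
    outliers: frozenset = frozenset()
    refit = None
    if outlier_policy == "flag":
        resid = model.resid
        if np.std(resid) > 1e-12:
            student = OLSInfluence(model).resid_studentized_internal
            mask = np.abs(student) > 3.0
            outliers = frozenset(i for i, m in zip(ids, mask) if m)
            if outliers and (~mask).sum() >= 3 and np.ptp(x[~mask]) > 0:
                refit = fit_trend(x[~mask], y[~mask], outlier_policy="none")
    elif outlier_policy != "none":
        raise ValueError(f"unknown outlier_policy {outlier_policy!r}")
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        outlier_ids=outliers,
        refit=refit,
    )
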