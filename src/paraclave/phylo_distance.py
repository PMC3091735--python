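"""Alignment-free evolutionary distances from shortest unique substrings.

For every position of a query sequence, the *shulen* is the length of the
shortest prefix of the suffix starting there that does NOT occur anywhere
in the subject sequence.  Closely related sequences share long substrings,
so their mean shulen is large; unrelated sequences only share short
background matches whose length is governed by sequence length alone
(about log4 of the subject length for uniform DNA).

The distance estimator inverts an explicit model of the expected mean
shulen.  Writing pi for the per-site mismatch probability between the two
sequences, the longest match starting at a query position is the maximum
of the homologous match (geometric, success rate 1 - pi) and the best
background match (longest common prefix with any of ~m subject suffixes),
truncated at the end of the query.  The observed mean shulen is matched to
this expectation by root finding, and pi is then Jukes-Cantor corrected,
``d = -3/4 ln(1 - 4 pi / 3)``.  Both query/subject orientations are
estimated and averaged.  Pairs whose mean shulen is statistically
indistinguishable from the unrelated-sequence expectation are flagged
saturated and capped at the distance of the near-saturation mismatch rate.

Shulens are computed exactly with a suffix automaton of the (reversed)
subject in O(|query| + |subject|); a naive substring-search oracle in the
test suite guards the implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .biclustering import Bicluster

logger = logging.getLogger("paraclave")

#: mismatch probability at which the Jukes-Cantor correction saturates
JC_BOUND = 0.75
#: cap applied to the mismatch estimate of saturated pairs
PI_CAP = 0.74
#: minimum sequence length for a stable estimate
MIN_STABLE_LENGTH = 1000


def jukes_cantor(pi: float) -> float:
    """Substitutions per site from a mismatch probability."""
    if pi >= JC_BOUND:
        raise ValueError(f"mismatch probability {pi} at or beyond the JC bound")
    return -0.75 * np.log1p(-4.0 * pi / 3.0)


class _SuffixAutomaton:
    """Suffix automaton over a byte string; supports streaming match lengths."""

    __slots__ = ("trans", "link", "length", "last")

    def __init__(self, text: str) -> None:
        self.trans: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.last = 0
        for ch in text:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        trans, link, length = self.trans, self.link, self.length
        cur = len(trans)
        trans.append({})
        length.append(length[self.last] + 1)
        link.append(-1)
        p = self.last
        while p != -1 and ch not in trans[p]:
            trans[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(trans)
                trans.append(dict(trans[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and trans[p].get(ch) == q:
                    trans[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self.last = cur

    def matching_statistics(self, query: str) -> np.ndarray:
        """ms[i] = length of the longest suffix of query[:i+1] occurring in the text."""
        trans, link, length = self.trans, self.link, self.length
        out = np.empty(len(query), dtype=np.int64)
        v, l = 0, 0
        for i, ch in enumerate(query):
            while ch not in trans[v] and v != 0:
                v = link[v]
                l = length[v]
            nxt = trans[v].get(ch)
            if nxt is not None:
                v = nxt
                l += 1
            else:
                l = 0
            out[i] = l
        return out


def _clean(seq: str, label: str = "sequence") -> str:
    seq = seq.upper()
    if set(seq) <= set("ACGT"):
        return seq
    kept = "".join(c for c in seq if c in "ACGT")
    logger.warning(
        "%s: stripped %d non-ACGT symbols", label, len(seq) - len(kept)
    )
    return kept


def shulen_profile(query: str, subject: str) -> np.ndarray:
    """Exact shortest-unique-substring length at every query position.

    ``profile[i]`` is 1 + the length of the longest prefix of ``query[i:]``
    occurring as a substring of ``subject``; when the whole suffix occurs
    the value is (remaining length + 1), the shortest absent extension.
    """
    query, subject = _clean(query, "query"), _clean(subject, "subject")
    if not query or not subject:
        raise ValueError("empty sequence after cleaning")
    # longest prefix of query[i:] in subject == longest suffix of
    # reverse(query)[: n - i] in reverse(subject)
    sa = _SuffixAutomaton(subject[::-1])
    ms = sa.matching_statistics(query[::-1])
    return ms[::-1] + 1


def expected_mean_shulen(pi: float, query_len: int, subject_len: int) -> float:
    """Model expectation of the mean shulen between homologous sequences.

    The longest match from a query position is max(homologous geometric
    match, background match against ~subject_len random suffixes),
    truncated at the query end; summing tail probabilities with the
    truncation weight (1 - x / L) gives the mean of the profile.
    """
    L = query_len
    x = np.arange(0, L, dtype=float)
    p_hom_gt = (1.0 - pi) ** (x + 1.0)  # P(homologous match > x)
    with np.errstate(divide="ignore"):
        log_bg_le = subject_len * np.log1p(-(0.25 ** (x + 1.0)))
    p_bg_le = np.exp(log_bg_le)  # P(background match <= x)
    tail = 1.0 - (1.0 - p_hom_gt) * p_bg_le
    return 1.0 + float(np.sum(tail * (1.0 - x / L)))


@dataclass
class KrEstimate:
    distance: float
    saturated: bool = False
    low_confidence: bool = False


def _pi_from_profile(profile: np.ndarray, subject_len: int) -> tuple[float, bool]:
    """Invert the mean-shulen model for one direction; returns (pi, saturated)."""
    profile = profile.astype(float)
    obs = float(profile.mean())
    L, m = len(profile), subject_len
    # standard error of the mean via block means (positions are correlated)
    block = 200
    n_blocks = max(L // block, 1)
    blocks = profile[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    se = float(blocks.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    e_null = expected_mean_shulen(PI_CAP, L, m)
    if obs <= e_null + 4.0 * se:
        return PI_CAP, True
    lo, hi = 1e-9, PI_CAP
    if obs >= expected_mean_shulen(lo, L, m):
        return 0.0, False
    pi = brentq(lambda p: expected_mean_shulen(p, L, m) - obs, lo, hi, xtol=1e-9)
    return float(pi), False


def kr_distance(a: str, b: str) -> KrEstimate:
    """Symmetric alignment-free substitutions-per-site estimate.

    Both directed mismatch estimates are Jukes-Cantor corrected and
    averaged.  Saturated pairs (mean shulen consistent with unrelated
    sequences) are capped and flagged; sequences shorter than 1 kb are
    flagged low-confidence.
    """
    a, b = _clean(a, "a"), _clean(b, "b")
    low_conf = min(len(a), len(b)) < MIN_STABLE_LENGTH
    if low_conf:
        logger.warning("sequences shorter than %d bp; distance has wide uncertainty",
                       MIN_STABLE_LENGTH)
    if a == b:
        return KrEstimate(0.0, saturated=False, low_confidence=low_conf)
    pi_ab, sat_ab = _pi_from_profile(shulen_profile(a, b), len(b))
    pi_ba, sat_ba = _pi_from_profile(shulen_profile(b, a), len(a))
    saturated = sat_ab and sat_ba
    d = 0.5 * (jukes_cantor(min(pi_ab, PI_CAP)) + jukes_cantor(min(pi_ba, PI_CAP)))
    return KrEstimate(float(d), saturated=saturated, low_confidence=low_conf)


def distance_matrix(
    sequences: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[tuple[str, str], KrEstimate]]:
    """All pairwise distances; symmetric with zero diagonal.

    Organisms with empty sequences are dropped with a warning.  Returns the
    matrix and the per-pair estimates (with saturation flags).
    """
    cleaned = {}
    for org in sorted(sequences):
        seq = _clean(sequences[org], org)
        if seq:
            cleaned[org] = seq
        else:
            logger.warning("organism %s has no usable sequence; dropped", org)
    labels = sorted(cleaned)
    if len(labels) < 2:
        raise ValueError("need at least 2 organisms with sequences")
    # one suffix automaton per (reversed) sequence, shared across all pairs
    automata = {org: _SuffixAutomaton(cleaned[org][::-1]) for org in labels}
    reversed_seqs = {org: cleaned[org][::-1] for org in labels}

    def directed(query: str, subject: str) -> tuple[float, bool]:
        ms = automata[subject].matching_statistics(reversed_seqs[query])
        return _pi_from_profile(ms[::-1] + 1, len(cleaned[subject]))

    d = np.zeros((len(labels), len(labels)))
    details: dict[tuple[str, str], KrEstimate] = {}
    low_conf = min(len(s) for s in cleaned.values()) < MIN_STABLE_LENGTH
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            if cleaned[a] == cleaned[b]:
                est = KrEstimate(0.0, saturated=False, low_confidence=low_conf)
            else:
                pi_ab, sat_ab = directed(a, b)
                pi_ba, sat_ba = directed(b, a)
                est = KrEstimate(
                    0.5 * (jukes_cantor(min(pi_ab, PI_CAP))
                           + jukes_cantor(min(pi_ba, PI_CAP))),
                    saturated=sat_ab and sat_ba,
                    low_confidence=low_conf,
                )
            d[i, j] = d[j, i] = est.distance
            details[(a, b)] = est
    return pd.DataFrame(d, index=labels, columns=labels), details


def write_phylip(matrix: pd.DataFrame, path: str | Path) -> None:
    """Square PHYLIP distance matrix (names truncated/padded to 10 chars)."""
    labels = list(matrix.index)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for a in labels:
            vals = " ".join(f"{matrix.loc[a, b]:.6f}" for b in labels)
            fh.write(f"{a[:10]:<10} {vals}\n")


def cluster_distance(
    bicluster: Bicluster, matrix: pd.DataFrame, method: str = "mean"
) -> float:
    """Aggregate pairwise distance over a bicluster's organisms.

    ``mean`` (default) averages all unordered pairs; ``max`` takes the
    widest pair.  A bicluster with a single organism has distance 0.
    """
    missing = sorted(set(bicluster.rows) - set(matrix.index))
    if missing:
        raise ValueError(f"organisms missing from distance matrix: {missing}")
    pairs = [matrix.loc[a, b] for a, b in combinations(bicluster.rows, 2)]
    if not pairs:
        return 0.0
    if method == "mean":
        return float(np.mean(pairs))
    if method == "max":
        return float(np.max(pairs))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ClusterScore:
    bicluster: Bicluster
    go_similarity: float
    phylo_distance: float


@dataclass
class ConvergenceCall:
    bicluster: Bicluster
    go_similarity: float
    phylo_distance: float
    selected: bool


def select_convergent(
    cluster_scores: Sequence[ClusterScore],
    sim_cut: float = 0.7,
    dist_cut: float = 0.1,
    dedup: bool = True,
) -> list[ConvergenceCall]:
    """Flag biclusters that are functionally similar yet phylogenetically distant.

    Selection requires strictly ``go_similarity > sim_cut`` AND
    ``phylo_distance > dist_cut``.  With ``dedup``, among selected clusters
    with overlapping organism sets only the one with fewest organisms is
    kept (ties: fewest terms, then lexicographic), since overlapping
    biclusters are alternative views of the same signal.
    """
    passing = [
        cs
        for cs in cluster_scores
        if cs.go_similarity > sim_cut and cs.phylo_distance > dist_cut
    ]
    selected: set[Bicluster] = set()
    if dedup:
        taken_rows: set[str] = set()
        for cs in sorted(
            passing,
            key=lambda c: (len(c.bicluster.rows), len(c.bicluster.cols),
                           c.bicluster.rows, c.bicluster.cols),
        ):
            if not (set(cs.bicluster.rows) & taken_rows):
                selected.add(cs.bicluster)
                taken_rows |= set(cs.bicluster.rows)
    else:
        selected = {cs.bicluster for cs in passing}
    return [
        ConvergenceCall(
            bicluster=cs.bicluster,
            go_similarity=cs.go_similarity,
            phylo_distance=cs.phylo_distance,
            selected=cs.bicluster in selected,
        )
        for cs in cluster_scores
    ]
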