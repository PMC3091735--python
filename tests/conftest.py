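"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
substring search, brute-force path products) and independent of the
implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paraclave.core_model import OntologyDag

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact hypergeometric upper tail by integer enumeration."""
    if k == 0:
        return 1.0
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def maximal_biclusters_oracle(matrix, min_rows=2, min_cols=2):
    """All inclusion-maximal all-ones submatrices by row-subset enumeration."""
    rows = list(matrix.index)
    cols = list(matrix.columns)
    vals = matrix.to_numpy()
    n_rows = len(rows)
    found = set()
    for size in range(1, n_rows + 1):
        for subset in combinations(range(n_rows), size):
            common = [j for j in range(len(cols)) if all(vals[r, j] for r in subset)]
            if not common:
                continue
            # close on rows: every row containing all common columns
            closed_rows = tuple(
                r for r in range(n_rows) if all(vals[r, j] for j in common)
            )
            if closed_rows == subset:
                found.add(
                    (
                        tuple(rows[r] for r in subset),
                        tuple(cols[j] for j in common),
                    )
                )
    return {
        (r, c)
        for r, c in found
        if len(r) >= min_rows and len(c) >= min_cols
    }


def shulen_oracle(query: str, subject: str) -> np.ndarray:
    """Naive O(n*m) shortest-unique-substring profile."""
    n = len(query)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        length = 0
        while i + length < n and query[i : i + length + 1] in subject:
            length += 1
        out[i] = length + 1
    return out


def wang_svalues_oracle(term: str, dag: OntologyDag, weights=None) -> dict[str, float]:
    """S-values by exhaustive enumeration of upward paths (max product)."""
    w = {"is_a": 0.8, "part_of": 0.6} if weights is None else dict(weights)
    best = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, value = stack.pop()
        for parent, rel in dag.parents(node):
            cand = value * w[rel]
            if cand > best.get(parent, 0.0):
                best[parent] = cand
                stack.append((parent, cand))
    return best


def jc_alignment_oracle(a: str, b: str) -> float:
    """Alignment-based Jukes-Cantor distance for equal-length sequences."""
    assert len(a) == len(b)
    mism = sum(x != y for x, y in zip(a, b)) / len(a)
    return -0.75 * np.log1p(-4.0 * mism / 3.0)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def chain_dag() -> OntologyDag:
    """c is_a b is_a a, all one namespace."""
    return OntologyDag(
        terms={"a", "b", "c"},
        edges={("c", "b", "is_a"), ("b", "a", "is_a")},
        namespaces={t: "process" for t in "abc"},
    )


@pytest.fixture(scope="session")
def demo_world(tmp_path_factory):
    """The bundled 12-organism synthetic world, built once per session."""
    from paraclave.synthetic_data import build_demo_world

    world = tmp_path_factory.mktemp("demo_world")
    config_path = build_demo_world(world, seed=0)
    return world, config_path


@pytest.fixture(scope="session")
def demo_run(demo_world, tmp_path_factory):
    """One full pipeline run over the demo world."""
    from paraclave.pipeline import PipelineConfig, run_all

    world, config_path = demo_world
    outdir = tmp_path_factory.mktemp("demo_run")
    config = PipelineConfig.from_yaml(config_path)
    bundle = run_all(config, outdir)
    return world, outdir, bundle
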