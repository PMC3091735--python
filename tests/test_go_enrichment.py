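"""Propagation, the Fisher tail, per-organism enrichment and the cross-organism filter."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paraclave.core_model import AnnotationMap, OntologyDag
from paraclave.go_enrichment import (
    BackgroundModel,
    EnrichmentRecord,
    cross_organism_filter,
    enrich_organism,
    fisher_p,
    propagate,
)
from tests.conftest import fisher_oracle


class TestPropagate:
    def test_chain(self, chain_dag):
        out = propagate(AnnotationMap(direct={"p": {"c"}}), chain_dag)
        assert out.propagated["p"] == {"a", "b", "c"}

    def test_diamond_root_once(self):
        dag = OntologyDag(
            terms={"r", "x", "y", "leaf"},
            edges={
                ("x", "r", "is_a"),
                ("y", "r", "is_a"),
                ("leaf", "x", "is_a"),
                ("leaf", "y", "part_of"),
            },
        )
        out = propagate(AnnotationMap(direct={"p": {"leaf"}}), dag)
        assert out.propagated["p"] == {"r", "x", "y", "leaf"}

    def test_empty_direct(self, chain_dag):
        out = propagate(AnnotationMap(direct={"p": set()}), chain_dag)
        assert out.propagated["p"] == set()

    def test_unknown_term_dropped_with_warning(self, chain_dag, caplog):
        with caplog.at_level("WARNING", logger="paraclave"):
            out = propagate(AnnotationMap(direct={"p": {"c", "nope"}}), chain_dag)
        assert out.direct["p"] == {"c"}
        assert "nope" in caplog.text

    def test_is_a_only_propagation(self):
        dag = OntologyDag(
            terms={"r", "x", "leaf"},
            edges={("x", "r", "part_of"), ("leaf", "x", "is_a")},
        )
        out = propagate(AnnotationMap(direct={"p": {"leaf"}}), dag, relations=("is_a",))
        assert out.propagated["p"] == {"leaf", "x"}


class TestFisher:
    def test_k_zero_is_one(self):
        assert fisher_p(0, 5, 10, 100) == 1.0

    def test_degenerate_table(self):
        assert fisher_p(5, 5, 5, 5) == 1.0

    def test_example_table_equals_enumeration(self):
        assert fisher_p(4, 5, 10, 100) == pytest.approx(
            fisher_oracle(4, 5, 10, 100), abs=1e-14
        )

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            fisher_p(6, 5, 10, 100)
        with pytest.raises(ValueError):
            fisher_p(2, 5, 120, 100)

    @given(
        st.integers(1, 40).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            ).flatmap(
                lambda t: st.tuples(
                    st.just(t[0]),
                    st.just(t[1]),
                    st.just(t[2]),
                    st.integers(0, min(t[1], t[2])),
                )
            )
        )
    )
    def test_monotone_in_k(self, table):
        N, n, K, k = table
        if k > 0:
            assert fisher_p(k, n, K, N) <= fisher_p(k - 1, n, K, N) + 1e-12


def _flat_dag(terms):
    all_terms = set(terms) | {"root"}
    return OntologyDag(
        terms=all_terms,
        edges={(t, "root", "is_a") for t in terms},
    )


class TestEnrichOrganism:
    def test_study_equals_background_nothing_passes(self):
        terms = [f"t{i}" for i in range(5)]
        dag = _flat_dag(terms)
        rng = np.random.default_rng(0)
        direct = {
            f"p{i}": {t for t in terms if rng.random() < 0.3} for i in range(20)
        }
        annotations = propagate(AnnotationMap(direct=direct), dag)
        members = frozenset(direct)
        records = enrich_organism(
            "org", set(members), BackgroundModel("all_paralogs", members), annotations
        )
        assert records == []

    def test_bonferroni_arithmetic(self):
        """p_bonferroni = min(1, m * p_raw) with m = tested terms."""
        terms = [f"t{i}" for i in range(3)]
        dag = _flat_dag(terms)
        direct = {f"s{i}": {"t0"} for i in range(5)}
        direct |= {f"b{i}": {"t1"} for i in range(45)}
        annotations = propagate(AnnotationMap(direct=direct), dag)
        study = {f"s{i}" for i in range(5)}
        background = BackgroundModel("all_paralogs", frozenset(direct))
        records = enrich_organism("org", study, background, annotations, alpha=1.0)
        by_term = {r.term: r for r in records}
        assert by_term["t0"].m_tests == 2  # t0 and the root
        assert by_term["t0"].p_bonferroni == pytest.approx(
            min(1.0, by_term["t0"].p_raw * 2)
        )

    def test_ease_variant_is_more_conservative(self):
        terms = [f"t{i}" for i in range(3)]
        dag = _flat_dag(terms)
        direct = {f"s{i}": {"t0"} for i in range(5)}
        direct |= {f"b{i}": {"t1"} for i in range(45)}
        annotations = propagate(AnnotationMap(direct=direct), dag)
        study = {f"s{i}" for i in range(5)}
        background = BackgroundModel("all_paralogs", frozenset(direct))
        classic = enrich_organism("o", study, background, annotations, alpha=1.0)
        eased = enrich_organism("o", study, background, annotations, alpha=1.0, ease=True)
        p_classic = {r.term: r.p_raw for r in classic}
        p_ease = {r.term: r.p_raw for r in eased}
        assert p_ease["t0"] > p_classic["t0"]

    def test_empty_study_warns(self, caplog):
        dag = _flat_dag(["t0"])
        annotations = propagate(AnnotationMap(direct={"p": {"t0"}}), dag)
        with caplog.at_level("WARNING", logger="paraclave"):
            out = enrich_organism(
                "org", set(), BackgroundModel("all_paralogs", frozenset({"p"})),
                annotations,
            )
        assert out == []

    def test_study_outside_background_rejected(self):
        dag = _flat_dag(["t0"])
        annotations = propagate(AnnotationMap(direct={"p": {"t0"}}), dag)
        with pytest.raises(ValueError, match="background"):
            enrich_organism(
                "org", {"p"}, BackgroundModel("all_paralogs", frozenset({"q"})),
                annotations,
            )

    def test_all_three_backgrounds_produce_valid_records(self):
        terms = [f"t{i}" for i in range(4)]
        dag = _flat_dag(terms)
        rng = np.random.default_rng(1)
        orgs = {f"o{j}": [f"o{j}p{i}" for i in range(30)] for j in range(3)}
        direct = {}
        for j, (org, prots) in enumerate(orgs.items()):
            for pid in prots:
                direct[pid] = {t for t in terms if rng.random() < 0.2}
        # make o0's paranome strongly annotated with t0
        paranome = set(orgs["o0"][:10])
        for pid in paranome:
            direct[pid] = direct[pid] | {"t0"}
        annotations = propagate(AnnotationMap(direct=direct), dag)
        all_paralogs = frozenset(p for prots in orgs.values() for p in prots[:10])
        pools = {
            "all_paralogs": all_paralogs,
            "all_proteomes": frozenset(direct),
            "individual_proteome": frozenset(orgs["o0"]),
        }
        for kind, members in pools.items():
            records = enrich_organism(
                "o0", paranome, BackgroundModel(kind, members), annotations, alpha=1.0
            )
            for r in records:
                assert 0 <= r.k <= min(r.n, r.K)
                assert r.n == len(paranome) and r.N == len(members)
                assert 0 <= r.p_raw <= r.p_bonferroni <= 1


class TestCrossOrganismFilter:
    def _rec(self, org, term):
        return EnrichmentRecord(org, term, 1, 1, 1, 2, 0.001, 0.001, 1)

    def test_term_in_two_organisms_removed(self):
        results = {
            "a": [self._rec("a", "t")],
            "b": [self._rec("b", "t")],
            "c": [],
        }
        out = cross_organism_filter(results, min_organisms=3)
        assert all(not v for v in out.values())

    def test_term_in_three_kept_exactly_there(self):
        results = {o: [self._rec(o, "t")] for o in "abc"} | {"d": []}
        out = cross_organism_filter(results, min_organisms=3)
        assert {o for o, v in out.items() if v} == {"a", "b", "c"}

    def test_min_one_is_identity(self):
        results = {"a": [self._rec("a", "t")], "b": []}
        assert cross_organism_filter(results, min_organisms=1) == results


class TestNullCalibration:
    def test_null_false_positive_rate_small(self):
        """Without planted signal, Bonferroni keeps per-organism FWER under alpha."""
        from paraclave.synthetic_data import (
            FamilySpec,
            generate_annotations,
            generate_go_dag,
            generate_proteome,
        )

        dag = generate_go_dag(30, 1, mean_parents=1.2, seed=0)
        fp_orgs = 0
        n_orgs = 0
        for seed in range(30):
            proteomes, paranomes = [], {}
            for j in range(2):
                p, truth = generate_proteome(
                    [FamilySpec(3, 0.9, 40)] * 3, 41, 1000,
                    seed=seed * 10 + j, organism_id=f"s{seed}o{j}",
                    singleton_length=40,
                )
                proteomes.append(p)
                paranomes[p.organism_id] = set(truth[truth.is_paralog].protein_id)
            annotations, _ = generate_annotations(
                proteomes, paranomes, dag, planted={}, base_rate=0.05, seed=seed
            )
            members = frozenset().union(*paranomes.values())
            background = BackgroundModel("all_paralogs", members)
            for org in paranomes:
                n_orgs += 1
                if enrich_organism(org, paranomes[org], background, annotations):
                    fp_orgs += 1
        assert fp_orgs / n_orgs <= 0.05
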