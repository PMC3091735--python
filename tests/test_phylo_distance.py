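"""Shulen profiles, the alignment-free distance, and the convergence screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paraclave.biclustering import Bicluster
from paraclave.phylo_distance import (
    ClusterScore,
    cluster_distance,
    distance_matrix,
    kr_distance,
    select_convergent,
    shulen_profile,
    write_phylip,
)
from paraclave.synthetic_data import SimTree, generate_16s_set
from tests.conftest import shulen_oracle


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestShulenProfile:
    def test_self_comparison_convention(self):
        rng = np.random.default_rng(0)
        seq = _random_dna(rng, 200)
        profile = shulen_profile(seq, seq)
        # every suffix occurs, so each value is remaining length + 1
        assert (profile == np.arange(len(seq), 0, -1) + 1).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = _random_dna(rng, 400)
        s = _random_dna(rng, 500)
        assert (shulen_profile(q, s) == shulen_oracle(q, s)).all()

    def test_mismatch_dips_profile(self):
        rng = np.random.default_rng(1)
        s = _random_dna(rng, 1000)
        q = s[:500] + ("A" if s[500] != "A" else "C") + s[501:]
        full = shulen_profile(s, s)
        dipped = shulen_profile(q, s)
        window = slice(480, 502)
        assert dipped[window].mean() < full[window].mean()
        assert (dipped == shulen_oracle(q, s)).all()

    def test_random_mean_near_log4_of_subject(self):
        rng = np.random.default_rng(2)
        q = _random_dna(rng, 10_000)
        s = _random_dna(rng, 10_000)
        mean = shulen_profile(q, s).mean()
        expected = np.log(len(s)) / np.log(4)
        assert abs(mean - expected) < 3.0  # O(1) offset around log4(m)

    def test_non_acgt_stripped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        s = _random_dna(rng, 200)
        with caplog.at_level("WARNING", logger="paraclave"):
            profile = shulen_profile(s[:100] + "NNN" + s[100:], s)
        assert len(profile) == 200
        assert "stripped" in caplog.text


class TestKrDistance:
    def test_identical_zero(self):
        rng = np.random.default_rng(0)
        seq = _random_dna(rng, 2000)
        est = kr_distance(seq, seq)
        assert est.distance == 0.0 and not est.saturated

    def test_jc_pair_recovered(self):
        tree = SimTree.from_newick("(A:0.05,B:0.05);")
        seqs, _ = generate_16s_set(tree, 50_000, seed=3)
        est = kr_distance(seqs["A"], seqs["B"])
        assert 0.08 <= est.distance <= 0.12
        assert not est.saturated

    def test_independent_random_saturated(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = _random_dna(rng, 10_000)
            b = _random_dna(rng, 10_000)
            assert kr_distance(a, b).saturated

    def test_short_sequences_low_confidence(self, caplog):
        rng = np.random.default_rng(5)
        with caplog.at_level("WARNING", logger="paraclave"):
            est = kr_distance(_random_dna(rng, 300), _random_dna(rng, 300))
        assert est.low_confidence


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        rng = np.random.default_rng(0)
        seq = _random_dna(rng, 2000)
        mat, _ = distance_matrix({"a": seq, "b": seq, "c": seq})
        assert (mat.to_numpy() == 0).all()

    def test_star_tree_equal_branches(self):
        newick = "(" + ",".join(f"L{i}:0.05" for i in range(4)) + ");"
        seqs, _ = generate_16s_set(SimTree.from_newick(newick), 50_000, seed=6)
        mat, _ = distance_matrix(seqs)
        off = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert ((off >= 0.08) & (off <= 0.12)).all()
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_empty_sequence_dropped(self, caplog):
        rng = np.random.default_rng(1)
        seqs = {"a": _random_dna(rng, 2000), "b": _random_dna(rng, 2000), "c": ""}
        with caplog.at_level("WARNING", logger="paraclave"):
            mat, _ = distance_matrix(seqs)
        assert list(mat.index) == ["a", "b"]

    def test_phylip_writer(self, tmp_path):
        mat = pd.DataFrame(
            [[0.0, 0.1], [0.1, 0.0]], index=["aa", "bb"], columns=["aa", "bb"]
        )
        p = tmp_path / "m.phy"
        write_phylip(mat, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("aa") and "0.100000" in lines[1]


class TestClusterDistance:
    def _matrix(self):
        labels = ["a", "b", "c"]
        vals = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        return pd.DataFrame(vals, index=labels, columns=labels)

    def test_pair_is_single_distance(self):
        bc = Bicluster(("a", "b"), ("t",))
        assert cluster_distance(bc, self._matrix()) == pytest.approx(0.1)

    def test_triple_mean(self):
        bc = Bicluster(("a", "b", "c"), ("t",))
        assert cluster_distance(bc, self._matrix()) == pytest.approx(0.2)

    def test_max_method(self):
        bc = Bicluster(("a", "b", "c"), ("t",))
        assert cluster_distance(bc, self._matrix(), method="max") == pytest.approx(0.3)

    def test_missing_organism_listed(self):
        bc = Bicluster(("a", "zz"), ("t",))
        with pytest.raises(ValueError, match="zz"):
            cluster_distance(bc, self._matrix())


class TestSelectConvergent:
    def _score(self, name, sim, dist, rows=("a", "b")):
        return ClusterScore(Bicluster(rows, (name,) + ("t2",)), sim, dist)

    def test_strict_cuts(self):
        calls = select_convergent(
            [
                self._score("low_dist", 0.8, 0.05),
                self._score("ok", 0.75, 0.15, rows=("c", "d")),
                self._score("at_cut", 0.7, 0.15, rows=("e", "f")),
            ]
        )
        selected = {c.bicluster.cols[0] for c in calls if c.selected}
        assert selected == {"ok"}

    def test_overlap_dedup_keeps_smallest(self):
        big = ClusterScore(Bicluster(("a", "b", "c", "d", "e"), ("t1", "t2")), 0.9, 0.2)
        small = ClusterScore(Bicluster(("a", "b", "c"), ("t1", "t2")), 0.8, 0.2)
        calls = select_convergent([big, small])
        by_size = {len(c.bicluster.rows): c.selected for c in calls}
        assert by_size == {5: False, 3: True}

    def test_dedup_disabled_keeps_both(self):
        big = ClusterScore(Bicluster(("a", "b", "c", "d", "e"), ("t1", "t2")), 0.9, 0.2)
        small = ClusterScore(Bicluster(("a", "b", "c"), ("t1", "t2")), 0.8, 0.2)
        calls = select_convergent([big, small], dedup=False)
        assert all(c.selected for c in calls)

    def test_cut_monotonicity(self):
        rng = np.random.default_rng(7)
        scores = [
            ClusterScore(
                Bicluster((f"x{i}", f"y{i}"), ("t1", "t2")),
                float(rng.uniform(0.4, 1.0)),
                float(rng.uniform(0.0, 0.4)),
            )
            for i in range(40)
        ]
        prev_by_dist: dict[float, set] = {}
        for sim_cut in (0.5, 0.6, 0.7, 0.8):
            prev = None
            for dist_cut in (0.05, 0.1, 0.2):
                chosen = {
                    c.bicluster
                    for c in select_convergent(scores, sim_cut, dist_cut, dedup=False)
                    if c.selected
                }
                if prev is not None:
                    assert chosen <= prev
                if dist_cut in prev_by_dist:
                    assert chosen <= prev_by_dist[dist_cut]
                prev_by_dist[dist_cut] = chosen
                prev = chosen


class TestConsistency:
    def test_median_error_and_monotonicity_over_grid(self):
        """Mean estimates increase with true d; median |error| stays small."""
        grid = [0.02, 0.05, 0.1, 0.2]
        means = []
        for d in grid:
            errors = []
            tree = SimTree.from_newick(f"(A:{d / 2},B:{d / 2});")
            ests = []
            for seed in range(8):
                seqs, _ = generate_16s_set(tree, 20_000, seed=seed)
                est = kr_distance(seqs["A"], seqs["B"]).distance
                ests.append(est)
                errors.append(abs(est - d))
            means.append(np.mean(ests))
            assert np.median(errors) <= 0.02
        assert all(b > a for a, b in zip(means, means[1:]))
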