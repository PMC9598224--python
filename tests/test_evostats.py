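"""Neutrality, transition/transversion bias and distance/tree statistics."""

import math

import numpy as np
import pytest

from trnadyn import (GeneAlignment, distance_matrix, leaf_order, nj_tree,
                     ordered_matrix, tajima_d, tstv_bias)
from trnadyn.evostats import tajima_coefficients, tn93_distance


def _alig(rows, domain="D-loop"):
    length = len(next(iter(rows.values())))
    return GeneAlignment("trnX", rows, [domain] * length)


class TestTajima:
    def test_a1_matches_direct_summation(self):
        for n in range(4, 51):
            coef = tajima_coefficients(n)
            assert coef["a1"] == pytest.approx(
                sum(1 / i for i in range(1, n)), abs=1e-12)
            assert coef["a2"] == pytest.approx(
                sum(1 / i ** 2 for i in range(1, n)), abs=1e-12)

    def test_identical_sequences_have_null_d(self):
        rows = {f"s{i}": "ACGTACGTAC" for i in range(5)}
        res = tajima_d(_alig(rows))
        assert res.S == 0 and res.D is None and not res.significant

    def test_small_sample_rejected(self):
        rows = {"a": "ACGT", "b": "ACGA", "c": "ACGT"}
        with pytest.raises(ValueError):
            tajima_d(_alig(rows))

    def test_gap_columns_excluded(self):
        rows = {"s0": "AAAA-", "s1": "AAAAC", "s2": "AAAAC", "s3": "AAAAC"}
        res = tajima_d(_alig(rows))
        assert res.S == 0   # the only variable column contains a gap


class TestTsTv:
    def test_identical_sequences_undefined(self):
        rows = {"a": "ACGT" * 10, "b": "ACGT" * 10}
        assert tstv_bias(_alig(rows)).R is None

    def test_pure_transversions_give_vanishing_bias(self):
        rng = np.random.default_rng(0)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}   # transversions
        b = "".join(flip[ch] if rng.random() < 0.1 else ch for ch in a)
        res = tstv_bias(_alig({"a": a, "b": b}))
        assert res.R is not None and res.R < 0.2

    def test_coverage_filter_drops_gappy_columns(self):
        rows = {"a": "ACGTA", "b": "ACGT-", "c": "ACGTA", "d": "ACGTA"}
        res = tstv_bias(_alig(rows), coverage_cutoff=0.95)
        assert res.sites_used == 4


class TestDistancesAndNJ:
    def test_distance_axioms(self, aligned_cohort):
        _, _, aligs = aligned_cohort
        mat = distance_matrix(list(aligs.values()))
        vals = mat.values
        assert np.allclose(vals, vals.T)
        assert np.allclose(np.diag(vals), 0)
        assert (vals >= 0).all()

    def test_identical_sequences_distance_zero(self):
        rows = {"a": "ACGT" * 20, "b": "ACGT" * 20, "c": "AGGT" * 20}
        mat = distance_matrix(_alig(rows))
        assert mat.loc["a", "b"] == 0
        assert mat.loc["a", "c"] > 0

    def test_nj_recovers_additive_four_taxon_tree(self):
        """((A,B),(C,D)) with known branch lengths is recovered exactly
        from its additive distance matrix."""
        import io
        import pandas as pd
        from skbio import TreeNode
        # branches: A=0.1, B=0.2, internal=0.3, C=0.15, D=0.25
        bl = {"A": 0.1, "B": 0.2, "C": 0.15, "D": 0.25}
        internal = 0.3
        names = ["A", "B", "C", "D"]
        dist = pd.DataFrame(0.0, index=names, columns=names)
        for i in names:
            for j in names:
                if i == j:
                    continue
                same = {i, j} <= {"A", "B"} or {i, j} <= {"C", "D"}
                dist.loc[i, j] = bl[i] + bl[j] + (0 if same else internal)
        newick = nj_tree(dist)
        tree = TreeNode.read(io.StringIO(newick))
        # the split {A,B} | {C,D} must be present
        splits = set()
        for node in tree.non_tips(include_self=False):
            splits.add(frozenset(t.name for t in node.tips()))
        assert frozenset({"A", "B"}) in splits \
            or frozenset({"C", "D"}) in splits
        # recovered patristic distances equal the additive input
        for i in names:
            for j in names:
                if i < j:
                    ti = tree.find(i)
                    assert ti.distance(tree.find(j)) == pytest.approx(
                        dist.loc[i, j], abs=1e-9)

    def test_ordered_matrix_follows_leaf_order(self):
        rows = {"a": "ACGT" * 20, "b": "ACGA" * 20, "c": "TCGA" * 20,
                "d": "TGGA" * 20}
        mat = distance_matrix(_alig(rows))
        newick = nj_tree(mat)
        om = ordered_matrix(mat, newick)
        assert list(om.index) == leaf_order(newick)
        assert set(om.index) == set(mat.index)


class TestTN93Distance:
    def test_zero_for_identical(self):
        g = {b: 0.25 for b in "ACGT"}
        assert tn93_distance(0, 0, 0, g) == pytest.approx(0)

    def test_reduces_to_jukes_cantor_under_equal_rates(self):
        # equal base frequencies with every substitution type equally
        # frequent (p1 = p2 = p/6, q = 2p/3) must collapse to Jukes-Cantor
        g = {b: 0.25 for b in "ACGT"}
        p = 0.1
        d = tn93_distance(p / 6, p / 6, 2 * p / 3, g)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, rel=1e-9)
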